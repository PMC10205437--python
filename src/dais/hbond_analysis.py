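"""Hydrogen-bond formation rates around significant structural features.

Around each feature of interest, all atoms of every residue whose CA lies
within 10 Å of any generator CA are collected (whole-residue inclusion).
A hydrogen bond D-H···A is counted in a frame when the hydrogen is
covalently carried by an N/O donor, the acceptor is N/O of a different
residue, the H···A distance R satisfies 1.5 <= R <= 2.2 Å (closed bounds)
and the D-H-A angle measured at the hydrogen strictly exceeds 160°
(180° = linear).  The formation rate of a bond is the fraction of frames
in which it is present; bonds whose rates differ most between Case and
Control are the interaction-change candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import NoHydrogensError
from .trajectory_io import ConformationEnsemble, ResidueKey

logger = logging.getLogger(__name__)

DONOR_ACCEPTOR_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBondGeometryConfig:
    """Geometric hydrogen-bond criteria (strong N/O bonds)."""

    r_min: float = 1.5  # Angstrom, H...acceptor
    r_max: float = 2.2
    theta_min: float = 160.0  # degrees at the hydrogen, strict
    neighborhood_radius: float = 10.0
    covalent_dh_max: float = 1.2  # H belongs to nearest N/O within this

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError("need 0 < r_min < r_max")
        if not 0 < self.theta_min <= 180:
            raise ValueError("theta_min must be in (0, 180]")


#: bond identity portable across conditions: mutated residues are matched
#: by (chain, residue_number, atom_name), never by residue name
BondKey = tuple[str, int, str, str, int, str]


@dataclass
class HBondRecord:
    """One donor-H-acceptor triple with its per-frame presence."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    key: BondKey
    presence: np.ndarray  # (F,) bool

    @property
    def formation_rate(self) -> float:
        return float(self.presence.mean())


@dataclass
class HBondDiff:
    """Formation-rate difference of one bond between conditions."""

    key: BondKey
    rate_control: float
    rate_case: float
    large: bool = False

    @property
    def rate_delta(self) -> float:
        return self.rate_case - self.rate_control


def neighborhood_atoms(
    feature_generators: frozenset,
    ensemble: ConformationEnsemble,
    frame_index: int = 0,
    radius: float = 10.0,
) -> set[int]:
    """Atom ids of every residue whose CA lies within ``radius`` (closed
    bound) of ANY generator CA in the given frame; whole residues are
    included."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ca_index = ensemble.ca_index_by_residue()
    gen_idx = []
    for key in feature_generators:
        if key in ca_index:
            gen_idx.append(ca_index[key])
        else:
            logger.warning("generator residue %s has no CA; skipped", key)
    if not gen_idx:
        return set()
    coords = ensemble.frames[frame_index]
    all_keys = list(ca_index)
    ca_coords = coords[[ca_index[k] for k in all_keys]]
    d = cdist(ca_coords, coords[gen_idx])
    near = {k for k, row in zip(all_keys, d) if row.min() <= radius + 1e-9}
    return {
        a.atom_id for a in ensemble.atoms if a.residue_key in near
    }


def _atom_arrays(ensemble: ConformationEnsemble, candidate_atoms: set[int]):
    idx = [i for i, a in enumerate(ensemble.atoms) if a.atom_id in candidate_atoms]
    atoms = [ensemble.atoms[i] for i in idx]
    return np.array(idx, dtype=int), atoms


def detect_hbonds(
    ensemble: ConformationEnsemble,
    frame_index: int,
    candidate_atoms: set[int],
    cfg: HBondGeometryConfig = HBondGeometryConfig(),
) -> frozenset[tuple[int, int, int]]:
    """Hydrogen bonds present in one frame among the candidate atoms.

    Returns (donor_atom_id, hydrogen_atom_id, acceptor_atom_id) triples.
    Intra-residue bonds are excluded.  Raises if the ensemble carries no
    explicit hydrogens (a silent empty answer would be misleading).
    """
    if not any(a.element == "H" for a in ensemble.atoms):
        raise NoHydrogensError(
            "ensemble has no explicit hydrogens; cannot detect H-bonds"
        )
    idx, atoms = _atom_arrays(ensemble, candidate_atoms)
    coords = ensemble.frames[frame_index][idx]
    h_pos = [i for i, a in enumerate(atoms) if a.element == "H"]
    no_pos = [i for i, a in enumerate(atoms) if a.element in DONOR_ACCEPTOR_ELEMENTS]
    if not h_pos or not no_pos:
        return frozenset()
    dmat = cdist(coords[h_pos], coords[no_pos])

    bonds = set()
    for hi, drow in zip(h_pos, dmat):
        # covalent donor: nearest N/O within the covalent cutoff
        j = int(np.argmin(drow))
        if drow[j] > cfg.covalent_dh_max:
            continue
        di = no_pos[j]
        donor, hydrogen = atoms[di], atoms[hi]
        v_hd = coords[di] - coords[hi]
        for k, aj in enumerate(no_pos):
            acceptor = atoms[aj]
            if aj == di or acceptor.residue_key == donor.residue_key:
                continue
            r = drow[k]
            # closed distance bounds, strict angle bound; 1e-9 guards keep
            # exact-boundary geometries on the intended side of each test
            if not (cfg.r_min - 1e-9 <= r <= cfg.r_max + 1e-9):
                continue
            v_ha = coords[aj] - coords[hi]
            cosang = np.dot(v_hd, v_ha) / (
                np.linalg.norm(v_hd) * np.linalg.norm(v_ha)
            )
            theta = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if theta > cfg.theta_min + 1e-9:
                bonds.add((donor.atom_id, hydrogen.atom_id, acceptor.atom_id))
    return frozenset(bonds)


def _bond_key(ensemble: ConformationEnsemble, triple: tuple[int, int, int]) -> BondKey:
    by_id = {a.atom_id: a for a in ensemble.atoms}
    d, _, a = triple
    da, aa = by_id[d], by_id[a]
    return (
        da.chain_id, da.residue_number, da.atom_name,
        aa.chain_id, aa.residue_number, aa.atom_name,
    )


def formation_rates(
    ensemble: ConformationEnsemble,
    candidate_atoms: set[int],
    cfg: HBondGeometryConfig = HBondGeometryConfig(),
) -> list[HBondRecord]:
    """Per-bond presence across all frames; a bond appears in the output
    if it is detected in at least one frame."""
    F = ensemble.n_frames
    per_frame = [
        detect_hbonds(ensemble, t, candidate_atoms, cfg) for t in range(F)
    ]
    all_triples = sorted(set().union(*per_frame)) if per_frame else []
    records = []
    for triple in all_triples:
        presence = np.array([triple in s for s in per_frame], dtype=bool)
        records.append(
            HBondRecord(
                donor_atom=triple[0],
                hydrogen_atom=triple[1],
                acceptor_atom=triple[2],
                key=_bond_key(ensemble, triple),
                presence=presence,
            )
        )
    return records


def hbond_diff(
    control_rates: list[HBondRecord],
    case_rates: list[HBondRecord],
    top_k: int | None = 20,
    min_abs_delta: float | None = None,
    large_delta: float = 0.3,
) -> list[HBondDiff]:
    """Rank bonds by |rate_case - rate_control| descending (ties by bond
    key).  Bonds seen in only one condition get rate 0 in the other.
    ``large_delta`` only sets the ``large`` flag; ``min_abs_delta`` and
    ``top_k`` actually truncate the list."""
    ctl = {r.key: r.formation_rate for r in control_rates}
    cas = {r.key: r.formation_rate for r in case_rates}
    diffs = [
        HBondDiff(
            key=k,
            rate_control=ctl.get(k, 0.0),
            rate_case=cas.get(k, 0.0),
        )
        for k in set(ctl) | set(cas)
    ]
    for d in diffs:
        d.large = abs(d.rate_delta) >= large_delta
    diffs.sort(key=lambda d: (-abs(d.rate_delta), d.key))
    if min_abs_delta is not None:
        diffs = [d for d in diffs if abs(d.rate_delta) >= min_abs_delta]
    if top_k is not None:
        diffs = diffs[:top_k]
    return diffs


def hbond_diffs_to_dataframe(diffs: list[HBondDiff]):
    import pandas as pd

    rows = []
    for d in diffs:
        rows.append(
            {
                "donor_chain": d.key[0],
                "donor_resnum": d.key[1],
                "donor_atom": d.key[2],
                "acceptor_chain": d.key[3],
                "acceptor_resnum": d.key[4],
                "acceptor_atom": d.key[5],
                "rate_control": d.rate_control,
                "rate_case": d.rate_case,
                "rate_delta": d.rate_delta,
                "large": d.large,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "donor_chain", "donor_resnum", "donor_atom",
            "acceptor_chain", "acceptor_resnum", "acceptor_atom",
            "rate_control", "rate_case", "rate_delta", "large",
        ],
    )
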