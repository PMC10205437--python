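"""Reading, writing and subsetting conformational ensembles.

An ensemble is a fixed atom table plus an ``(F, A, 3)`` coordinate block in
Angstroms — the post-processed output of thermodynamic sampling (e.g. an MD
trajectory with solvent already stripped).  Multi-model PDB files serve as
both topology and trajectory; DCD/XTC trajectories are read against a PDB
topology via MDAnalysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    FormatError,
    IncompatibleEnsemblesError,
    InsufficientFramesError,
)

logger = logging.getLogger(__name__)

#: residue identity portable across Case/Control: (chain_id, residue_number)
ResidueKey = tuple[str, int]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (frame-invariant) topology."""

    atom_id: int
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number)


@dataclass
class ConformationEnsemble:
    """Frames x atoms x 3 coordinates with per-atom metadata.

    Invariants: every frame has the same atom count, all coordinates are
    finite, and there are at least two frames.
    """

    atoms: list[AtomRecord]
    frames: np.ndarray  # (F, A, 3) float64, Angstrom
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(
                f"frames must be (F, A, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InsufficientFramesError(
                f"ensemble needs >= 2 frames, got {self.frames.shape[0]}"
            )
        if self.frames.shape[1] != len(self.atoms):
            raise FormatError(
                f"atom table has {len(self.atoms)} atoms but frames have "
                f"{self.frames.shape[1]}"
            )
        if not np.isfinite(self.frames).all():
            raise FormatError("non-finite coordinates in ensemble")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate atom_id in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def ca_index_by_residue(self) -> dict[ResidueKey, int]:
        """Map residue_key -> array index of its alpha-carbon.

        First CA wins if duplicates slipped past altloc filtering.
        """
        out: dict[ResidueKey, int] = {}
        for i, a in enumerate(self.atoms):
            if a.atom_name == "CA" and a.residue_key not in out:
                out[a.residue_key] = i
        return out

    def residue_keys(self) -> list[ResidueKey]:
        """All residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)


@dataclass(frozen=True)
class CASelection:
    """A fixed subset of residues (by residue_key) whose CAs form the
    point cloud for persistent homology.

    Drawn once per Case/Control pair and shared by both conditions and all
    frames, so that generator sets are comparable across conditions.
    """

    residue_keys: tuple[ResidueKey, ...]
    ca_atom_ids: tuple[int, ...]  # resolved against the control ensemble
    seed: int = 0

    def __len__(self) -> int:
        return len(self.residue_keys)

    def coordinates(self, ensemble: ConformationEnsemble) -> np.ndarray:
        """Return the (F, n, 3) CA coordinate block of this selection."""
        index = ensemble.ca_index_by_residue()
        try:
            cols = [index[k] for k in self.residue_keys]
        except KeyError as e:  # pragma: no cover - guarded by select_cas
            raise IncompatibleEnsemblesError(
                f"ensemble lacks CA for residue {e.args[0]}"
            ) from None
        return ensemble.frames[:, cols, :]


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    # PDB convention: digits may prefix hydrogens (e.g. 1HB1)
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in "HDT":
        return "H"
    return stripped[0].upper()


def read_ensemble(
    path_topology: str,
    path_frames: str | None = None,
    condition_label: str = "",
) -> ConformationEnsemble:
    """Read an ensemble from a multi-model PDB, or a PDB topology plus a
    DCD/XTC trajectory.

    Alternate locations other than blank/"A" are dropped.  Coordinates are
    returned in Angstroms.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if path_frames is None:
                u = mda.Universe(path_topology)
            else:
                u = mda.Universe(path_topology, path_frames)
    except InsufficientFramesError:
        raise
    except Exception as e:
        raise FormatError(f"cannot read ensemble: {e}") from e

    ag = u.atoms
    if hasattr(ag, "altLocs"):
        keep = np.array([al in ("", " ", "A") for al in ag.altLocs])
        if not keep.all():
            logger.warning("dropping %d altloc atoms", (~keep).sum())
            ag = ag[keep]

    names = ag.names
    resids = ag.resids
    resnames = ag.resnames
    chains = (
        ag.chainIDs
        if hasattr(ag, "chainIDs")
        else np.array([s.strip() or "A" for s in ag.segids])
    )
    if hasattr(ag, "elements"):
        elements = [
            (e.strip() or _guess_element(n)).capitalize()
            for e, n in zip(ag.elements, names)
        ]
    else:
        elements = [_guess_element(n) for n in names]

    atoms = [
        AtomRecord(
            atom_id=i,
            atom_name=str(names[i]).strip(),
            element=elements[i],
            residue_number=int(resids[i]),
            residue_name=str(resnames[i]).strip(),
            chain_id=str(chains[i]).strip() or "A",
        )
        for i in range(len(ag))
    ]

    try:
        coords = np.array(
            [ag.positions.copy() for _ in u.trajectory], dtype=float
        )
    except Exception as e:
        raise FormatError(f"cannot read trajectory frames: {e}") from e
    if coords.shape[0] < 2:
        raise InsufficientFramesError(
            f"{path_topology}: ensemble has {coords.shape[0]} frame(s); "
            "need at least 2"
        )
    return ConformationEnsemble(atoms, coords, condition_label)


def write_ensemble(ensemble: ConformationEnsemble, path: str) -> None:
    """Write an ensemble to a multi-model PDB file (MODEL/ENDMDL records)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    atoms = ensemble.atoms
    # residue table in order of first appearance
    res_order: dict[ResidueKey, int] = {}
    for a in atoms:
        res_order.setdefault(a.residue_key, len(res_order))
    resindex = np.array([res_order[a.residue_key] for a in atoms])
    n_res = len(res_order)
    res_atoms: dict[ResidueKey, AtomRecord] = {}
    for a in atoms:
        res_atoms.setdefault(a.residue_key, a)

    u = mda.Universe.empty(
        len(atoms),
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.atom_name for a in atoms])
    u.add_TopologyAttr("elements", [a.element for a in atoms])
    u.add_TopologyAttr(
        "resnames", [res_atoms[k].residue_name for k in res_order]
    )
    u.add_TopologyAttr("resids", [k[1] for k in res_order])
    u.add_TopologyAttr("chainIDs", [a.chain_id for a in atoms])
    u.add_TopologyAttr("occupancies", np.ones(len(atoms)))
    u.add_TopologyAttr("tempfactors", np.zeros(len(atoms)))
    u.load_new(ensemble.frames.astype(np.float32), format=MemoryReader)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def select_cas(
    control: ConformationEnsemble,
    case: ConformationEnsemble,
    n_cas: int = 500,
    seed: int = 0,
) -> CASelection:
    """Pick the shared representative alpha-carbon subset.

    Residues are sampled without replacement by residue_key with a fixed
    seed; if there are no more than ``n_cas`` CAs, all are kept.  The same
    selection is applied to both conditions (sampling is keyed by residue,
    not by atom index, so it is invariant to atom ordering).
    """
    ctl_ca = control.ca_index_by_residue()
    case_ca = case.ca_index_by_residue()
    if set(ctl_ca) != set(case_ca):
        missing = set(ctl_ca) ^ set(case_ca)
        raise IncompatibleEnsemblesError(
            "Case and Control do not share CA residue keys; "
            f"{len(missing)} mismatched (e.g. {sorted(missing)[:3]})"
        )
    for ens, ca in ((control, ctl_ca), (case, case_ca)):
        n_missing = len(ens.residue_keys()) - len(ca)
        if n_missing:
            logger.warning(
                "%s: %d residue(s) without a CA excluded from sampling pool",
                ens.condition_label or "ensemble",
                n_missing,
            )
    pool = sorted(ctl_ca)
    if len(pool) > n_cas:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=n_cas, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    keys = tuple(pool)
    return CASelection(
        residue_keys=keys,
        ca_atom_ids=tuple(control.atoms[ctl_ca[k]].atom_id for k in keys),
        seed=seed,
    )
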