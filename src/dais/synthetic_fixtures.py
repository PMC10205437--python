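"""Self-contained synthetic ensembles with known topological structure.

These fixtures stand in for thermodynamic-sampling output: N frames of 3D
coordinates with per-atom residue metadata, small Gaussian thermal jitter,
an optional injected conformational change in the Case copy, and
explicit-hydrogen donor/acceptor geometries for H-bond tests.  They are
geometric constructions, not force-field dynamics: jitter is isotropic
and uncorrelated, and injected changes are prescribed displacements.

The basic scaffold is a ring of alpha-carbons (radius 10 Å by default)
carrying exactly one dimension-1 persistence feature.  A small
out-of-plane sine modulation (0.5 Å) keeps the cloud in general position
for the 3D alpha complex even at zero jitter.  The ``ring_opening``
injection places the injected residues on their own small ring far from
the main one and grows its radius after the onset frame, so the change is
localized to a feature whose generators are exactly the injected
residues; ``hinge`` dilates the injected residues about the centroid (a
global opening mode under which the main loop's death radius grows).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .trajectory_io import AtomRecord, ConformationEnsemble

logger = logging.getLogger(__name__)

_Z_WAVE = 0.5  # out-of-plane modulation amplitude, Angstrom


@dataclass(frozen=True)
class Injection:
    """A prescribed conformational change applied to the Case copy."""

    kind: str  # "ring_opening" | "hinge" | "none"
    residues: tuple[int, ...] = ()
    magnitude: float = 5.0  # Angstrom
    onset_frame: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ring_opening", "hinge", "none"):
            raise ConfigError(f"unknown injection kind {self.kind!r}")
        if self.kind != "none" and not self.residues:
            raise ConfigError("injection needs target residues")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic ensemble."""

    n_residues: int = 20
    n_frames: int = 100
    jitter_sd: float = 0.05  # Angstrom
    seed: int = 0
    ring_radius: float = 10.0
    injection: Injection | None = None
    with_hbond_atoms: bool = False

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if self.n_frames < 2:
            raise ConfigError("need at least 2 frames")
        if self.injection is not None and self.injection.kind != "none":
            bad = [
                r
                for r in self.injection.residues
                if not 1 <= r <= self.n_residues
            ]
            if bad:
                raise ConfigError(f"injection residues outside chain: {bad}")


def _ring_positions(n: int, radius: float, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    phi = 2 * np.pi * np.arange(n) / n
    pts = np.stack(
        [
            radius * np.cos(phi),
            radius * np.sin(phi),
            _Z_WAVE * np.sin(3 * phi),
        ],
        axis=1,
    )
    return pts + np.asarray(center)


def _build_atoms(
    resnums: list[int], with_hbond_atoms: bool
) -> tuple[list[AtomRecord], list[tuple[int, str]]]:
    """Atom table plus a (resnum, atom_name) layout list, one entry per
    atom, in the order coordinates will be laid out."""
    atoms: list[AtomRecord] = []
    layout: list[tuple[int, str]] = []
    names = (
        [("CA", "C"), ("N", "N"), ("H", "H"), ("O", "O")]
        if with_hbond_atoms
        else [("CA", "C")]
    )
    aid = 0
    for resnum in resnums:
        for name, element in names:
            atoms.append(
                AtomRecord(
                    atom_id=aid,
                    atom_name=name,
                    element=element,
                    residue_number=resnum,
                    residue_name="GLY",
                    chain_id="A",
                )
            )
            layout.append((resnum, name))
            aid += 1
    return atoms, layout


def _backbone_offsets(ca_base: np.ndarray, center: np.ndarray):
    """Deterministic local N/H/O placement around each base CA position.

    N sits outward of the ring (+0.3 Å in z), O mirrored (-0.3 Å in z),
    H extends from N along the chain tangent — neighbouring residues then
    offer H···O contacts near the 2 Å hydrogen-bond window.
    """
    n = len(ca_base)
    radial = ca_base - center
    radial[:, 2] = 0.0
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    tangent = np.roll(ca_base, -1, axis=0) - np.roll(ca_base, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    z = np.array([0.0, 0.0, 1.0])
    offs = {
        "CA": np.zeros((n, 3)),
        "N": 0.8 * radial + 0.3 * z,
        "H": 0.8 * radial + 0.3 * z + 1.0 * tangent,
        "O": 0.8 * radial - 0.3 * z,
    }
    return offs


def _progress(t: int, n_frames: int, onset: int) -> float:
    if t <= onset or n_frames - 1 <= onset:
        return 0.0
    return (t - onset) / (n_frames - 1 - onset)


def make_ring_ensemble(
    spec: FixtureSpec, condition_label: str = "control"
) -> ConformationEnsemble:
    """A jittered CA ring; one dimension-1 feature per frame is
    guaranteed for jitter_sd <= 0.5 Å at the default radius."""
    if spec.n_residues < 8:
        raise ConfigError("ring fixture needs >= 8 residues")
    control, _ = make_case_pair(
        FixtureSpec(
            n_residues=spec.n_residues,
            n_frames=spec.n_frames,
            jitter_sd=spec.jitter_sd,
            seed=spec.seed,
            ring_radius=spec.ring_radius,
            injection=None,
            with_hbond_atoms=spec.with_hbond_atoms,
        )
    )
    control.condition_label = condition_label
    return control


def make_case_pair(
    spec: FixtureSpec,
) -> tuple[ConformationEnsemble, ConformationEnsemble]:
    """Control and Case ensembles sharing the first frame.

    Both conditions see the identical jitter stream, so without an
    injection the pair is bit-identical; with one, Case additionally
    drifts per the injection after its onset frame (zero displacement at
    frame 0 keeps the initial conformations equal).
    """
    if spec.n_residues < 8:
        raise ConfigError("ring fixture needs >= 8 residues")
    inj = spec.injection
    injected = set(inj.residues) if inj and inj.kind != "none" else set()
    main_res = [r for r in range(1, spec.n_residues + 1) if r not in injected]
    inj_res = sorted(injected)

    # base geometry: main ring at the origin; ring_opening puts the
    # injected residues on their own small ring well outside the H-bond
    # neighborhood of the main one
    base = np.zeros((spec.n_residues, 3))
    centers = np.zeros((spec.n_residues, 3))
    main_center = np.zeros(3)
    base[[r - 1 for r in main_res]] = _ring_positions(
        len(main_res), spec.ring_radius, main_center
    )
    if inj_res and inj.kind == "ring_opening":
        r2 = max(2.5, len(inj_res) * 3.0 / (2 * np.pi))
        c2 = np.array([spec.ring_radius + r2 + 15.0, 0.0, 0.0])
        base[[r - 1 for r in inj_res]] = _ring_positions(len(inj_res), r2, c2)
        centers[[r - 1 for r in inj_res]] = c2
    elif inj_res:  # hinge: injected residues stay on the main ring
        keep = [r for r in range(1, spec.n_residues + 1)]
        base = _ring_positions(spec.n_residues, spec.ring_radius, main_center)
        centers[:] = base.mean(axis=0)

    atoms, layout = _build_atoms(
        list(range(1, spec.n_residues + 1)), spec.with_hbond_atoms
    )
    offs = _backbone_offsets(base, main_center) if spec.with_hbond_atoms else None

    def atom_base(resnum: int, name: str) -> np.ndarray:
        p = base[resnum - 1]
        if offs is not None:
            return p + offs[name][resnum - 1]
        return p

    A = len(layout)
    rng = np.random.default_rng(spec.seed)
    jitter = (
        rng.normal(0.0, spec.jitter_sd, size=(spec.n_frames, A, 3))
        if spec.jitter_sd > 0
        else np.zeros((spec.n_frames, A, 3))
    )
    base_coords = np.array([atom_base(rn, nm) for rn, nm in layout])
    control_frames = base_coords[None, :, :] + jitter

    case_frames = control_frames.copy()
    if inj_res:
        res_of_atom = np.array([rn for rn, _ in layout])
        mask = np.isin(res_of_atom, inj_res)
        for t in range(spec.n_frames):
            g = _progress(t, spec.n_frames, inj.onset_frame)
            if g == 0.0:
                continue
            if inj.kind == "ring_opening":
                direction = base_coords - centers[res_of_atom - 1]
                direction[:, 2] = 0.0
                norms = np.linalg.norm(direction, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                disp = direction / norms * (g * inj.magnitude)
            else:  # hinge: radial dilation about the centroid
                direction = base_coords - centers[res_of_atom - 1]
                norms = np.linalg.norm(direction, axis=1, keepdims=True)
                norms[norms == 0] = 1.0
                disp = direction / norms * (g * inj.magnitude)
            case_frames[t, mask] += disp[mask]

    control = ConformationEnsemble(atoms, control_frames, "control")
    case = ConformationEnsemble(list(atoms), case_frames, "case")
    return control, case


def make_hbond_system(
    r_schedule, theta_schedule_deg, condition_label: str = "control"
) -> ConformationEnsemble:
    """A two-residue donor/acceptor system realizing per-frame H-bond
    geometry exactly.

    Residue 1 carries N-H (donor, N at the origin, H at 1.0 Å along +x);
    residue 2 carries the acceptor O placed so that the H···O distance is
    ``r_schedule[t]`` and the N-H···O angle at the hydrogen is
    ``theta_schedule_deg[t]`` (180° = linear).
    """
    r = np.asarray(r_schedule, dtype=float)
    theta = np.asarray(theta_schedule_deg, dtype=float)
    if r.shape != theta.shape or r.ndim != 1:
        raise ConfigError("r and theta schedules must be equal-length 1D")
    if len(r) < 2:
        raise ConfigError("need at least 2 frames")
    if not np.isfinite(r).all() or (r <= 0).any():
        raise ConfigError("distances must be finite and positive")
    if ((theta <= 0) | (theta > 180)).any():
        raise ConfigError("angles must be in (0, 180] degrees")

    N = np.array([0.0, 0.0, 0.0])
    H = np.array([1.0, 0.0, 0.0])
    ca1 = np.array([-1.5, 0.0, 0.0])
    th = np.radians(theta)
    # angle at H between H->N (-x) and H->O equals theta
    O = H + np.stack(
        [-r * np.cos(th), r * np.sin(th), np.zeros_like(r)], axis=1
    )
    ca2 = O + np.array([0.0, 0.0, 1.5])

    specs = [
        ("CA", "C", 1), ("N", "N", 1), ("H", "H", 1),
        ("CA", "C", 2), ("O", "O", 2),
    ]
    atoms = [
        AtomRecord(i, name, element, resnum, "GLY", "A")
        for i, (name, element, resnum) in enumerate(specs)
    ]
    F = len(r)
    frames = np.empty((F, len(atoms), 3))
    for t in range(F):
        frames[t, 0] = ca1
        frames[t, 1] = N
        frames[t, 2] = H
        frames[t, 3] = ca2[t]
        frames[t, 4] = O[t]
    return ConformationEnsemble(atoms, frames, condition_label)
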