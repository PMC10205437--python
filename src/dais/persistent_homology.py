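"""Per-frame persistence diagrams with generator alpha-carbon sets.

The point cloud of selected alpha-carbons is filtered either by the alpha
complex (default; exact and fast for 3D via the Delaunay triangulation) or
by the Vietoris-Rips complex (full enumeration; exponential, retained for
small clouds and cross-checks).  All births and deaths are reported as
sphere RADII in Angstroms: Rips edge lengths are halved, alpha squared
radii are square-rooted.  This convention is load-bearing — the polar
change scoring consumes these numbers.

Every feature carries the set of input points (as residue keys) generating
it: the representative cycle of the class at its birth simplex, read off
the V matrix of the R = DV column reduction over Z/2.  On a ring of CAs
this is the full loop, which is what generator-overlap tracking needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigError, DegenerateInputError
from .trajectory_io import CASelection, ConformationEnsemble

logger = logging.getLogger(__name__)

_GABRIEL_EPS = 1e-9
_MAX_RIPS_SIMPLICES = 2_000_000


@dataclass(frozen=True)
class PersistenceFeature:
    """One point of a persistence diagram plus its generating CA set."""

    frame_index: int
    dimension: int
    birth: float  # radius, Angstrom
    death: float  # radius, Angstrom; math.inf for essential classes
    generators: frozenset
    feature_id: int

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.death)


@dataclass
class Diagram:
    """All persistence features of one frame."""

    frame_index: int
    features: list[PersistenceFeature] = field(default_factory=list)

    def in_dimension(self, dim: int) -> list[PersistenceFeature]:
        return [f for f in self.features if f.dimension == dim]


# --------------------------------------------------------------------------
# geometry helpers


def _circumsphere(pts: np.ndarray) -> tuple[np.ndarray, float]:
    """Circumcenter/radius of a k-simplex (k+1 points) within its affine
    hull, via the Gram-matrix linear system."""
    p0 = pts[0]
    d = pts[1:] - p0
    if len(d) == 0:
        return p0.copy(), 0.0
    G = d @ d.T
    h = 0.5 * np.einsum("ij,ij->i", d, d)
    try:
        y = np.linalg.solve(G, h)
    except np.linalg.LinAlgError:
        raise DegenerateInputError("degenerate simplex (collinear/coplanar)")
    c = p0 + y @ d
    return c, float(np.linalg.norm(c - p0))


def _is_gabriel(
    points: np.ndarray, simplex: tuple[int, ...], center: np.ndarray, r: float
) -> bool:
    """True iff the diametral sphere of the simplex contains no other
    input point strictly inside."""
    d2 = np.einsum("ij,ij->i", points - center, points - center)
    d2[list(simplex)] = np.inf
    return bool(d2.min() >= r * r - _GABRIEL_EPS * max(1.0, r * r))


# --------------------------------------------------------------------------
# filtrations: lists of (value, vertex-tuple), sorted faces-before-cofaces


def _alpha_filtration(points: np.ndarray) -> list[tuple[float, tuple[int, ...]]]:
    """Alpha filtration; exact for clouds in general position, falling
    back to a joggled (QJ, ~1e-10 Å perturbation) triangulation for
    degenerate inputs such as exactly symmetric fixtures."""
    try:
        return _alpha_filtration_opts(points, "Qbb Qc")
    except (QhullError, DegenerateInputError):
        pass
    try:
        return _alpha_filtration_opts(points, "Qbb Qc QJ")
    except QhullError as e:
        raise DegenerateInputError(
            f"Delaunay triangulation failed (degenerate cloud?): {e}"
        ) from e


def _alpha_filtration_opts(
    points: np.ndarray, qhull_options: str
) -> list[tuple[float, tuple[int, ...]]]:
    tri = Delaunay(points, qhull_options=qhull_options)

    values: dict[tuple[int, ...], float] = {}
    tri_cofaces: dict[tuple[int, ...], list] = {}
    edge_cofaces: dict[tuple[int, ...], list] = {}

    for s in tri.simplices:
        tet = tuple(sorted(int(v) for v in s))
        _, r = _circumsphere(points[list(tet)])
        values[tet] = r
        for f in combinations(tet, 3):
            tri_cofaces.setdefault(f, []).append(tet)

    for t, cofs in tri_cofaces.items():
        c, r = _circumsphere(points[list(t)])
        own = r if _is_gabriel(points, t, c, r) else math.inf
        values[t] = min([own] + [values[cf] for cf in cofs])
        for e in combinations(t, 2):
            edge_cofaces.setdefault(e, []).append(t)

    for e, cofs in edge_cofaces.items():
        c = points[list(e)].mean(axis=0)
        r = 0.5 * float(np.linalg.norm(points[e[0]] - points[e[1]]))
        own = r if _is_gabriel(points, e, c, r) else math.inf
        values[e] = min([own] + [values[cf] for cf in cofs])

    filtration = [(0.0, (v,)) for v in range(len(points))]
    filtration += [(val, s) for s, val in values.items()]
    filtration.sort(key=lambda vs: (vs[0], len(vs[1]), vs[1]))
    return filtration


def _rips_filtration(
    points: np.ndarray, max_dimension: int
) -> list[tuple[float, tuple[int, ...]]]:
    n = len(points)
    total = sum(math.comb(n, k) for k in range(1, max_dimension + 3))
    if total > _MAX_RIPS_SIMPLICES:
        raise ConfigError(
            f"Rips complex on {n} points up to dim {max_dimension + 1} has "
            f"{total} simplices; use the alpha filtration"
        )
    D = squareform(pdist(points))
    filtration: list[tuple[float, tuple[int, ...]]] = [
        (0.0, (v,)) for v in range(n)
    ]
    for size in range(2, max_dimension + 3):
        for s in combinations(range(n), size):
            val = max(D[i, j] for i, j in combinations(s, 2)) / 2.0
            filtration.append((val, s))
    filtration.sort(key=lambda vs: (vs[0], len(vs[1]), vs[1]))
    return filtration


# --------------------------------------------------------------------------
# persistence via column reduction with representative cycles


def _reduce(filtration):
    """Z/2 column reduction of the boundary matrix, maintaining V with
    R = D V so that birth simplices carry an explicit representative cycle.

    Returns (pairs, essential, V) where pairs is a list of
    (birth_col, death_col) and essential a list of unpaired creator columns.
    """
    index = {s: i for i, (_, s) in enumerate(filtration)}
    R: list[set] = []
    V: list[set] = []
    low_inv: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []
    for j, (_, s) in enumerate(filtration):
        if len(s) == 1:
            col: set = set()
        else:
            col = {index[f] for f in combinations(s, len(s) - 1)}
        v = {j}
        while col:
            low = max(col)
            k = low_inv.get(low)
            if k is None:
                break
            col ^= R[k]
            v ^= V[k]
        R.append(col)
        V.append(v)
        if col:
            low_inv[max(col)] = j
            pairs.append((max(col), j))
    births = {b for b, _ in pairs}
    essential = [
        i for i in range(len(filtration)) if not R[i] and i not in births
    ]
    return pairs, essential, V


def _dedupe_points(points: np.ndarray, labels: Sequence[Hashable]):
    uniq, first = np.unique(points, axis=0, return_index=True)
    if len(uniq) != len(points):
        logger.warning(
            "deduplicated %d coincident point(s)", len(points) - len(uniq)
        )
        keep = sorted(first)
        return points[keep], [labels[i] for i in keep]
    return points, list(labels)


def compute_diagram(
    points: np.ndarray,
    max_dimension: int = 2,
    filtration: str = "alpha",
    labels: Sequence[Hashable] | None = None,
    frame_index: int = 0,
) -> Diagram:
    """Persistence diagram of one frame's CA point cloud.

    ``labels`` maps point indices to hashable identifiers (residue keys in
    pipeline use); generator sets are expressed in those labels.  The
    essential dimension-0 class is retained with ``death = inf``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DegenerateInputError(f"expected (n, 3) points, got {points.shape}")
    if max_dimension > 2 or max_dimension < 0:
        raise ConfigError("max_dimension must be 0, 1 or 2")
    if labels is None:
        labels = list(range(len(points)))
    if len(labels) != len(points):
        raise ConfigError("labels length must equal point count")
    if len(points) < 2:
        raise DegenerateInputError("need at least 2 points")
    points, labels = _dedupe_points(points, labels)

    if filtration == "alpha":
        if len(points) < 4:
            raise DegenerateInputError(
                "alpha filtration in 3D needs >= 4 points; use rips"
            )
        filt = _alpha_filtration(points)
    elif filtration == "rips":
        filt = _rips_filtration(points, max_dimension)
    else:
        raise ConfigError(f"unknown filtration {filtration!r}")

    pairs, essential, V = _reduce(filt)

    features: list[PersistenceFeature] = []

    def _generators(col: int) -> frozenset:
        verts: set = set()
        for k in V[col]:
            verts.update(filt[k][1])
        return frozenset(labels[v] for v in verts)

    for b, d in pairs:
        dim = len(filt[b][1]) - 1
        if dim > max_dimension:
            continue
        features.append(
            PersistenceFeature(
                frame_index=frame_index,
                dimension=dim,
                birth=filt[b][0],
                death=filt[d][0],
                generators=_generators(b),
                feature_id=0,
            )
        )
    for i in essential:
        dim = len(filt[i][1]) - 1
        if dim > max_dimension:
            continue
        features.append(
            PersistenceFeature(
                frame_index=frame_index,
                dimension=dim,
                birth=filt[i][0],
                death=math.inf,
                generators=_generators(i),
                feature_id=0,
            )
        )

    features.sort(key=lambda f: (f.dimension, f.birth, f.death, sorted(map(repr, f.generators))))
    features = [
        PersistenceFeature(
            f.frame_index, f.dimension, f.birth, f.death, f.generators, i
        )
        for i, f in enumerate(features)
    ]
    return Diagram(frame_index=frame_index, features=features)


def compute_diagram_series(
    ensemble: ConformationEnsemble,
    selection: CASelection,
    max_dimension: int = 2,
    filtration: str = "alpha",
) -> list[Diagram]:
    """One diagram per frame on the selected CAs, frame_index ascending."""
    coords = selection.coordinates(ensemble)
    labels = list(selection.residue_keys)
    diagrams = []
    for t in range(coords.shape[0]):
        try:
            diagrams.append(
                compute_diagram(
                    coords[t],
                    max_dimension=max_dimension,
                    filtration=filtration,
                    labels=labels,
                    frame_index=t,
                )
            )
        except DegenerateInputError as e:
            raise DegenerateInputError(f"frame {t}: {e}") from e
    return diagrams


def diagrams_to_dataframe(diagrams: list[Diagram]):
    """Flatten diagrams to a table (frame, dim, birth, death, generators)."""
    import pandas as pd

    rows = []
    for dg in diagrams:
        for f in dg.features:
            rows.append(
                {
                    "frame": dg.frame_index,
                    "feature_id": f.feature_id,
                    "dimension": f.dimension,
                    "birth": f.birth,
                    "death": f.death,
                    "generators": ";".join(
                        f"{c}:{r}" for c, r in sorted(f.generators)
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["frame", "feature_id", "dimension", "birth", "death", "generators"],
    )
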