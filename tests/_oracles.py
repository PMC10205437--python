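"""Independent brute-force oracles for cross-checking the main engine.

Everything here enumerates the FULL simplicial complex on a small point
cloud and reduces the boundary matrix directly, with columns stored as
Python integers (bit k set = facet k present, Z/2 arithmetic via XOR) —
deliberately a different data layout and code path from the package's
reduction engine.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform


def _min_enclosing_radius(pts: np.ndarray) -> float:
    """Radius of the smallest sphere enclosing all points: the smallest
    circumsphere of any subset that covers the rest (exhaustive; fine for
    the <= 5-point simplices used here)."""
    n = len(pts)
    if n == 1:
        return 0.0
    best = math.inf
    for k in range(2, min(n, 4) + 1):
        for sub in combinations(range(n), k):
            c, r = _circumsphere_oracle(pts[list(sub)])
            if c is None:
                continue
            if (np.linalg.norm(pts - c, axis=1) <= r + 1e-9).all():
                best = min(best, r)
    return best


def _circumsphere_oracle(pts: np.ndarray):
    p0 = pts[0]
    d = pts[1:] - p0
    G = d @ d.T
    if abs(np.linalg.det(G)) < 1e-12:
        return None, None
    y = np.linalg.solve(G, 0.5 * np.einsum("ij,ij->i", d, d))
    c = p0 + y @ d
    return c, float(np.linalg.norm(c - p0))


def full_complex_persistence(
    points: np.ndarray, max_dim: int = 2, flavor: str = "rips"
) -> list[tuple[int, float, float]]:
    """(dim, birth, death) multiset of the full Rips or Cech complex,
    deaths of essential classes reported as math.inf."""
    n = len(points)
    D = squareform(pdist(points))
    simplices: list[tuple[float, tuple[int, ...]]] = [(0.0, (v,)) for v in range(n)]
    for size in range(2, max_dim + 3):
        for s in combinations(range(n), size):
            if flavor == "rips":
                val = max(D[i, j] for i, j in combinations(s, 2)) / 2.0
            else:  # cech: min enclosing ball radius
                val = _min_enclosing_radius(points[list(s)])
            simplices.append((val, s))
    simplices.sort(key=lambda vs: (vs[0], len(vs[1]), vs[1]))

    index = {s: i for i, (_, s) in enumerate(simplices)}
    columns: list[int] = []
    for _, s in simplices:
        col = 0
        if len(s) > 1:
            for f in combinations(s, len(s) - 1):
                col |= 1 << index[f]
        columns.append(col)

    low_to_col: dict[int, int] = {}
    pairs = []
    for j in range(len(columns)):
        col = columns[j]
        while col:
            low = col.bit_length() - 1
            if low not in low_to_col:
                break
            col ^= columns[low_to_col[low]]
        columns[j] = col
        if col:
            low = col.bit_length() - 1
            low_to_col[low] = j
            pairs.append((low, j))

    births = {b for b, _ in pairs}
    out = []
    for b, d in pairs:
        dim = len(simplices[b][1]) - 1
        if dim <= max_dim:
            out.append((dim, simplices[b][0], simplices[d][0]))
    for i, col in enumerate(columns):
        if col == 0 and i not in births:
            dim = len(simplices[i][1]) - 1
            if dim <= max_dim:
                out.append((dim, simplices[i][0], math.inf))
    return sorted(out)


def bottleneck_leq(
    diag_a: list[tuple[float, float]],
    diag_b: list[tuple[float, float]],
    bound: float,
) -> bool:
    """True if the two diagrams (one homology dimension, finite points)
    admit a matching moving no point by more than ``bound`` in max-norm,
    with unmatched points allowed within ``bound`` of the diagonal.
    Exhaustive bipartite feasibility via Hopcroft-Karp-free augmenting
    search — fine at fixture sizes."""

    def diag_ok(p):  # distance to diagonal in max-norm
        return (p[1] - p[0]) / 2.0 <= bound + 1e-12

    a = [p for p in diag_a if not diag_ok(p)]
    b = [p for p in diag_b if not diag_ok(p)]
    adj = [
        [
            j
            for j, q in enumerate(b)
            if max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= bound + 1e-12
        ]
        for p in a
    ]
    match_b = [-1] * len(b)

    def augment(i, seen):
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_b[j] == -1 or augment(match_b[j], seen):
                match_b[j] = i
                return True
        return False

    return all(augment(i, set()) for i in range(len(a))) and len(a) <= len(b)


def brute_force_hbonds(
    coords: np.ndarray,
    elements: list[str],
    residues: list[int],
    r_min: float = 1.5,
    r_max: float = 2.2,
    theta_min: float = 160.0,
    covalent_max: float = 1.2,
) -> set[tuple[int, int, int]]:
    """All-triples O(n^3) hydrogen-bond detection on one frame."""
    n = len(coords)
    bonds = set()
    for h in range(n):
        if elements[h] != "H":
            continue
        # nearest N/O is the covalent donor
        donor, dbest = None, math.inf
        for d in range(n):
            if elements[d] in ("N", "O"):
                dist = float(np.linalg.norm(coords[h] - coords[d]))
                if dist < dbest:
                    donor, dbest = d, dist
        if donor is None or dbest > covalent_max:
            continue
        for a in range(n):
            if a == donor or elements[a] not in ("N", "O"):
                continue
            if residues[a] == residues[donor]:
                continue
            r = float(np.linalg.norm(coords[h] - coords[a]))
            if not (r_min - 1e-9 <= r <= r_max + 1e-9):
                continue
            v1 = coords[donor] - coords[h]
            v2 = coords[a] - coords[h]
            cosang = float(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            )
            theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if theta > theta_min + 1e-9:
                bonds.add((donor, h, a))
    return bonds
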