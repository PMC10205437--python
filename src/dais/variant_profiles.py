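"""Diversity profiling of structural-change patterns across many variants.

Each variant analyzed against the common Control yields a set of retained
change features; counting, per residue position, how many of those
features include the residue in their generator set gives a
variants x residues change-count matrix.  The matrix is embedded in 2D
with UMAP for visualization and factorized with non-negative matrix
factorization (NMF); the NMF rank is chosen from the consensus-clustering
cophenetic correlation curve (largest rank before its first substantial
drop).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .change_scoring import STATUS_RETAINED, ChangeScore
from .errors import ConfigError, DegenerateInputError, IncompatibleEnsemblesError

logger = logging.getLogger(__name__)


def count_changed_residues(
    scores_by_variant: dict[str, list[ChangeScore]],
    residues: list[int] | None = None,
) -> pd.DataFrame:
    """Variants x residues matrix of change counts.

    Cell (v, res) = number of retained change features of variant v whose
    generator set contains residue ``res`` (keyed by residue number; all
    variants must share the Control's numbering).
    """
    seen: set[int] = set()
    for scores in scores_by_variant.values():
        for s in scores:
            if s.status == STATUS_RETAINED:
                seen.update(r for _, r in s.generators)
    if residues is None:
        residues = sorted(seen)
    else:
        extra = seen - set(residues)
        if extra:
            raise IncompatibleEnsemblesError(
                f"variant features reference residues outside the shared "
                f"universe: {sorted(extra)[:5]}"
            )
    mat = pd.DataFrame(
        0, index=list(scores_by_variant), columns=residues, dtype=int
    )
    for variant, scores in scores_by_variant.items():
        for s in scores:
            if s.status != STATUS_RETAINED:
                continue
            for _, res in s.generators:
                mat.loc[variant, res] += 1
    return mat


def embed_umap(
    matrix: pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> pd.DataFrame:
    """2D UMAP embedding of variant change-count profiles (deterministic
    for a fixed seed)."""
    if len(matrix) < 4:
        raise ConfigError(f"need >= 4 variants to embed, got {len(matrix)}")
    if len(matrix) < n_neighbors:
        raise ConfigError(
            f"n_neighbors={n_neighbors} exceeds variant count {len(matrix)}"
        )
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        coords = reducer.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=matrix.index, columns=["umap1", "umap2"])


@dataclass
class NMFResult:
    """Chosen-rank NMF factors plus the rank-selection diagnostics."""

    basis: pd.DataFrame  # components x residues (H)
    coefficients: pd.DataFrame  # variants x components (W)
    rank: int
    cophenetic_by_rank: dict[int, float]
    reconstruction_error_by_rank: dict[int, float]


def _consensus_cophenetic(X: np.ndarray, rank: int, n_restarts: int, seed: int):
    """Consensus clustering over NMF restarts: variants co-cluster when
    their dominant coefficient component agrees; returns the cophenetic
    correlation of the consensus matrix and the best-reconstruction fit."""
    n = X.shape[0]
    consensus = np.zeros((n, n))
    best = None
    for r in range(n_restarts):
        model = NMF(
            n_components=rank,
            init="random",
            random_state=seed + 1000 * rank + r,
            max_iter=500,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(X)
        labels = W.argmax(axis=1)
        consensus += labels[:, None] == labels[None, :]
        if best is None or model.reconstruction_err_ < best[0]:
            best = (model.reconstruction_err_, W, model.components_)
    consensus /= n_restarts
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0] if len(condensed) else 0.0):
        coph = 1.0  # perfectly stable (or degenerate) consensus
    else:
        Z = average(condensed)
        coph = float(cophenet(Z, condensed)[0])
    return coph, best


def nmf_decompose(
    matrix: pd.DataFrame,
    candidate_ranks: list[int] | range = range(2, 7),
    n_restarts: int = 20,
    seed: int = 0,
    cophenetic_drop: float = 0.05,
) -> NMFResult:
    """NMF with cophenetic-based rank selection.

    For each candidate rank, ``n_restarts`` random-init factorizations
    are consensus-clustered; the selected rank is the largest before the
    first drop of the cophenetic coefficient exceeding
    ``cophenetic_drop``, or the best-cophenetic rank if the curve never
    drops.  Factors come from the best-reconstruction restart at the
    selected rank.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise DegenerateInputError("count matrix must be nonnegative")
    if not X.any():
        raise DegenerateInputError("all-zero count matrix")
    ranks = sorted(set(int(r) for r in candidate_ranks))
    if not ranks or ranks[0] < 1:
        raise ConfigError("candidate ranks must be positive")
    if ranks[-1] > min(X.shape):
        raise ConfigError(
            f"max rank {ranks[-1]} exceeds matrix min dimension {min(X.shape)}"
        )

    coph_by_rank: dict[int, float] = {}
    err_by_rank: dict[int, float] = {}
    fits: dict[int, tuple] = {}
    for k in ranks:
        coph, best = _consensus_cophenetic(X, k, n_restarts, seed)
        coph_by_rank[k] = coph
        err_by_rank[k] = float(best[0])
        fits[k] = best

    selected = None
    for a, b in zip(ranks, ranks[1:]):
        if coph_by_rank[b] < coph_by_rank[a] - cophenetic_drop:
            selected = a
            break
    if selected is None:
        # no substantial drop: take the largest rank on the maximal
        # plateau (rank grows while the consensus stays maximally stable)
        best = max(coph_by_rank.values())
        selected = max(k for k in ranks if coph_by_rank[k] == best)

    _, W, H = fits[selected]
    comp_names = [f"component_{i + 1}" for i in range(selected)]
    return NMFResult(
        basis=pd.DataFrame(H, index=comp_names, columns=matrix.columns),
        coefficients=pd.DataFrame(W, index=matrix.index, columns=comp_names),
        rank=selected,
        cophenetic_by_rank=coph_by_rank,
        reconstruction_error_by_rank=err_by_rank,
    )
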