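"""Scoring structural change of paired Control/Case feature tracks.

Each diagram point (Birth, Death) is re-plotted as (Birth, Death - Birth)
and transformed to polar coordinates; the distance component

    r = sqrt(Birth^2 + (Death - Birth)^2)

is followed over time, normalized by its initial value (rate of change),
smoothed, and differenced between conditions:

    Δr_t = r̄_case(t) - r̄_control(t)

The importance-of-change (ID) score of a pair is |Σ_t Δr_t| over the
frames where both tracks exist.  A two-stage percentile filter then
excludes outliers (1st percentile or below, 99th or above) and small
changes (5th-95th percentile); only the (1, 5) and (95, 99) bands are
retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigError, DegenerateTrackError, NotScoreableError
from .feature_tracking import FeatureTrack, TrackPair

logger = logging.getLogger(__name__)

STATUS_RETAINED = "retained"
STATUS_OUTLIER = "excluded_outlier"
STATUS_SMALL = "excluded_small"
STATUS_UNSTRUCTURED = "excluded_unstructured"

_R_FIRST_TOL = 1e-6


@dataclass
class PolarSeries:
    """Polar-distance time series of one track.

    theta is computed and stored for completeness but plays no role in
    scoring (only the distance component is scored).
    """

    r: np.ndarray
    ratio: np.ndarray
    smoothed: np.ndarray
    theta: np.ndarray


@dataclass
class ChangeScore:
    """ID score of one Control/Case track pair plus its filter status."""

    pair_id: int
    dimension: int
    delta_r: np.ndarray
    id_score: float
    generators: frozenset = frozenset()
    percentile: float | None = None
    status: str = STATUS_RETAINED


def to_polar_distance(birth: float, death: float) -> float:
    """r = sqrt(birth^2 + (death - birth)^2); infinite death not scoreable."""
    if math.isinf(death):
        raise NotScoreableError("infinite death has no polar distance")
    if death < birth or birth < 0:
        raise NotScoreableError(f"invalid diagram point ({birth}, {death})")
    return math.hypot(birth, death - birth)


def smooth(series, window: int):
    """Centered moving average with shrinking windows at the edges.

    window must be odd, >= 1 and <= len(series); window=1 is identity.
    """
    x = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 1, got {window}")
    if window > len(x):
        raise ConfigError(
            f"window {window} exceeds series length {len(x)}"
        )
    h = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo = max(0, i - h)
        hi = min(len(x), i + h + 1)
        out[i] = x[lo:hi].mean()
    return out


def _clamped_window(window: int, length: int) -> int:
    w = min(window, length)
    if w % 2 == 0:
        w -= 1
    return max(w, 1)


def ratio_series(track: FeatureTrack, window: int = 11) -> PolarSeries:
    """Polar distances of a track, normalized by the initial distance and
    smoothed.  The window is clamped to the track length (next lower odd)."""
    if len(track) < 2:
        raise DegenerateTrackError("track shorter than 2 frames")
    births = np.array([f.birth for _, f in track.entries])
    deaths = np.array([f.death for _, f in track.entries])
    r = np.array([to_polar_distance(b, d) for b, d in zip(births, deaths)])
    theta = np.arctan2(deaths - births, births)
    if r[0] <= _R_FIRST_TOL:
        raise DegenerateTrackError(
            f"initial polar distance {r[0]:.2e} below tolerance"
        )
    ratio = r / r[0]
    smoothed = smooth(ratio, _clamped_window(window, len(ratio)))
    return PolarSeries(r=r, ratio=ratio, smoothed=smoothed, theta=theta)


def id_score(
    pair: TrackPair, window: int = 11, sum_abs: bool = False
) -> ChangeScore:
    """ID score |Σ_t Δr_t| of a track pair over its overlap frames.

    ``sum_abs=True`` switches to Σ_t |Δr_t| (no sign cancellation); the
    plain absolute sum is the default.
    """
    if len(pair.overlap_frames) < 2:
        raise NotScoreableError(
            f"pair {pair.pair_id} has {len(pair.overlap_frames)} overlap frame(s)"
        )
    ctl = ratio_series(pair.control_track, window)
    cas = ratio_series(pair.case_track, window)
    ctl_at = dict(zip(pair.control_track.frames(), ctl.smoothed))
    cas_at = dict(zip(pair.case_track.frames(), cas.smoothed))
    delta = np.array([cas_at[t] - ctl_at[t] for t in pair.overlap_frames])
    score = float(np.sum(np.abs(delta))) if sum_abs else float(abs(delta.sum()))
    return ChangeScore(
        pair_id=pair.pair_id,
        dimension=pair.dimension,
        delta_r=delta,
        id_score=score,
        generators=pair.control_track.anchor_generators,
    )


def score_pairs(
    pairs: list[TrackPair], window: int = 11, sum_abs: bool = False
) -> list[ChangeScore]:
    """Score every scoreable pair; pairs without enough overlap are skipped
    with a log message."""
    out = []
    for p in pairs:
        try:
            out.append(id_score(p, window=window, sum_abs=sum_abs))
        except (NotScoreableError, DegenerateTrackError) as e:
            logger.warning("pair %d not scored: %s", p.pair_id, e)
    return out


def percentile_filter(
    scores: list[ChangeScore],
    outlier_low: float = 1.0,
    small_low: float = 5.0,
    small_high: float = 95.0,
    outlier_high: float = 99.0,
    min_scores: int = 20,
) -> list[ChangeScore]:
    """Two-stage percentile exclusion on the ID-score distribution.

    Percentile rank is the linear-interpolation definition
    (rank - 1) / (n - 1) * 100 with average ranks for ties.  Scores at or
    below the 1st / at or above the 99th percentile are excluded as
    outliers; the closed 5th-95th band is excluded as small; the open
    bands (1, 5) and (95, 99) are retained.  With fewer than
    ``min_scores`` scores all are retained (percentiles meaningless).
    """
    if not scores:
        return []
    if len(scores) < min_scores:
        logger.warning(
            "only %d scores; percentile filter skipped, all retained",
            len(scores),
        )
        for s in scores:
            s.percentile = None
            s.status = STATUS_RETAINED
        return scores
    vals = np.array([s.id_score for s in scores])
    ranks = rankdata(vals, method="average")
    pct = (ranks - 1) / (len(vals) - 1) * 100.0
    for s, p in zip(scores, pct):
        s.percentile = float(p)
        if p <= outlier_low or p >= outlier_high:
            s.status = STATUS_OUTLIER
        elif small_low <= p <= small_high:
            s.status = STATUS_SMALL
        else:
            s.status = STATUS_RETAINED
    return scores


def scores_to_dataframe(scores: list[ChangeScore]):
    import pandas as pd

    rows = []
    for s in scores:
        rows.append(
            {
                "pair_id": s.pair_id,
                "dimension": s.dimension,
                "generators": ";".join(f"{c}:{r}" for c, r in sorted(s.generators)),
                "id_score": s.id_score,
                "percentile": s.percentile,
                "status": s.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "dimension", "generators", "id_score", "percentile", "status"],
    )
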