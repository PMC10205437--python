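"""Matching persistence features over time and between conditions.

Two diagram points are "the same structural site" when their generator CA
sets overlap:

    Sim(p, q) = |G_p ∩ G_q| / max(|G_p|, |G_q|)

and the match is accepted only when Sim exceeds the threshold delta
STRICTLY (delta = 0.75 by default; equality does not match).  Within a
condition, features are chained frame-to-frame into tracks; between
conditions, Control and Case tracks are paired by the similarity of their
first-frame generator sets, the two ensembles being constructed to
coincide at frame 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import IncompatibleTracksError, InvalidFeatureError
from .persistent_homology import Diagram, PersistenceFeature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchingConfig:
    """Parameters of generator-overlap matching.

    delta is the similarity threshold for considering homology (default
    0.75); min_persistence drops near-diagonal diagram points as numerical
    noise before tracking; min_track_fraction drops tracks shorter than
    that fraction of the frame count from downstream scoring.
    """

    delta: float = 0.75
    require_same_dimension: bool = True
    dimensions: tuple[int, ...] = (1, 2)
    min_persistence: float = 0.05
    min_track_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(f"delta must be in [0, 1), got {self.delta}")


@dataclass
class FeatureTrack:
    """One feature followed through consecutive frames of one condition."""

    condition_label: str
    dimension: int
    entries: list[tuple[int, PersistenceFeature]]
    track_id: int = 0

    @property
    def first_frame(self) -> int:
        return self.entries[0][0]

    @property
    def last_frame(self) -> int:
        return self.entries[-1][0]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def anchor_generators(self) -> frozenset:
        """Generator set at the first frame of the track."""
        return self.entries[0][1].generators

    def frames(self) -> list[int]:
        return [t for t, _ in self.entries]

    def feature_at(self, frame: int) -> PersistenceFeature:
        for t, f in self.entries:
            if t == frame:
                return f
        raise KeyError(frame)


@dataclass
class TrackPair:
    """A Control track and its corresponding Case track."""

    control_track: FeatureTrack
    case_track: FeatureTrack
    anchor_similarity: float
    overlap_frames: list[int]
    pair_id: int = 0

    @property
    def dimension(self) -> int:
        return self.control_track.dimension


@dataclass
class PairingResult:
    """Paired tracks plus the unpaired remainder of each condition
    (features that vanished in Case or were created by it)."""

    pairs: list[TrackPair]
    unpaired_control: list[FeatureTrack]
    unpaired_case: list[FeatureTrack]


def sim_raw(p: PersistenceFeature, q: PersistenceFeature) -> float:
    """Generator-overlap similarity |G_p ∩ G_q| / max(|G_p|, |G_q|)."""
    if not p.generators or not q.generators:
        raise InvalidFeatureError("feature with empty generator set")
    inter = len(p.generators & q.generators)
    return inter / max(len(p.generators), len(q.generators))


def is_match(p: PersistenceFeature, q: PersistenceFeature, cfg: MatchingConfig) -> bool:
    """True iff Sim(p, q) > delta strictly (equality at the threshold is
    rejected) and, if required, the dimensions agree."""
    if cfg.require_same_dimension and p.dimension != q.dimension:
        return False
    return sim_raw(p, q) > cfg.delta


def _trackable(diagram: Diagram, cfg: MatchingConfig) -> list[PersistenceFeature]:
    return [
        f
        for f in diagram.features
        if f.dimension in cfg.dimensions
        and not f.is_infinite
        and f.persistence >= cfg.min_persistence
    ]


def _tiebreak(p: PersistenceFeature, q: PersistenceFeature) -> float:
    return abs(p.birth - q.birth) + abs(p.death - q.death)


def build_tracks(
    diagrams: list[Diagram],
    cfg: MatchingConfig = MatchingConfig(),
    condition_label: str = "",
) -> list[FeatureTrack]:
    """Chain features of consecutive frames into tracks.

    Greedy one-to-one assignment per frame step in descending sim_raw,
    ties broken by smaller |Δbirth| + |Δdeath|, then by lower feature_id.
    Unmatched features close their track (disappearance) or open a new
    one (creation).  Deterministic for identical inputs.
    """
    diagrams = sorted(diagrams, key=lambda d: d.frame_index)
    open_tracks: list[FeatureTrack] = []
    closed: list[FeatureTrack] = []
    for dg in diagrams:
        feats = _trackable(dg, cfg)
        if not open_tracks:
            new = [
                FeatureTrack(condition_label, f.dimension, [(dg.frame_index, f)])
                for f in feats
            ]
            open_tracks = new
            continue
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = tr.entries[-1][1]
            for fi, f in enumerate(feats):
                if is_match(last, f, cfg):
                    candidates.append(
                        (
                            -sim_raw(last, f),
                            _tiebreak(last, f),
                            last.feature_id,
                            f.feature_id,
                            ti,
                            fi,
                        )
                    )
        candidates.sort()
        used_tracks: set[int] = set()
        used_feats: set[int] = set()
        for _, _, _, _, ti, fi in candidates:
            if ti in used_tracks or fi in used_feats:
                continue
            used_tracks.add(ti)
            used_feats.add(fi)
            open_tracks[ti].entries.append((dg.frame_index, feats[fi]))
        still_open = []
        for ti, tr in enumerate(open_tracks):
            if ti in used_tracks:
                still_open.append(tr)
            else:
                closed.append(tr)  # disappearance
        for fi, f in enumerate(feats):
            if fi not in used_feats:  # creation
                still_open.append(
                    FeatureTrack(condition_label, f.dimension, [(dg.frame_index, f)])
                )
        open_tracks = still_open
    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr.first_frame, tr.dimension, tr.entries[0][1].feature_id))
    for i, tr in enumerate(closed):
        tr.track_id = i
    return closed


def _anchor_sim(a: FeatureTrack, b: FeatureTrack) -> float:
    return sim_raw(a.entries[0][1], b.entries[0][1])


def pair_tracks(
    control: list[FeatureTrack],
    case: list[FeatureTrack],
    cfg: MatchingConfig = MatchingConfig(),
    n_frames: int | None = None,
) -> PairingResult:
    """Pair Control and Case tracks by first-frame generator overlap.

    One-to-one greedy pairing in descending anchor similarity; a pair is
    kept only if the anchor features satisfy is_match.  Tracks shorter
    than ``cfg.min_track_fraction * n_frames`` are dropped before pairing
    (noise guard).  Unpaired tracks are reported as created / vanished.
    """
    if n_frames is not None:
        min_len = max(2, int(cfg.min_track_fraction * n_frames))
        control = [t for t in control if len(t) >= min_len]
        case = [t for t in case if len(t) >= min_len]
    ctl_universe = set().union(*(t.anchor_generators for t in control)) if control else set()
    case_universe = set().union(*(t.anchor_generators for t in case)) if case else set()
    if control and case and not (ctl_universe & case_universe):
        raise IncompatibleTracksError(
            "Control and Case generator universes are disjoint; "
            "tracks were not built from a shared CA selection"
        )
    candidates = []
    for ci, ct in enumerate(control):
        for ki, kt in enumerate(case):
            pa, qa = ct.entries[0][1], kt.entries[0][1]
            if is_match(pa, qa, cfg):
                candidates.append(
                    (-sim_raw(pa, qa), _tiebreak(pa, qa), ct.track_id, kt.track_id, ci, ki)
                )
    candidates.sort()
    pairs: list[TrackPair] = []
    used_c: set[int] = set()
    used_k: set[int] = set()
    for negsim, _, _, _, ci, ki in candidates:
        if ci in used_c or ki in used_k:
            continue
        used_c.add(ci)
        used_k.add(ki)
        common = sorted(set(control[ci].frames()) & set(case[ki].frames()))
        pairs.append(
            TrackPair(
                control_track=control[ci],
                case_track=case[ki],
                anchor_similarity=-negsim,
                overlap_frames=common,
                pair_id=len(pairs),
            )
        )
    return PairingResult(
        pairs=pairs,
        unpaired_control=[t for i, t in enumerate(control) if i not in used_c],
        unpaired_case=[t for i, t in enumerate(case) if i not in used_k],
    )


def tracks_to_dataframe(tracks: list[FeatureTrack]):
    import pandas as pd

    rows = []
    for tr in tracks:
        for t, f in tr.entries:
            rows.append(
                {
                    "track_id": tr.track_id,
                    "condition": tr.condition_label,
                    "dimension": tr.dimension,
                    "frame": t,
                    "birth": f.birth,
                    "death": f.death,
                    "generators": ";".join(f"{c}:{r}" for c, r in sorted(f.generators)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "condition", "dimension", "frame", "birth", "death", "generators"],
    )
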