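"""End-to-end orchestration: ensembles in, change tables out.

The stages mirror the analysis flow: read Case/Control ensembles, fix a
shared CA selection, compute per-frame persistence diagrams, track and
pair features by generator overlap, score paired tracks, filter by
percentile (and optionally by secondary structure), then compare
hydrogen-bond formation rates around the retained features.  Every stage
writes a plain CSV so stages can be rerun or inspected independently; a
manifest JSON records the fully-resolved configuration and a content
hash of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import change_scoring, feature_tracking, hbond_analysis
from . import persistent_homology as ph
from . import ss_filter, trajectory_io
from .errors import DaisError, FormatError, NoHydrogensError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully-resolved run parameters; defaults are the method's stated
    operating point (500 CAs, delta 0.75, window 11, percentile bands
    1/5/95/99, H-bond 1.5-2.2 Å / 160° / 10 Å neighborhood)."""

    control_path: str = ""
    case_path: str = ""
    control_frames_path: str | None = None
    case_frames_path: str | None = None
    dssp_path: str | None = None
    out_dir: str = "dais_out"

    n_cas: int = 500
    seed: int = 0
    filtration: str = "alpha"
    max_dimension: int = 2

    delta: float = 0.75
    min_persistence: float = 0.05
    min_track_fraction: float = 0.1

    window: int = 11
    sum_abs: bool = False
    outlier_low: float = 1.0
    small_low: float = 5.0
    small_high: float = 95.0
    outlier_high: float = 99.0

    ss_min_fraction: float = 0.5
    structured_classes: str = "HGIEB"

    run_hbond: str = "auto"  # "auto" | "always" | "never"
    hbond_r_min: float = 1.5
    hbond_r_max: float = 2.2
    hbond_theta_min: float = 160.0
    neighborhood_radius: float = 10.0
    hbond_top_k: int = 20

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def matching(self) -> feature_tracking.MatchingConfig:
        return feature_tracking.MatchingConfig(
            delta=self.delta,
            min_persistence=self.min_persistence,
            min_track_fraction=self.min_track_fraction,
        )

    def hbond_geometry(self) -> hbond_analysis.HBondGeometryConfig:
        return hbond_analysis.HBondGeometryConfig(
            r_min=self.hbond_r_min,
            r_max=self.hbond_r_max,
            theta_min=self.hbond_theta_min,
            neighborhood_radius=self.neighborhood_radius,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    selection: trajectory_io.CASelection
    diagrams_control: list
    diagrams_case: list
    tracks_control: list
    tracks_case: list
    pairing: feature_tracking.PairingResult
    scores: list
    hbond_diffs: list
    manifest: dict


def run_pipeline(
    config: RunConfig,
    control: trajectory_io.ConformationEnsemble | None = None,
    case: trajectory_io.ConformationEnsemble | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Run every stage; ensembles may be passed in memory (fixtures) or
    read from the configured paths."""
    t0 = time.time()
    if control is None:
        if not os.path.exists(config.control_path):
            raise FormatError(f"control path not found: {config.control_path}")
        control = trajectory_io.read_ensemble(
            config.control_path, config.control_frames_path, "control"
        )
    if case is None:
        if not os.path.exists(config.case_path):
            raise FormatError(f"case path not found: {config.case_path}")
        case = trajectory_io.read_ensemble(
            config.case_path, config.case_frames_path, "case"
        )

    selection = trajectory_io.select_cas(
        control, case, n_cas=config.n_cas, seed=config.seed
    )
    logger.info("selected %d CAs [%.1fs]", len(selection), time.time() - t0)

    diagrams_control = ph.compute_diagram_series(
        control, selection, config.max_dimension, config.filtration
    )
    diagrams_case = ph.compute_diagram_series(
        case, selection, config.max_dimension, config.filtration
    )
    logger.info("diagrams done [%.1fs]", time.time() - t0)

    cfg = config.matching()
    tracks_control = feature_tracking.build_tracks(diagrams_control, cfg, "control")
    tracks_case = feature_tracking.build_tracks(diagrams_case, cfg, "case")
    pairing = feature_tracking.pair_tracks(
        tracks_control, tracks_case, cfg, n_frames=control.n_frames
    )

    scores = change_scoring.score_pairs(
        pairing.pairs, window=config.window, sum_abs=config.sum_abs
    )
    scores = change_scoring.percentile_filter(
        scores,
        outlier_low=config.outlier_low,
        small_low=config.small_low,
        small_high=config.small_high,
        outlier_high=config.outlier_high,
    )
    if config.dssp_path:
        ann = ss_filter.read_dssp(config.dssp_path)
        scores = ss_filter.filter_by_ss(
            scores,
            ann,
            structured_classes=frozenset(config.structured_classes),
            min_fraction=config.ss_min_fraction,
        )
    logger.info("scoring done [%.1fs]", time.time() - t0)

    hbond_diffs: list = []
    has_h = any(a.element == "H" for a in control.atoms)
    want_h = config.run_hbond == "always" or (
        config.run_hbond == "auto" and has_h
    )
    if config.run_hbond == "auto" and not has_h:
        logger.warning("no explicit hydrogens; H-bond stage skipped")
    if want_h:
        focus = [
            s for s in scores if s.status == change_scoring.STATUS_RETAINED
        ] or scores
        gen_union: frozenset = frozenset().union(
            *(s.generators for s in focus)
        ) if focus else frozenset()
        if gen_union:
            cand_ctl = hbond_analysis.neighborhood_atoms(
                gen_union, control, 0, config.neighborhood_radius
            )
            cand_case = hbond_analysis.neighborhood_atoms(
                gen_union, case, 0, config.neighborhood_radius
            )
            geometry = config.hbond_geometry()
            rates_ctl = hbond_analysis.formation_rates(control, cand_ctl, geometry)
            rates_case = hbond_analysis.formation_rates(case, cand_case, geometry)
            hbond_diffs = hbond_analysis.hbond_diff(
                rates_ctl, rates_case, top_k=config.hbond_top_k
            )
        logger.info("h-bond stage done [%.1fs]", time.time() - t0)

    manifest: dict = {"config": dataclasses.asdict(config), "outputs": {}}
    if write_outputs:
        os.makedirs(config.out_dir, exist_ok=True)
        tables = {
            "diagrams_control.csv": ph.diagrams_to_dataframe(diagrams_control),
            "diagrams_case.csv": ph.diagrams_to_dataframe(diagrams_case),
            "tracks_control.csv": feature_tracking.tracks_to_dataframe(tracks_control),
            "tracks_case.csv": feature_tracking.tracks_to_dataframe(tracks_case),
            "scores.csv": change_scoring.scores_to_dataframe(scores),
            "hbond_diffs.csv": hbond_analysis.hbond_diffs_to_dataframe(hbond_diffs),
        }
        for name, df in tables.items():
            path = os.path.join(config.out_dir, name)
            df.to_csv(path, index=False)
            manifest["outputs"][name] = {"path": path, "sha256": _sha256(path)}
        mpath = os.path.join(config.out_dir, "manifest.json")
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete [%.1fs]", time.time() - t0)

    return PipelineResult(
        selection=selection,
        diagrams_control=diagrams_control,
        diagrams_case=diagrams_case,
        tracks_control=tracks_control,
        tracks_case=tracks_case,
        pairing=pairing,
        scores=scores,
        hbond_diffs=hbond_diffs,
        manifest=manifest,
    )
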