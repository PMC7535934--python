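"""End-to-end workflows tying tracking, kinematics, ratiometry and stats.

Two orchestrations are provided. The behaviour workflow takes grouped
videos (plus optional manual leg-order annotations), tracks each fly,
issues walking verdicts, tabulates walked/not-walked counts per group and
runs the pairwise exact chi-squared comparison with Bonferroni correction.
The imaging workflow takes a treadmill session table, converts rotations to
kinematics, segments walking/resting epochs, computes %dR/R and the
epoch-aligned averages, and persists every intermediate as CSV/JSON.

Outputs embed the seed and a hash of the configuration so identical
configurations give identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import catstats, kinematics, ratiometric, tracking

logger = logging.getLogger("undeadlab")

SESSION_COLUMNS = ("frame", "t_s", "rot_fwd", "rot_side", "rot_yaw",
                   "F_activity", "F_reference")


@dataclass
class RunConfig:
    """Bundle of stage configurations for a pipeline run."""

    tracking_cfg: tracking.TrackingConfig = field(
        default_factory=tracking.TrackingConfig)
    criterion: tracking.WalkingCriterion = field(
        default_factory=tracking.WalkingCriterion)
    kinematics_cfg: kinematics.KinematicsConfig = field(
        default_factory=kinematics.KinematicsConfig)
    thresholds: kinematics.EpochThresholds = field(
        default_factory=kinematics.EpochThresholds)
    baseline: str = "percentile:8"
    min_support: int = 4
    family: catstats.FamilySpec | None = None
    seed: int = 0
    output_dir: str | Path | None = None

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in
                        dataclasses.asdict(obj).items()}
            if isinstance(obj, (Path, np.floating, np.integer)):
                return str(obj)
            return obj
        blob = json.dumps({k: enc(v) for k, v in vars(self).items()
                           if k != "output_dir"},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_behaviour_workflow(groups: dict[str, list], cfg: RunConfig | None = None,
                           annotations: dict | None = None) -> dict:
    """Track grouped videos, classify walkers, and compare groups.

    ``groups`` maps a group label to a list of :class:`tracking.VideoStack`
    (or TIFF paths). ``annotations`` optionally maps (group, index) to the
    manual leg-order flag. Returns a report with per-fly verdicts, the
    groups x {walked, not-walked} table and the pairwise statistics; when
    ``cfg.output_dir`` is set everything is persisted there.
    """
    cfg = cfg or RunConfig()
    if len(groups) < 1:
        raise ValueError("need at least one group")
    annotations = annotations or {}
    verdicts: dict[str, list[bool]] = {}
    for label, videos in groups.items():
        verdicts[label] = []
        for i, video in enumerate(videos):
            if not isinstance(video, tracking.VideoStack):
                video = tracking.VideoStack.from_tiff(video)
            try:
                track = tracking.track_video(video, cfg.tracking_cfg)
            except tracking.UntrackableVideoError as err:
                raise RuntimeError(
                    f"tracking failed for group {label!r} video {i}: {err}"
                ) from err
            crit = cfg.criterion
            if crit.require_leg_sequence and (label, i) in annotations:
                crit = dataclasses.replace(
                    crit, leg_sequence_annotation=annotations[(label, i)])
            verdicts[label].append(tracking.classify_walker(track, crit))

    counts = [(int(sum(v)), len(v)) for v in verdicts.values()]
    labels = list(verdicts)
    report: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "verdicts": {k: [bool(b) for b in v] for k, v in verdicts.items()},
        "counts": {k: {"walked": c[0], "total": c[1]}
                   for k, c in zip(labels, counts)},
    }
    if len(groups) >= 2:
        results = catstats.pairwise_group_comparison(counts, cfg.family,
                                                     labels=labels)
        report["pairwise"] = [r.to_dict() for r in results]
    else:
        report["pairwise"] = None
        logger.info("single group: contingency stage skipped")

    if cfg.output_dir is not None:
        _write_json(Path(cfg.output_dir) / "behaviour_report.json", report)
    return report


def validate_session(df: pd.DataFrame) -> None:
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session is missing columns: {missing}")


def run_imaging_workflow(session: pd.DataFrame | str | Path, fps: float,
                         cfg: RunConfig | None = None,
                         label: str = "walking") -> dict:
    """Kinematics -> epochs -> %dR/R -> epoch-aligned averages.

    ``session`` is a table (or CSV path) with columns
    frame, t_s, rot_fwd, rot_side, rot_yaw, F_activity, F_reference.
    """
    cfg = cfg or RunConfig()
    if not isinstance(session, pd.DataFrame):
        session = pd.read_csv(session)
    validate_session(session)

    ball = kinematics.BallTrace.from_dataframe(session, fps=fps)
    kin = kinematics.rotations_to_kinematics(ball, cfg.kinematics_cfg)
    epochs = kinematics.segment_epochs(kin, cfg.thresholds)
    trace = ratiometric.TwoChannelTrace(session["F_activity"].to_numpy(),
                                        session["F_reference"].to_numpy(),
                                        fps=fps)
    R, valid = ratiometric.ratio_trace(trace)
    ratio = ratiometric.delta_r_over_r(R, cfg.baseline, valid)
    aligned = ratiometric.epoch_align_average(ratio.dRR, epochs, label,
                                              cfg.min_support)

    report = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_frames": int(len(session)),
        "epochs": epochs.to_records(),
        "n_epochs": {lab: len(epochs.of_label(lab))
                     for lab in ("walking", "resting")},
        "average_defined": bool(np.isfinite(aligned.average).any()),
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        kin_df = kin.to_dataframe()
        kin_df["label"] = epochs.labels
        kin_df["dRR"] = ratio.dRR
        kin_df.to_csv(out / "kinematics.csv", index=False)
        _write_json(out / "epochs.json", {"epochs": epochs.to_records()})
        pd.DataFrame({
            "aligned_index": np.arange(aligned.support.size),
            "support": aligned.support,
            "average_dRR": aligned.average,
        }).to_csv(out / f"aligned_{label}.csv", index=False)
        _write_json(out / "imaging_report.json", report)
    report["kinematics"] = kin
    report["ratio"] = ratio
    report["aligned"] = aligned
    report["epoch_objects"] = epochs
    return report
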