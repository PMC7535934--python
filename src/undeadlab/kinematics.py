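"""Spherical-treadmill kinematics and walking/resting epoch segmentation.

Ball rotation rates recorded from a tethered fly are converted into
body-frame speeds (one rotation/s = 31.42 mm/s for the translational axes,
360 deg/s for yaw) and then into per-frame displacements. A frame counts as
resting only when the forward, sideways and yaw displacements are all below
their thresholds (defaults 0.12 mm, 0.12 mm, 5 deg per frame); every other
frame is walking. Maximal runs of equally labelled frames form epochs that
tile the session exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BallTrace",
    "KinematicsConfig",
    "KinematicsTrace",
    "EpochThresholds",
    "Epoch",
    "BehaviourEpochs",
    "rotations_to_kinematics",
    "segment_epochs",
]

MM_PER_ROTATION = 31.42
DEG_PER_ROTATION = 360.0


@dataclass(frozen=True)
class BallTrace:
    """Per-frame ball rotation rates (rotations/s) about three axes."""

    rot_fwd: np.ndarray
    rot_side: np.ndarray
    rot_yaw: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        arrays = [np.asarray(a, dtype=float)
                  for a in (self.rot_fwd, self.rot_side, self.rot_yaw)]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise ValueError("rotation arrays must have equal length")
        for name, a in zip(("rot_fwd", "rot_side", "rot_yaw"), arrays):
            object.__setattr__(self, name, a)

    @property
    def n_frames(self) -> int:
        return self.rot_fwd.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float) -> "BallTrace":
        return cls(df["rot_fwd"].to_numpy(), df["rot_side"].to_numpy(),
                   df["rot_yaw"].to_numpy(), fps=fps)


@dataclass(frozen=True)
class KinematicsConfig:
    """Rotation-to-speed conversion constants."""

    mm_per_rotation: float = MM_PER_ROTATION
    deg_per_rotation: float = DEG_PER_ROTATION

    def __post_init__(self) -> None:
        if self.mm_per_rotation <= 0 or self.deg_per_rotation <= 0:
            raise ValueError("conversion constants must be positive")


@dataclass(frozen=True)
class KinematicsTrace:
    """Body-frame speeds and per-frame displacements."""

    v_forward: np.ndarray   # mm/s
    v_side: np.ndarray      # mm/s
    v_rotation: np.ndarray  # deg/s
    fps: float

    @property
    def d_fwd(self) -> np.ndarray:
        """Forward displacement per frame, mm."""
        return self.v_forward / self.fps

    @property
    def d_side(self) -> np.ndarray:
        return self.v_side / self.fps

    @property
    def d_rot(self) -> np.ndarray:
        """Yaw displacement per frame, deg."""
        return self.v_rotation / self.fps

    @property
    def n_frames(self) -> int:
        return self.v_forward.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "v_forward": self.v_forward,
            "v_side": self.v_side,
            "v_rotation": self.v_rotation,
            "d_fwd": self.d_fwd,
            "d_side": self.d_side,
            "d_rot": self.d_rot,
        })


@dataclass(frozen=True)
class EpochThresholds:
    """Resting thresholds on per-frame displacements (mm, mm, deg).

    ``per_second=True`` reinterprets the same numbers as speed thresholds
    (mm/s, mm/s, deg/s) instead of per-frame displacements.
    """

    theta_fwd: float = 0.12
    theta_side: float = 0.12
    theta_rot: float = 5.0
    per_second: bool = False

    def __post_init__(self) -> None:
        if min(self.theta_fwd, self.theta_side, self.theta_rot) < 0:
            raise ValueError("thresholds must be non-negative")


Epoch = tuple[int, int, str]  # (start, end half-open, "walking"|"resting")


@dataclass
class BehaviourEpochs:
    """Alternating walking/resting epochs tiling [0, n_frames)."""

    epochs: list[Epoch]
    n_frames: int
    labels: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        pos = 0
        prev = None
        for start, end, label in self.epochs:
            if start != pos or end <= start:
                raise ValueError("epochs must tile the session without gaps")
            if label == prev:
                raise ValueError("adjacent epochs must have different labels")
            pos, prev = end, label
        if self.epochs and pos != self.n_frames:
            raise ValueError("epochs must cover all frames")
        if self.labels is None:
            labels = np.empty(self.n_frames, dtype=object)
            for start, end, label in self.epochs:
                labels[start:end] = label
            self.labels = labels

    def of_label(self, label: str) -> list[Epoch]:
        return [e for e in self.epochs if e[2] == label]

    def to_records(self) -> list[dict]:
        return [{"start": s, "end": e, "label": lab}
                for s, e, lab in self.epochs]


def rotations_to_kinematics(ball: BallTrace,
                            cfg: KinematicsConfig | None = None
                            ) -> KinematicsTrace:
    """Convert rotation rates to speeds: v = rate x constant, elementwise."""
    cfg = cfg or KinematicsConfig()
    return KinematicsTrace(
        v_forward=ball.rot_fwd * cfg.mm_per_rotation,
        v_side=ball.rot_side * cfg.mm_per_rotation,
        v_rotation=ball.rot_yaw * cfg.deg_per_rotation,
        fps=ball.fps,
    )


def segment_epochs(kin: KinematicsTrace,
                   thr: EpochThresholds | None = None) -> BehaviourEpochs:
    """Label each frame walking/resting and merge runs into epochs.

    A frame is resting iff |d_fwd| < theta_fwd AND |d_side| < theta_side AND
    |d_rot| < theta_rot — strictly below, so a displacement exactly at a
    threshold is walking. Absolute values make the rule direction-agnostic.
    """
    thr = thr or EpochThresholds()
    if thr.per_second:
        d_fwd, d_side, d_rot = kin.v_forward, kin.v_side, kin.v_rotation
    else:
        d_fwd, d_side, d_rot = kin.d_fwd, kin.d_side, kin.d_rot
    resting = ((np.abs(d_fwd) < thr.theta_fwd)
               & (np.abs(d_side) < thr.theta_side)
               & (np.abs(d_rot) < thr.theta_rot))
    labels = np.where(resting, "resting", "walking")

    epochs: list[Epoch] = []
    n = labels.size
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            epochs.append((start, i, str(labels[start])))
            start = i
    return BehaviourEpochs(epochs=epochs, n_frames=n, labels=labels)
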