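"""Ratiometric %dR/R fluorescence analysis and epoch-aligned averaging.

The activity measure is the ratio R of an activity reporter (e.g. GCaMP6s)
to an activity-independent anatomical reporter (e.g. tdTomato) within the
same region of interest; expressing changes as %dR/R = 100 (R - R0) / R0
cancels motion and expression-level artefacts common to both channels.
Traces belonging to behavioural epochs of one label are aligned at epoch
start and averaged wherever at least ``min_support`` (default 4) traces are
still running.

Also provided: per-channel max normalisation of intensity line profiles,
mean-intensity extraction from small circular sub-ROIs, and an integer-pixel
rigid registration stand-in for motion correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .kinematics import BehaviourEpochs

__all__ = [
    "TwoChannelTrace",
    "RatioTrace",
    "EpochAlignedTraces",
    "LineProfile",
    "SubRoi",
    "ratio_trace",
    "delta_r_over_r",
    "epoch_align_average",
    "normalise_trace",
    "line_profile_normalise",
    "subroi_traces",
    "register_rigid",
]

DEFAULT_BASELINE_PERCENTILE = 8.0
DEFAULT_MIN_SUPPORT = 4


@dataclass(frozen=True)
class TwoChannelTrace:
    """Paired activity / reference fluorescence traces at a common frame rate."""

    F_activity: np.ndarray
    F_reference: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        act = np.asarray(self.F_activity, dtype=float)
        ref = np.asarray(self.F_reference, dtype=float)
        if act.size != ref.size:
            raise ValueError("channels must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "F_activity", act)
        object.__setattr__(self, "F_reference", ref)


@dataclass
class RatioTrace:
    """Per-frame ratio, its baseline, and the derived %dR/R."""

    R: np.ndarray
    R0: float | np.ndarray
    dRR: np.ndarray
    valid: np.ndarray


def ratio_trace(tc: TwoChannelTrace) -> tuple[np.ndarray, np.ndarray]:
    """R = F_activity / F_reference elementwise.

    Frames whose reference signal is not positive are marked invalid (NaN in
    R); a trace with no valid frame raises.
    """
    valid = tc.F_reference > 0
    if not valid.any():
        raise ValueError("no frame has a positive reference signal")
    R = np.full(tc.F_activity.shape, np.nan)
    R[valid] = tc.F_activity[valid] / tc.F_reference[valid]
    return R, valid


def _resolve_baseline(R: np.ndarray, valid: np.ndarray, baseline) -> float | np.ndarray:
    """Baseline spec: ('percentile', q) | ('min-smoothed', w) | ('fixed', v).

    Strings like ``"percentile:8"`` are accepted for CLI convenience.
    """
    if isinstance(baseline, str):
        name, _, arg = baseline.partition(":")
        baseline = (name, float(arg)) if arg else (name,)
    method = baseline[0]
    if method == "percentile":
        q = baseline[1] if len(baseline) > 1 else DEFAULT_BASELINE_PERCENTILE
        return float(np.percentile(R[valid], q))
    if method == "min-smoothed":
        w = int(baseline[1]) if len(baseline) > 1 else 31
        filled = np.where(valid, R, np.inf)
        rolling_min = ndimage.minimum_filter1d(filled, size=w, mode="nearest")
        return ndimage.uniform_filter1d(rolling_min, size=w, mode="nearest")
    if method == "fixed":
        return float(baseline[1])
    raise ValueError(f"unknown baseline method {method!r}")


def delta_r_over_r(R: np.ndarray, baseline="percentile:8",
                   valid: np.ndarray | None = None) -> RatioTrace:
    """%dR/R = 100 (R - R0) / R0 with a declared baseline rule.

    Baselines: ``percentile:q`` (default q = 8, robust to transients),
    ``min-smoothed:w`` (rolling minimum of width w, smoothed), or
    ``fixed:v``. R0 must be positive everywhere it is used.
    """
    R = np.asarray(R, dtype=float)
    if valid is None:
        valid = ~np.isnan(R)
    R0 = _resolve_baseline(R, valid, baseline)
    if np.any(np.asarray(R0) <= 0):
        raise ValueError("baseline R0 must be positive")
    dRR = np.full(R.shape, np.nan)
    R0_arr = np.broadcast_to(np.asarray(R0, dtype=float), R.shape)
    dRR[valid] = 100.0 * (R[valid] - R0_arr[valid]) / R0_arr[valid]
    return RatioTrace(R=R, R0=R0, dRR=dRR, valid=valid)


@dataclass
class EpochAlignedTraces:
    """Start-aligned per-epoch dR/R segments and their supported average.

    ``support[i]`` counts the segments still running at aligned index i;
    ``average[i]`` is their mean and is defined (non-NaN) only where
    ``support[i] >= min_support``.
    """

    segments: list[np.ndarray]
    support: np.ndarray
    average: np.ndarray
    min_support: int = DEFAULT_MIN_SUPPORT
    epoch_bounds: list[tuple[int, int]] = field(default_factory=list)


def epoch_align_average(dRR: np.ndarray, epochs: BehaviourEpochs,
                        label: str = "walking",
                        min_support: int = DEFAULT_MIN_SUPPORT
                        ) -> EpochAlignedTraces:
    """Align the dR/R segments of same-behaviour epochs by their start.

    Every epoch of the requested label contributes its segment beginning at
    its start frame. The average at aligned index i is the mean over the
    segments longer than i, emitted only where that count reaches
    ``min_support``. No epochs of the label yields an empty result.
    """
    dRR = np.asarray(dRR, dtype=float)
    if epochs.n_frames != dRR.size:
        raise ValueError("epochs must tile the dR/R trace")
    selected = epochs.of_label(label)
    segments = [dRR[s:e] for s, e, _ in selected]
    if not segments:
        return EpochAlignedTraces([], np.zeros(0, dtype=int),
                                  np.zeros(0), min_support, [])
    max_len = max(len(seg) for seg in segments)
    support = np.zeros(max_len, dtype=int)
    total = np.zeros(max_len)
    for seg in segments:
        support[:len(seg)] += 1
        total[:len(seg)] += seg
    average = np.full(max_len, np.nan)
    ok = support >= min_support
    average[ok] = total[ok] / support[ok]
    return EpochAlignedTraces(segments, support, average, min_support,
                              [(s, e) for s, e, _ in selected])


def normalise_trace(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Divide a trace by its maximum absolute value; peak maps to +/-1.

    Returns ``(normalised, flagged)``; an all-zero trace comes back
    unchanged with the flag set.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be non-empty")
    peak = np.nanmax(np.abs(series))
    if peak == 0 or np.isnan(peak):
        return series.copy(), True
    return series / peak, False


@dataclass
class LineProfile:
    """Raw and per-channel max-normalised intensities along a user line."""

    positions: np.ndarray
    channels: dict[str, np.ndarray]
    normalised: dict[str, np.ndarray] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)


def line_profile_normalise(profile: LineProfile) -> LineProfile:
    """Normalise each channel by its own maximum along the line.

    Every positive channel ends up on a common 0-1 scale with its maximum at
    exactly 1; channels are normalised independently, so rescaling one never
    changes another. An all-zero channel is left at zero and flagged.
    Idempotent.
    """
    if profile.positions.size == 0:
        raise ValueError("profile must contain at least one sample")
    normalised, flags = {}, {}
    for name, values in profile.channels.items():
        values = np.asarray(values, dtype=float)
        peak = values.max() if values.size else 0.0
        if peak > 0:
            normalised[name] = values / peak
            flags[name] = False
        else:
            normalised[name] = values.copy()
            flags[name] = True
    return LineProfile(profile.positions, profile.channels, normalised, flags)


@dataclass(frozen=True)
class SubRoi:
    """A circular sub-ROI: centre (cx, cy) and radius, in pixels."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius ** 2


def subroi_traces(activity_stack: np.ndarray, reference_stack: np.ndarray,
                  rois: list[SubRoi], fps: float,
                  baseline="percentile:8",
                  aggregate: str = "mean") -> list[RatioTrace]:
    """Per-ROI %dR/R traces from paired activity/reference image stacks.

    For each circular ROI the per-frame pixel aggregate (mean by default,
    median available) is taken in both channels, ratioed, and converted to
    %dR/R. ROIs extending beyond the frame raise, naming the offender.
    """
    activity_stack = np.asarray(activity_stack, dtype=float)
    reference_stack = np.asarray(reference_stack, dtype=float)
    if activity_stack.shape != reference_stack.shape:
        raise ValueError("activity and reference stacks must match in shape")
    h, w = activity_stack.shape[1:]
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    traces = []
    for i, roi in enumerate(rois):
        if (roi.cx - roi.radius < 0 or roi.cy - roi.radius < 0
                or roi.cx + roi.radius > w - 1 or roi.cy + roi.radius > h - 1):
            raise ValueError(f"ROI {i} (cx={roi.cx}, cy={roi.cy}, "
                             f"r={roi.radius}) extends outside the frame")
        m = roi.mask((h, w))
        act = np.array([agg(frame[m]) for frame in activity_stack])
        ref = np.array([agg(frame[m]) for frame in reference_stack])
        R, valid = ratio_trace(TwoChannelTrace(act, ref, fps))
        traces.append(delta_r_over_r(R, baseline, valid))
    return traces


def register_rigid(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer-pixel rigid registration of a stack to its first frame.

    Each frame is translated (circularly) by the integer shift that
    maximises its cross-correlation with frame 0, estimated by phase
    correlation. Returns ``(registered stack, shifts (n, 2) as (dy, dx))``.
    A single-frame stack is returned unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    n = stack.shape[0]
    registered = stack.copy()
    shifts = np.zeros((n, 2), dtype=int)
    for i in range(1, n):
        shift, _, _ = phase_cross_correlation(stack[0], stack[i],
                                              upsample_factor=1,
                                              normalization=None)
        shift = np.round(shift).astype(int)
        shifts[i] = shift
        registered[i] = np.roll(stack[i], shift, axis=(0, 1))
    return registered, shifts
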