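"""Centroid tracking of a single fly in overhead behaviour videos.

Pipeline per frame: greyscale -> contrast-limited adaptive histogram
equalisation (CLAHE) -> Gaussian smoothing (sigma = 4 px) -> binarisation
(Otsu by default) -> centroid of the largest connected component. The
per-frame centroids form a track whose cumulative Euclidean path length, in
body lengths, drives the walking verdict: a fly "walked" when it covered at
least one body length (and, when required, showed the hind-to-front
T3-T2-T1 leg recruitment — consumed as a manual annotation, never computed).

Spatial calibration comes from a photographed piece of graph paper: the
median peak-to-peak spacing of grid-line projections maps pixels to mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.signal import find_peaks
from skimage import exposure, filters, measure

__all__ = [
    "VideoStack",
    "TrackingConfig",
    "BodyTrack",
    "WalkingCriterion",
    "UntrackableVideoError",
    "CalibrationError",
    "preprocess_frame",
    "extract_centroid",
    "track_video",
    "calibrate",
    "classify_walker",
    "render_overlay",
]

INVALID = (np.nan, np.nan)
MAX_INVALID_FRACTION = 0.5


class UntrackableVideoError(RuntimeError):
    """More than half of the frames yielded no body segmentation."""


class CalibrationError(RuntimeError):
    """Grid image does not contain enough detectable grid lines."""


@dataclass
class VideoStack:
    """Time-ordered greyscale frames with frame rate and optional calibration."""

    frames: np.ndarray  # (T, H, W), intensities in [0, 1]
    fps: float = 25.0
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("need a (frames, height, width) stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_tiff(cls, path: str | Path, fps: float = 25.0,
                  mm_per_px: float | None = None) -> "VideoStack":
        frames = tifffile.imread(path).astype(float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim == 4:  # RGB -> luminance
            frames = frames.mean(axis=-1)
        if frames.max() > 1:
            frames = frames / 255.0
        return cls(frames=frames, fps=fps, mm_per_px=mm_per_px)


@dataclass(frozen=True)
class TrackingConfig:
    """Segmentation settings; gauss_sigma = 4 is the protocol's fixed value."""

    clahe_clip: float = 0.01
    clahe_tile: int | None = None  # None -> 1/8 of the frame side
    gauss_sigma: float = 4.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.5
    polarity: str = "dark-body"  # or "bright-body"

    def __post_init__(self) -> None:
        if self.gauss_sigma <= 0:
            raise ValueError("gauss_sigma must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and not 0 <= self.fixed_threshold <= 1:
            raise ValueError("fixed_threshold must lie in [0, 1]")
        if self.polarity not in ("dark-body", "bright-body"):
            raise ValueError("polarity must be 'dark-body' or 'bright-body'")


@dataclass
class BodyTrack:
    """Per-frame centroids (px and, when calibrated, mm) and path length."""

    centroids_px: np.ndarray       # (T, 2) as (x, y); NaN where invalid
    valid: np.ndarray              # (T,) bool
    mm_per_px: float | None = None
    body_length_px: float | None = None
    fps: float = 25.0

    @property
    def centroids_mm(self) -> np.ndarray | None:
        if self.mm_per_px is None:
            return None
        return self.centroids_px * self.mm_per_px

    @property
    def path_length_px(self) -> float:
        """Sum of Euclidean steps over consecutive valid frame pairs."""
        c = self.centroids_px
        both = self.valid[:-1] & self.valid[1:]
        steps = np.linalg.norm(np.diff(c, axis=0), axis=1)
        return float(steps[both].sum()) if both.any() else 0.0

    @property
    def path_length_mm(self) -> float | None:
        if self.mm_per_px is None:
            return None
        return self.path_length_px * self.mm_per_px

    @property
    def body_length_mm(self) -> float | None:
        if self.mm_per_px is None or self.body_length_px is None:
            return None
        return self.body_length_px * self.mm_per_px

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "frame": np.arange(len(self.valid)),
            "x_px": self.centroids_px[:, 0],
            "y_px": self.centroids_px[:, 1],
            "valid": self.valid,
        })
        if self.mm_per_px is not None:
            df["x_mm"] = df["x_px"] * self.mm_per_px
            df["y_mm"] = df["y_px"] * self.mm_per_px
        return df


@dataclass(frozen=True)
class WalkingCriterion:
    """Walked = path >= min_path_body_lengths x body length (+ leg order)."""

    min_path_body_lengths: float = 1.0
    require_leg_sequence: bool = False
    leg_sequence_annotation: bool | None = None

    def __post_init__(self) -> None:
        if self.min_path_body_lengths <= 0:
            raise ValueError("min_path_body_lengths must be positive")


def preprocess_frame(frame: np.ndarray, cfg: TrackingConfig | None = None
                     ) -> np.ndarray:
    """Segment putative body pixels: CLAHE -> Gaussian(sigma) -> threshold.

    The order is fixed; polarity decides which side of the threshold is
    body. A featureless frame legally yields an empty mask.
    """
    cfg = cfg or TrackingConfig()
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) < 1e-6:  # no contrast: CLAHE/Otsu undefined
        return np.zeros(frame.shape, dtype=bool)
    tile = cfg.clahe_tile or max(8, min(frame.shape) // 8)
    eq = exposure.equalize_adapthist(np.clip(frame, 0, 1),
                                     kernel_size=tile,
                                     clip_limit=cfg.clahe_clip)
    smoothed = filters.gaussian(eq, sigma=cfg.gauss_sigma)
    if cfg.threshold_method == "otsu":
        thr = filters.threshold_otsu(smoothed)
    else:
        thr = cfg.fixed_threshold
    if cfg.polarity == "dark-body":
        return smoothed < thr
    return smoothed > thr


def extract_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (x, y) of the largest connected component of a binary mask.

    The centroid is the unweighted mean of pixel centres. An empty mask
    returns the NaN sentinel rather than raising, so a few bad frames never
    abort a video.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return INVALID
    labels = measure.label(mask)
    largest = max(measure.regionprops(labels), key=lambda r: r.area)
    cy, cx = largest.centroid
    return float(cx), float(cy)


def _body_length_from_masks(masks: np.ndarray) -> float | None:
    """Median over frames of the best-fit-ellipse major-axis length.

    Fitted to the largest connected component of each non-empty frame mask;
    the median over frames is robust to occasional bad segmentations and,
    unlike a time-median mask, well defined for a moving animal.
    """
    majors = []
    for mask in masks:
        if not mask.any():
            continue
        labels = measure.label(mask)
        largest = max(measure.regionprops(labels), key=lambda r: r.area)
        majors.append(largest.axis_major_length)
    return float(np.median(majors)) if majors else None


def track_video(video: VideoStack, cfg: TrackingConfig | None = None
                ) -> BodyTrack:
    """Track the body centroid across all frames of a video.

    Raises :class:`UntrackableVideoError` when more than half of the frames
    produce no segmentation. Body length defaults to the major-axis length
    of the best-fit ellipse of the median (over time) body mask.
    """
    cfg = cfg or TrackingConfig()
    centroids = np.full((video.n_frames, 2), np.nan)
    masks = np.zeros(video.frames.shape, dtype=bool)
    for i, frame in enumerate(video.frames):
        masks[i] = preprocess_frame(frame, cfg)
        centroids[i] = extract_centroid(masks[i])
    valid = ~np.isnan(centroids[:, 0])
    invalid_fraction = 1.0 - valid.mean()
    if invalid_fraction > MAX_INVALID_FRACTION:
        raise UntrackableVideoError(
            f"{invalid_fraction:.0%} of frames have no trackable body "
            f"(limit {MAX_INVALID_FRACTION:.0%})")
    return BodyTrack(
        centroids_px=centroids,
        valid=valid,
        mm_per_px=video.mm_per_px,
        body_length_px=_body_length_from_masks(masks[valid]),
        fps=video.fps,
    )


def calibrate(grid_image: np.ndarray, grid_spacing_mm: float = 1.0
              ) -> float:
    """mm per pixel from a photographed square grid (graph paper).

    Grid lines are darker than the paper; the mean intensity profile along
    each axis dips at each line. The median peak-to-peak spacing over both
    axes converts the known grid pitch to mm/px. Fewer than 3 detectable
    lines on either axis is a calibration failure.
    """
    grid_image = np.asarray(grid_image, dtype=float)
    spacings = []
    for axis in (0, 1):
        profile = grid_image.mean(axis=axis)
        inverted = profile.max() - profile
        if np.ptp(inverted) == 0:
            raise CalibrationError("grid image has no contrast")
        peaks, _ = find_peaks(inverted, prominence=0.25 * np.ptp(inverted))
        if peaks.size < 3:
            raise CalibrationError(
                f"only {peaks.size} grid lines found along axis {axis} "
                "(need >= 3)")
        spacings.append(np.median(np.diff(peaks)))
    return grid_spacing_mm / float(np.median(spacings))


def classify_walker(track: BodyTrack, crit: WalkingCriterion | None = None
                    ) -> bool:
    """Walking verdict: path length >= threshold x body length (inclusive).

    When the leg-order criterion is required, the manual T3-T2-T1
    annotation must be supplied and must be true as well.
    """
    crit = crit or WalkingCriterion()
    if track.body_length_px is None or track.body_length_px <= 0:
        raise ValueError("track has no positive body length")
    path_ok = (track.path_length_px
               >= crit.min_path_body_lengths * track.body_length_px)
    if crit.require_leg_sequence:
        if crit.leg_sequence_annotation is None:
            raise ValueError("leg-sequence criterion required but no "
                             "annotation supplied")
        return path_ok and crit.leg_sequence_annotation
    return path_ok


def render_overlay(video: VideoStack, track: BodyTrack,
                   marker_radius: int = 2, draw_trace: bool = True
                   ) -> np.ndarray:
    """RGB stack with a red centroid marker (and cumulative trace) per frame.

    Invalid frames get no marker. Intended for manual inspection of
    tracking quality, mirroring the annotated-movie QC step.
    """
    if len(track.valid) != video.n_frames:
        raise ValueError("track and video lengths differ")
    h, w = video.frames.shape[1:]
    rgb = np.repeat((np.clip(video.frames, 0, 1) * 255)
                    .astype(np.uint8)[..., None], 3, axis=-1)
    yy, xx = np.mgrid[0:h, 0:w]
    past: list[tuple[int, int]] = []
    for i in range(video.n_frames):
        if not track.valid[i]:
            continue
        cx, cy = track.centroids_px[i]
        if draw_trace:
            past.append((int(round(cx)), int(round(cy))))
            for px, py in past:
                if 0 <= py < h and 0 <= px < w:
                    rgb[i, py, px] = (255, 0, 0)
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= marker_radius ** 2
        rgb[i][disk] = (255, 0, 0)
    return rgb


def save_track(track: BodyTrack, out_dir: str | Path,
               verdict: bool | None = None) -> None:
    """Write track CSV and verdict JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track.to_dataframe().to_csv(out / "track.csv", index=False)
    payload = {
        "path_length_px": track.path_length_px,
        "path_length_mm": track.path_length_mm,
        "body_length_px": track.body_length_px,
        "body_length_mm": track.body_length_mm,
        "n_frames": int(len(track.valid)),
        "n_valid": int(track.valid.sum()),
    }
    if verdict is not None:
        payload["walked"] = bool(verdict)
    (out / "verdict.json").write_text(json.dumps(payload, indent=2))
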