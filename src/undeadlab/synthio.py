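"""Synthetic inputs with known ground truth for every pipeline stage.

Generators for: (1) overhead videos of a dark fly-shaped blob moving on a
bright calibrated arena, (2) spherical-treadmill sessions with a two-state
(walk/rest) Markov bout structure driving ball rotations and a
kernel-convolved activity fluorescence channel next to an
activity-independent reference channel, (3) labelled neuroblast-lineage
snapshots in which dying cells advance through death stages with distance
from the neuroblast, and (4) paired numeric samples from several
distribution families for exercising the two-group statistics decision
tree.

Every generator is a pure function of its spec, including the seed.
Defaults emulate the recording conditions the analyses assume: 25 fps
video, a ~2.5 mm decapitated-fly body, walk bouts of a few seconds with
forward speeds around 8 mm/s, calcium-indicator-like transients
(fast rise, ~1 s decay) riding on a constant-ratio baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .kinematics import (BallTrace, BehaviourEpochs, KinematicsConfig)
from .tracking import VideoStack

__all__ = [
    "TrajectorySpec",
    "OpticsSpec",
    "BoutSpec",
    "CouplingSpec",
    "LineageSpec",
    "TwoGroupSpec",
    "BehaviourSession",
    "gen_fly_video",
    "gen_treadmill_session",
    "gen_lineage_population",
    "gen_two_group_samples",
]


# ---------------------------------------------------------------------------
# Fly arena videos
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Path of the fly centroid over the arena.

    kind: stationary | straight | circular | random-walk. Speeds in mm/s,
    turn rate in deg/s, start pose (x mm, y mm, heading deg).
    """

    kind: str = "straight"
    speed: float = 3.0
    turn_rate: float = 60.0
    duration: float = 2.0
    start_pose: tuple[float, float, float] = (3.0, 6.4, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("stationary", "straight", "circular",
                             "random-walk"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")


@dataclass(frozen=True)
class OpticsSpec:
    """Camera and rendering model of the arena video."""

    frame_size: tuple[int, int] = (128, 128)  # (height, width) px
    mm_per_px: float = 0.1
    fps: float = 25.0
    body_axes: tuple[float, float] = (2.5, 1.2)  # (major, minor) mm
    background_level: float = 0.85
    body_level: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0 or self.fps <= 0:
            raise ValueError("mm_per_px and fps must be positive")
        if self.body_level == self.background_level:
            raise ValueError("body must contrast with the background")

    @property
    def body_length_mm(self) -> float:
        return self.body_axes[0]


def _trajectory_path(traj: TrajectorySpec, fps: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-frame (x, y, heading) in mm/deg at frame times i/fps."""
    n = max(1, int(round(traj.duration * fps)))
    x, y, heading = traj.start_pose
    dt = 1.0 / fps
    poses = np.empty((n, 3))
    for i in range(n):
        poses[i] = (x, y, heading)
        if traj.kind == "stationary":
            continue
        if traj.kind == "circular":
            heading += traj.turn_rate * dt
        elif traj.kind == "random-walk":
            heading += rng.normal(0.0, traj.turn_rate) * dt
        rad = np.deg2rad(heading)
        x += traj.speed * dt * np.cos(rad)
        y += traj.speed * dt * np.sin(rad)
    return poses


def gen_fly_video(traj: TrajectorySpec, optics: OpticsSpec
                  ) -> tuple[VideoStack, pd.DataFrame]:
    """Render a fly-as-ellipse video plus its exact centroid ground truth.

    Each frame paints a filled ellipse (major axis = body length, rotated to
    the heading) at the trajectory pose on a uniform background, then adds
    Gaussian pixel noise clipped to [0, 1]. Returns the video and a ground
    truth table (frame, x_mm, y_mm, x_px, y_px, heading_deg).

    Raises if the body would leave the frame, naming the first offending
    frame.
    """
    rng = np.random.default_rng(optics.seed)
    poses = _trajectory_path(traj, optics.fps, rng)
    h, w = optics.frame_size
    major_px = optics.body_axes[0] / 2 / optics.mm_per_px
    minor_px = optics.body_axes[1] / 2 / optics.mm_per_px

    frames = np.full((len(poses), h, w), optics.background_level)
    for i, (x_mm, y_mm, heading) in enumerate(poses):
        cx, cy = x_mm / optics.mm_per_px, y_mm / optics.mm_per_px
        if (cx - major_px < 0 or cy - major_px < 0
                or cx + major_px > w - 1 or cy + major_px > h - 1):
            raise ValueError(
                f"trajectory leaves the frame at frame {i} "
                f"(centre {cx:.1f}, {cy:.1f} px)")
        rr, cc = draw_ellipse(cy, cx, minor_px, major_px,
                              shape=(h, w), rotation=np.deg2rad(heading))
        frames[i, rr, cc] = optics.body_level
    if optics.noise_sd > 0:
        frames = np.clip(
            frames + rng.normal(0.0, optics.noise_sd, frames.shape), 0, 1)

    truth = pd.DataFrame({
        "frame": np.arange(len(poses)),
        "x_mm": poses[:, 0],
        "y_mm": poses[:, 1],
        "x_px": poses[:, 0] / optics.mm_per_px,
        "y_px": poses[:, 1] / optics.mm_per_px,
        "heading_deg": poses[:, 2],
    })
    video = VideoStack(frames=frames, fps=optics.fps,
                       mm_per_px=optics.mm_per_px)
    return video, truth


# ---------------------------------------------------------------------------
# Treadmill sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutSpec:
    """Two-state Markov walk/rest bout structure of a treadmill session."""

    p_start: float = 0.02   # per-frame rest -> walk
    p_stop: float = 0.05    # per-frame walk -> rest
    walk_speed_dist: tuple[float, float] = (8.0, 2.0)   # mm/s (mean, sd)
    rot_dist: tuple[float, float] = (40.0, 20.0)        # deg/s (mean, sd)
    duration: float = 120.0  # s
    fps: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_start <= 1 and 0 <= self.p_stop <= 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")


@dataclass(frozen=True)
class CouplingSpec:
    """Coupling of the activity channel to the walking state."""

    transient_amplitude: float = 0.5  # fractional dR/R at kernel peak
    rise_tau: float = 0.2             # s
    decay_tau: float = 1.0            # s
    baseline_ratio: float = 1.0
    channel_noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be positive")


@dataclass
class BehaviourSession:
    """Synchronized ball rotations, two-channel fluorescence and ground truth."""

    data: pd.DataFrame  # frame, t_s, rot_fwd, rot_side, rot_yaw,
                        # F_activity, F_reference, gt_state
    fps: float
    gt_epochs: BehaviourEpochs
    bouts: BoutSpec
    coupling: CouplingSpec

    def ball_trace(self) -> BallTrace:
        return BallTrace.from_dataframe(self.data, fps=self.fps)


def indicator_kernel(rise_tau: float, decay_tau: float, fps: float,
                     duration_s: float = 8.0) -> np.ndarray:
    """Difference-of-exponentials transient kernel, unit peak.

    k(t) = exp(-t/decay) - exp(-t/rise), the standard calcium-indicator
    impulse shape, sampled at the frame rate and normalised so its maximum
    is 1.
    """
    t = np.arange(int(duration_s * fps)) / fps
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = k.max()
    if peak <= 0:  # rise >= decay: flip sign so the kernel stays positive
        k = -k
        peak = k.max()
    return k / peak


def simulate_state_chain(p_start: float, p_stop: float, n: int,
                         rng: np.random.Generator,
                         initial: int = 0) -> np.ndarray:
    """Two-state Markov chain: 0 = rest, 1 = walk, one draw per frame."""
    state = np.empty(n, dtype=int)
    s = initial
    u = rng.random(n)
    for i in range(n):
        state[i] = s
        if s == 0:
            s = 1 if u[i] < p_start else 0
        else:
            s = 0 if u[i] < p_stop else 1
    return state


def _epochs_from_states(states: np.ndarray) -> BehaviourEpochs:
    labels = np.where(states == 1, "walking", "resting")
    epochs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            epochs.append((start, i, str(labels[start])))
            start = i
    return BehaviourEpochs(epochs=epochs, n_frames=len(labels),
                           labels=labels)


def gen_treadmill_session(bouts: BoutSpec, coupling: CouplingSpec,
                          kin_cfg: KinematicsConfig | None = None
                          ) -> BehaviourSession:
    """Simulate a treadmill session with ground-truth walking epochs.

    While walking, forward speed is drawn per frame from walk_speed_dist and
    yaw from rot_dist (sideways speed from a zero-mean normal with the walk
    sd); speeds convert to ball rotation rates through the kinematics
    constants. Resting frames have zero rotation. The activity channel is
    baseline x (1 + amplitude * (kernel (x) walk-state)) x noise and the
    reference channel constant x noise, both with multiplicative Gaussian
    noise of the configured CV.
    """
    kin_cfg = kin_cfg or KinematicsConfig()
    rng = np.random.default_rng(bouts.seed)
    fluo_rng = np.random.default_rng((coupling.seed, bouts.seed))
    n = max(1, int(round(bouts.duration * bouts.fps)))
    state = simulate_state_chain(bouts.p_start, bouts.p_stop, n, rng)

    mean_v, sd_v = bouts.walk_speed_dist
    mean_r, sd_r = bouts.rot_dist
    v_fwd = np.where(state == 1,
                     np.clip(rng.normal(mean_v, sd_v, n), 0, None), 0.0)
    v_side = np.where(state == 1, rng.normal(0.0, sd_v, n), 0.0)
    v_yaw = np.where(state == 1, rng.normal(mean_r, sd_r, n), 0.0)

    kernel = indicator_kernel(coupling.rise_tau, coupling.decay_tau,
                              bouts.fps)
    drive = np.convolve(state.astype(float), kernel)[:n]
    drive /= max(drive.max(), 1.0)  # unit peak for sustained walking
    ref_level = 100.0
    act_clean = (coupling.baseline_ratio * ref_level
                 * (1.0 + coupling.transient_amplitude * drive))
    cv = coupling.channel_noise_cv
    act = act_clean * (1.0 + fluo_rng.normal(0.0, cv, n)) if cv > 0 else act_clean
    ref = (ref_level * (1.0 + fluo_rng.normal(0.0, cv, n)) if cv > 0
           else np.full(n, ref_level))

    data = pd.DataFrame({
        "frame": np.arange(n),
        "t_s": np.arange(n) / bouts.fps,
        "rot_fwd": v_fwd / kin_cfg.mm_per_rotation,
        "rot_side": v_side / kin_cfg.mm_per_rotation,
        "rot_yaw": v_yaw / kin_cfg.deg_per_rotation,
        "F_activity": act,
        "F_reference": ref,
        "gt_state": np.where(state == 1, "walking", "resting"),
        "gt_drive": drive,
    })
    return BehaviourSession(data=data, fps=bouts.fps,
                            gt_epochs=_epochs_from_states(state),
                            bouts=bouts, coupling=coupling)


# ---------------------------------------------------------------------------
# Lineage snapshots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineageSpec:
    """Labelled-lineage snapshot generator settings.

    ``n_labelled`` may be an int or an inclusive (low, high) range sampled
    per lineage. ``p_doomed_cell`` is the per-cell death probability; with
    10-20 labelled cells, p = 1.3/15 reproduces the observed ~1.3 dying
    cells per lineage on average.
    """

    n_labelled: int | tuple[int, int] = (10, 20)
    p_doomed_cell: float = 1.3 / 15.0
    nb_position: tuple[float, float] = (0.0, 0.0)
    cell_spacing: float = 3.0  # um between consecutive cells
    stage_vs_distance_slope: float = 0.02  # translocation-index units / um
    seed: int = 0

    def __post_init__(self) -> None:
        lo = (self.n_labelled if isinstance(self.n_labelled, int)
              else self.n_labelled[0])
        if lo < 1:
            raise ValueError("n_labelled must be >= 1")
        if not 0 <= self.p_doomed_cell <= 1:
            raise ValueError("p_doomed_cell must lie in [0, 1]")


def gen_lineage_population(spec: LineageSpec, n_lineages: int = 1
                           ) -> list[pd.DataFrame]:
    """Generate lineage snapshots as per-cell intensity tables.

    Cells sit at increasing distance from the neuroblast (oldest furthest).
    Doomed cells carry a nuclear:membrane reporter split whose nuclear
    fraction grows with distance at ``stage_vs_distance_slope`` (death
    advances with cell age); surviving cells are membrane-dominant. Columns:
    lineage_id, cell_id, distance_um, venus_nuc, venus_mem, rfp_mem,
    gt_doomed.
    """
    rng = np.random.default_rng(spec.seed)
    snapshots = []
    for lid in range(n_lineages):
        if isinstance(spec.n_labelled, int):
            n_cells = spec.n_labelled
        else:
            n_cells = int(rng.integers(spec.n_labelled[0],
                                       spec.n_labelled[1] + 1))
        distances = spec.cell_spacing * (1 + np.arange(n_cells)) \
            + rng.normal(0, 0.2, n_cells)
        doomed = rng.random(n_cells) < spec.p_doomed_cell
        total_venus = rng.normal(1000.0, 50.0, n_cells).clip(min=1.0)
        # survivors keep the reporter at the membrane; doomed cells shift it
        # nucleus-ward the further (older) they are
        index = np.where(
            doomed,
            np.clip(0.35 + spec.stage_vs_distance_slope * distances
                    + rng.normal(0, 0.05, n_cells), 0.0, 1.0),
            rng.uniform(0.0, 0.15, n_cells),
        )
        snapshots.append(pd.DataFrame({
            "lineage_id": lid,
            "cell_id": np.arange(n_cells),
            "distance_um": distances,
            "venus_nuc": index * total_venus,
            "venus_mem": (1 - index) * total_venus,
            "rfp_mem": rng.normal(800.0, 40.0, n_cells).clip(min=1.0),
            "gt_doomed": doomed,
        }))
    return snapshots


# ---------------------------------------------------------------------------
# Two-group numeric samples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoGroupSpec:
    """Paired numeric samples for the two-group decision tree.

    Families: ``normal`` (same distribution), ``shifted-normal`` (group 2
    mean-shifted by ``shift``), ``heteroscedastic-normal`` (group 2 scale
    multiplied by sqrt(var_ratio)), ``heavy-tailed`` (log-normal with
    ``sigma``), ``separated`` (group 2 entirely above group 1).
    """

    family: str = "normal"
    n1: int = 20
    n2: int = 20
    loc: float = 0.0
    scale: float = 1.0
    shift: float = 1.0
    var_ratio: float = 10.0
    sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("both groups need n >= 1")


def gen_two_group_samples(spec: TwoGroupSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw two reproducible samples from the configured family."""
    rng = np.random.default_rng(spec.seed)
    if spec.family == "normal":
        return (rng.normal(spec.loc, spec.scale, spec.n1),
                rng.normal(spec.loc, spec.scale, spec.n2))
    if spec.family == "shifted-normal":
        return (rng.normal(spec.loc, spec.scale, spec.n1),
                rng.normal(spec.loc + spec.shift, spec.scale, spec.n2))
    if spec.family == "heteroscedastic-normal":
        return (rng.normal(spec.loc, spec.scale, spec.n1),
                rng.normal(spec.loc, spec.scale * np.sqrt(spec.var_ratio),
                           spec.n2))
    if spec.family == "heavy-tailed":
        return (rng.lognormal(spec.loc, spec.sigma, spec.n1),
                rng.lognormal(spec.loc, spec.sigma, spec.n2))
    if spec.family == "separated":
        x = rng.normal(spec.loc, spec.scale, spec.n1)
        y = rng.normal(spec.loc, spec.scale, spec.n2)
        return x, y + (x.max() - y.min()) + spec.shift
    raise ValueError(f"unknown sample family {spec.family!r}")
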