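"""Synthetic reach-task imaging sessions with known ground truth.

This module generates everything the downstream analyses consume: a delayed
center-out reach task (4 radial targets at 10 cm, randomized 100-700 ms delay,
reaction times accepted in a 180-620 ms window), 60 Hz hand kinematics built
from minimum-jerk point-to-point reaches, a population of dendritic / somatic
regions of interest with rectified-cosine direction tuning, and single-plane
fluorescence movies with GCaMP6f-like exponential calcium kinetics
(decay time constant 0.7 s), shot-noise-like pixel noise and optional rigid
in-plane motion jitter.

All randomness flows through a caller-supplied :class:`numpy.random.Generator`
(or the ``rng_seed`` field of :class:`SessionConfig`), so identical
configurations regenerate bit-identical sessions.

Conventions: pixel indices are 0-based ``(row, col)``; angles are degrees
counterclockwise from the +x axis; times are milliseconds on a single session
clock starting at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import ndimage as _ndimage

from .errors import AlignmentError, ConfigError

__all__ = [
    "SessionConfig",
    "GroundTruthROI",
    "HandTrajectory",
    "ImagingMovie",
    "SimulatedSession",
    "minimum_jerk_position",
    "minimum_jerk_speed",
    "minimum_jerk_peak_speed",
    "generate_trials",
    "generate_ground_truth",
    "roi_drive",
    "calcium_from_drive",
    "simulate_roi_trace",
    "render_movie",
    "render_control_movie",
    "simulate_session",
    "stage_rng",
]

TRIAL_COLUMNS = [
    "trial_id",
    "target_index",
    "target_angle_deg",
    "target_onset_ms",
    "go_cue_ms",
    "movement_onset_ms",
    "target_acquire_ms",
    "trial_end_ms",
    "reaction_time_ms",
    "success",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named RNG substream: one global seed, independent stream per stage.

    Changing which stage names are drawn from does not perturb the streams of
    other stages, because each stream is keyed by (seed, hash(stage)).
    """
    key = np.frombuffer(stage.encode("utf8"), dtype=np.uint8)
    ss = np.random.SeedSequence([int(seed), *key.tolist()])
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SessionConfig:
    """Parameters of one simulated imaging + behavior session.

    Defaults are desk-scale: a 128x128 field of view keeps a full session in
    memory; the instrument geometry of the emulated rig (512x512 at 30.3 Hz)
    is available by overriding ``fov_height_px``/``fov_width_px``.
    """

    fov_height_px: int = 128
    fov_width_px: int = 128
    frame_rate: float = 30.3           # Hz
    n_targets: int = 4
    target_distance_cm: float = 10.0
    delay_range_ms: tuple[float, float] = (100.0, 700.0)
    rt_range_ms: tuple[float, float] = (180.0, 620.0)
    # uniform over the accepted range by default; "truncnorm" concentrates RTs
    # the way trained primates do (mean/sd below, truncated to the range)
    rt_distribution: Literal["uniform", "truncnorm"] = "uniform"
    rt_mean_ms: float = 300.0
    rt_sd_ms: float = 60.0
    n_trials_per_target: int = 40
    hand_rate: float = 60.0            # Hz
    motion_jitter_px: int = 1          # max |shift| per axis, 0 disables
    subpixel_jitter: bool = False
    noise_model: Literal["gaussian", "poisson", "none"] = "gaussian"
    noise_scale: float = 1.0           # SD = noise_scale * sqrt(mean) (gaussian)
    background: float = 20.0           # neuropil / offset fluorescence, a.u.
    rng_seed: int = 0

    # trial timeline (ms)
    center_hold_ms: float = 400.0
    move_duration_ms: float = 300.0
    hold_duration_ms: float = 200.0
    # slower return reach (lower drive) and an inter-trial interval long
    # enough for indicator fluorescence (tau 0.7 s) to decay before the next
    # trial's pre-event baseline windows
    return_duration_ms: float = 500.0
    iti_ms: float = 2000.0

    # ground-truth ROI population
    n_dendritic: int = 20
    n_somatic: int = 8
    n_puncta: int = 30                 # control-mode FOVs only
    gain_range: tuple[float, float] = (0.015, 0.03)   # dF/F per (cm/s)
    somatic_gain_scale: float = 1.0
    cis_gain: float = 0.2              # peri-movement dF/F bump amplitude
    baseline_f0_range: tuple[float, float] = (80.0, 120.0)
    puncta_f0: float = 300.0
    tau_decay_s: float = 0.7
    lag_ms: float = 50.0
    hand_noise_cm: float = 0.0         # tracker noise SD; 0 keeps onset rule exact

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fov_height_px < 16 or self.fov_width_px < 16:
            raise ConfigError("FOV must be at least 16x16 pixels")
        if self.frame_rate <= 0 or self.hand_rate <= 0:
            raise ConfigError("frame_rate and hand_rate must be positive")
        if self.n_targets < 2:
            raise ConfigError("need at least 2 targets")
        if self.n_trials_per_target < 1:
            raise ConfigError("need at least 1 trial per target")
        lo, hi = self.delay_range_ms
        if not (0 <= lo <= hi):
            raise ConfigError("invalid delay range")
        rlo, rhi = self.rt_range_ms
        if not (0 < rlo < rhi):
            raise ConfigError("invalid reaction-time range")
        if self.motion_jitter_px < 0 or self.motion_jitter_px > 2:
            raise ConfigError("motion jitter limited to 0-2 px")
        if self.tau_decay_s <= 0:
            raise ConfigError("tau_decay_s must be positive")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")

    @property
    def target_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_targets) * (360.0 / self.n_targets)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        for k in ("delay_range_ms", "rt_range_ms", "gain_range", "baseline_f0_range"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class HandTrajectory:
    """Uniformly sampled 2-D hand kinematics (cm, cm/s) on the session clock."""

    timestamps_ms: np.ndarray
    position_cm: np.ndarray   # (N, 2)
    velocity_cmps: np.ndarray  # (N, 2), centered finite difference

    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity_cmps[:, 0], self.velocity_cmps[:, 1])

    def velocity_at(self, t_ms: np.ndarray) -> np.ndarray:
        """Linear interpolation of (vx, vy) at arbitrary times."""
        vx = np.interp(t_ms, self.timestamps_ms, self.velocity_cmps[:, 0])
        vy = np.interp(t_ms, self.timestamps_ms, self.velocity_cmps[:, 1])
        return np.column_stack([vx, vy])


@dataclass
class GroundTruthROI:
    """One fluorescence source with known footprint and tuning."""

    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray
    shape_class: Literal["dendritic", "somatic", "punctum"]
    pd_deg: float
    gain: float               # dF/F per (cm/s) of PD-aligned velocity
    baseline_f0: float        # a.u.
    cis_gain: float           # dF/F amplitude of peri-movement bump
    tau_decay_s: float = 0.7
    lag_ms: float = 50.0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0):
            raise ConfigError("footprint weights must be non-negative")
        if self.tau_decay_s <= 0:
            raise ConfigError("tau_decay_s must be positive")
        if self.shape_class == "punctum" and (self.gain != 0 or self.cis_gain != 0):
            raise ConfigError("puncta must be non-modulated (gain = cis_gain = 0)")

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    def footprint_image(self, shape: tuple[int, int]) -> np.ndarray:
        img = np.zeros(shape, dtype=np.float64)
        img[self.rows, self.cols] = self.weights
        return img

    def to_jsonable(self) -> dict:
        return {
            "rows": self.rows.tolist(),
            "cols": self.cols.tolist(),
            "weights": self.weights.tolist(),
            "shape_class": self.shape_class,
            "pd_deg": float(self.pd_deg),
            "gain": float(self.gain),
            "baseline_f0": float(self.baseline_f0),
            "cis_gain": float(self.cis_gain),
            "tau_decay_s": float(self.tau_decay_s),
            "lag_ms": float(self.lag_ms),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "GroundTruthROI":
        return cls(**d)


def save_ground_truth(rois: Sequence[GroundTruthROI], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_jsonable() for r in rois], fh)


def load_ground_truth(path) -> list[GroundTruthROI]:
    with open(path) as fh:
        return [GroundTruthROI.from_jsonable(d) for d in json.load(fh)]


@dataclass
class ImagingMovie:
    """Time-ordered stack of single-channel fluorescence frames."""

    frames: np.ndarray          # (T, H, W) float32, a.u., >= 0
    frame_times_ms: np.ndarray  # (T,) frame start times
    frame_rate: float
    shifts: np.ndarray | None = None  # (T, 2) applied (drow, dcol) jitter

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ConfigError("frames must be (T, H, W)")
        if self.frames.shape[0] != self.frame_times_ms.shape[0]:
            raise AlignmentError("frame count does not match timestamps")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fov_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SimulatedSession:
    """Bundle of everything one simulated session produced."""

    config: SessionConfig
    trials: pd.DataFrame
    hand: HandTrajectory
    truth: list[GroundTruthROI]
    movie: ImagingMovie


# ---------------------------------------------------------------------------
# Minimum-jerk kinematics
# ---------------------------------------------------------------------------


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement profile on tau in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """d/dtau of the minimum-jerk profile (peak 1.875 at tau = 0.5)."""
    tau = np.asarray(tau, dtype=float)
    out = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return np.where((tau < 0) | (tau > 1), 0.0, out)


def minimum_jerk_peak_speed(amplitude_cm: float, duration_s: float) -> float:
    """Closed-form peak speed of a minimum-jerk reach: 1.875 * D / T (cm/s)."""
    return 1.875 * amplitude_cm / duration_s


def _min_jerk_5pct_offset_frac() -> float:
    """Fraction of movement duration at which speed first exceeds 5% of peak."""
    # solve 30 t^2 (1-t)^2 = 0.05 * 1.875 on (0, 0.5)
    from scipy.optimize import brentq

    return brentq(lambda t: 30 * t**2 * (1 - t) ** 2 - 0.09375, 1e-9, 0.5)


_T5_FRAC = 0.0594341  # cached root of the equation above (see tests)


# ---------------------------------------------------------------------------
# Behavior generation
# ---------------------------------------------------------------------------


def generate_trials(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, HandTrajectory]:
    """Generate a balanced delayed center-out session and its hand kinematics.

    Targets are interleaved in random order with exactly
    ``n_trials_per_target`` trials each.  Delays are uniform on
    ``delay_range_ms``; behavioral reaction times are uniform on the accepted
    window shrunk by a 20 ms guard band, so that the kinematically recomputed
    onset (first 5%-of-peak-speed crossing of the sampled hand speed) always
    lands inside the accepted 180-620 ms window.  Reaches are minimum-jerk
    center-out-and-back movements of ``target_distance_cm`` amplitude.

    ``movement_onset_ms`` in the returned table is *recomputed* from the
    sampled trajectory, not copied from the generative schedule.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    K = config.n_targets
    n_trials = K * config.n_trials_per_target
    order = rng.permutation(np.repeat(np.arange(K), config.n_trials_per_target))
    angles = config.target_angles_deg

    delays = rng.uniform(*config.delay_range_ms, size=n_trials)
    rlo, rhi = config.rt_range_ms
    if config.rt_distribution == "uniform":
        rts_nominal = rng.uniform(rlo + 20.0, rhi - 20.0, size=n_trials)
    else:  # truncated normal inside the accepted window (20 ms guard band)
        a = (rlo + 20.0 - config.rt_mean_ms) / config.rt_sd_ms
        b = (rhi - 20.0 - config.rt_mean_ms) / config.rt_sd_ms
        from scipy import stats as _st

        rts_nominal = _st.truncnorm.rvs(
            a, b, loc=config.rt_mean_ms, scale=config.rt_sd_ms,
            size=n_trials, random_state=rng,
        )

    dt_hand = 1000.0 / config.hand_rate
    move_T = config.move_duration_ms
    t5 = _T5_FRAC * move_T

    # schedule events on the session clock
    rows = []
    t = config.center_hold_ms
    segments: list[tuple[float, float, float, float]] = []  # (start, dur, angle, sign)
    for i in range(n_trials):
        k = int(order[i])
        target_onset = t
        go = target_onset + delays[i]
        move_start = go + rts_nominal[i] - t5
        acquire = move_start + move_T
        ret_start = acquire + config.hold_duration_ms
        ret_end = ret_start + config.return_duration_ms
        trial_end = ret_end + config.iti_ms
        segments.append((move_start, move_T, angles[k], +1.0))
        segments.append((ret_start, config.return_duration_ms, angles[k], -1.0))
        rows.append(
            dict(
                trial_id=i,
                target_index=k,
                target_angle_deg=float(angles[k]),
                target_onset_ms=target_onset,
                go_cue_ms=go,
                movement_onset_ms=np.nan,  # filled below from kinematics
                target_acquire_ms=acquire,
                trial_end_ms=trial_end,
                reaction_time_ms=np.nan,
                success=True,
            )
        )
        t = trial_end

    session_end = t + config.center_hold_ms
    ts = np.arange(0.0, session_end, dt_hand)
    pos = np.zeros((ts.size, 2))
    steps = np.zeros_like(pos)  # completed-displacement steps, cumsum'd below
    for start, dur, ang, sign in segments:
        # each segment is a displacement of +/- D along the target direction:
        # partial during the movement, full once it has completed
        i0 = np.searchsorted(ts, start, side="right")
        i1 = np.searchsorted(ts, start + dur, side="left")
        tau = (ts[i0:i1] - start) / dur
        prof = minimum_jerk_position(tau)
        u = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
        D = sign * config.target_distance_cm
        pos[i0:i1] += D * prof[:, None] * u[None, :]
        if i1 < steps.shape[0]:
            steps[i1] += D * u
    pos += np.cumsum(steps, axis=0)

    if config.hand_noise_cm > 0:
        pos = pos + rng.normal(0.0, config.hand_noise_cm, size=pos.shape)

    vel = np.gradient(pos, ts / 1000.0, axis=0)
    hand = HandTrajectory(timestamps_ms=ts, position_cm=pos, velocity_cmps=vel)
    speed = hand.speed()

    trials = pd.DataFrame(rows)
    onset, rt = _recompute_movement_onset(trials, ts, speed)
    trials["movement_onset_ms"] = onset
    trials["reaction_time_ms"] = rt
    trials["success"] = (rt >= rlo) & (rt <= rhi)
    return trials[TRIAL_COLUMNS], hand


def _recompute_movement_onset(
    trials: pd.DataFrame, ts: np.ndarray, speed: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First time in-plane speed crosses 5% of per-trial peak, interpolated."""
    onsets = np.full(len(trials), np.nan)
    for i, tr in enumerate(trials.itertuples()):
        i0 = np.searchsorted(ts, tr.go_cue_ms, side="left")
        i1 = np.searchsorted(ts, tr.target_acquire_ms + 50.0, side="right")
        if i1 <= i0:
            continue
        sw, tw = speed[i0:i1], ts[i0:i1]
        peak = sw.max()
        if peak <= 0:
            continue
        thresh = 0.05 * peak
        above = sw >= thresh
        idx = np.argmax(above)
        if not above[idx]:
            continue
        if idx == 0:
            onsets[i] = tw[0]
        else:
            # linear interpolation of the crossing between samples
            s0, s1 = sw[idx - 1], sw[idx]
            frac = (thresh - s0) / (s1 - s0)
            onsets[i] = tw[idx - 1] + frac * (tw[idx] - tw[idx - 1])
    rts = onsets - trials["go_cue_ms"].to_numpy()
    return onsets, rts


# ---------------------------------------------------------------------------
# Ground-truth ROI generation
# ---------------------------------------------------------------------------


def _dendrite_footprint(
    rng: np.random.Generator, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Elongated footprint: Gaussian tube around a random line segment."""
    H, W = shape
    length = rng.uniform(0.14, 0.28) * min(H, W)
    length = max(length, 12.0)
    width = rng.uniform(0.8, 1.2)
    ang = rng.uniform(0, np.pi)
    margin = length / 2 + 3
    cr = rng.uniform(margin, H - margin)
    cc = rng.uniform(margin, W - margin)
    dr, dc = np.sin(ang), np.cos(ang)
    half = int(np.ceil(length / 2 + 3 * width))
    r0, r1 = int(max(0, cr - half)), int(min(H, cr + half + 1))
    c0, c1 = int(max(0, cc - half)), int(min(W, cc + half + 1))
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    # distance along / across the segment axis
    u = (rr - cr) * dr + (cc_ - cc) * dc
    v = -(rr - cr) * dc + (cc_ - cc) * dr
    along = np.clip(np.abs(u) - length / 2, 0, None)
    d2 = along**2 + v**2
    w = np.exp(-d2 / (2 * width**2))
    keep = w > 0.05
    return rr[keep], cc_[keep], w[keep]


def _disk_footprint(
    rng: np.random.Generator, shape: tuple[int, int], radius_range=(3.0, 5.0)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Roughly circular footprint with a soft edge (soma-like)."""
    H, W = shape
    radius = rng.uniform(*radius_range)
    margin = radius + 3
    cr = rng.uniform(margin, H - margin)
    cc = rng.uniform(margin, W - margin)
    half = int(np.ceil(radius + 3))
    r0, r1 = int(max(0, cr - half)), int(min(H, cr + half + 1))
    c0, c1 = int(max(0, cc - half)), int(min(W, cc + half + 1))
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - cr, cc_ - cc)
    w = 1.0 / (1.0 + np.exp((d - radius) / 0.6))
    keep = w > 0.05
    return rr[keep], cc_[keep], w[keep]


def generate_ground_truth(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    control: bool = False,
) -> list[GroundTruthROI]:
    """Draw the ground-truth ROI population for one session.

    Standard mode: ``n_dendritic`` elongated dendritic footprints and
    ``n_somatic`` round somatic footprints, preferred directions uniform on
    [0, 360), velocity gains uniform on ``gain_range``.  Control mode: bright
    autofluorescent puncta with dendrite/soma-like geometry but zero task
    modulation.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    shape = (config.fov_height_px, config.fov_width_px)
    rois: list[GroundTruthROI] = []
    if control:
        for i in range(config.n_puncta):
            if rng.random() < 0.5:
                r, c, w = _dendrite_footprint(rng, shape)
            else:
                r, c, w = _disk_footprint(rng, shape, radius_range=(1.5, 3.5))
            rois.append(
                GroundTruthROI(
                    rows=r, cols=c, weights=w,
                    shape_class="punctum",
                    pd_deg=float(rng.uniform(0, 360)),
                    gain=0.0,
                    baseline_f0=float(config.puncta_f0 * rng.uniform(0.7, 1.3)),
                    cis_gain=0.0,
                    tau_decay_s=config.tau_decay_s,
                    lag_ms=config.lag_ms,
                )
            )
        return rois

    for i in range(config.n_dendritic + config.n_somatic):
        dendritic = i < config.n_dendritic
        if dendritic:
            r, c, w = _dendrite_footprint(rng, shape)
        else:
            r, c, w = _disk_footprint(rng, shape)
        gain = rng.uniform(*config.gain_range)
        if not dendritic:
            gain *= config.somatic_gain_scale
        rois.append(
            GroundTruthROI(
                rows=r, cols=c, weights=w,
                shape_class="dendritic" if dendritic else "somatic",
                pd_deg=float(rng.uniform(0, 360)),
                gain=float(gain),
                baseline_f0=float(rng.uniform(*config.baseline_f0_range)),
                cis_gain=float(config.cis_gain * rng.uniform(0.5, 1.5)),
                tau_decay_s=config.tau_decay_s,
                lag_ms=config.lag_ms,
            )
        )
    return rois


# ---------------------------------------------------------------------------
# Fluorescence dynamics
# ---------------------------------------------------------------------------


def calcium_from_drive(drive: np.ndarray, dt_s: float, tau_s: float) -> np.ndarray:
    """Exponential-decay calcium kinetics.

    ``c[n] = exp(-dt/tau) * c[n-1] + (dt/tau) * drive[n]`` — a first-order
    low-pass whose impulse response decays exactly as ``exp(-t/tau)`` and whose
    steady-state response to a sustained drive ``d`` approaches ``d``.
    """
    if tau_s <= 0:
        raise ConfigError("tau must be positive")
    a = np.exp(-dt_s / tau_s)
    return _signal.lfilter([dt_s / tau_s], [1.0, -a], np.asarray(drive, dtype=float))


def _cis_bump(frame_times: np.ndarray, trials: pd.DataFrame) -> np.ndarray:
    """Condition-independent peri-movement drive: raised cosine around onset."""
    bump = np.zeros_like(frame_times, dtype=float)
    half = 250.0  # ms half-width
    for onset in trials["movement_onset_ms"].to_numpy():
        if not np.isfinite(onset):
            continue
        c = onset + 100.0
        i0 = np.searchsorted(frame_times, c - half, side="right")
        i1 = np.searchsorted(frame_times, c + half, side="left")
        x = (frame_times[i0:i1] - c) / half
        bump[i0:i1] += 0.5 * (1 + np.cos(np.pi * x))
    return bump


def roi_drive(
    roi: GroundTruthROI,
    hand: HandTrajectory,
    trials: pd.DataFrame,
    frame_times: np.ndarray,
    cis_bump: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous drive of one ROI at frame times.

    Directional part: rectified cosine tuning against the hand velocity lagged
    by ``roi.lag_ms`` (fluorescence follows kinematics), i.e.
    ``gain * max(0, v(t - lag) . u_pd)``.  Condition-independent part: a
    peri-movement raised-cosine bump scaled by ``cis_gain`` (precompute it
    once with ``_cis_bump`` when rendering many ROIs).
    """
    v = hand.velocity_at(frame_times - roi.lag_ms)
    u = np.array([np.cos(np.deg2rad(roi.pd_deg)), np.sin(np.deg2rad(roi.pd_deg))])
    directional = roi.gain * np.clip(v @ u, 0.0, None)
    if roi.cis_gain:
        if cis_bump is None:
            cis_bump = _cis_bump(frame_times, trials)
        directional = directional + roi.cis_gain * cis_bump
    return directional


def simulate_roi_trace(
    roi: GroundTruthROI,
    hand: HandTrajectory,
    trials: pd.DataFrame,
    frame_times: np.ndarray,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """dF/F-scale trace of one ROI without rendering pixels.

    Used by calibration and power simulations where only the trace-level
    statistics matter; the noise SD approximates a ~50-pixel footprint average
    at default pixel noise.
    """
    dt = float(np.median(np.diff(frame_times))) / 1000.0
    c = calcium_from_drive(roi_drive(roi, hand, trials, frame_times), dt, roi.tau_decay_s)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        c = c + rng.normal(0.0, noise_sd, size=c.shape)
    return c


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------


def render_movie(
    truth: Sequence[GroundTruthROI],
    trials: pd.DataFrame,
    hand: HandTrajectory,
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    jitter_shifts: np.ndarray | None = None,
) -> ImagingMovie:
    """Render the fluorescence movie for a session.

    Pixel model: ``F = sum_r f0_r * (1 + c_r(t)) * w_r + background``, then
    optional rigid per-frame translation jitter (recorded in
    ``movie.shifts``), then pixel noise according to ``config.noise_model``.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    if len(trials) == 0:
        raise AlignmentError("empty trial table")
    t_end = float(trials["trial_end_ms"].max()) + config.center_hold_ms
    if t_end > hand.timestamps_ms[-1] + 1000.0 / config.hand_rate + 1e-6:
        raise AlignmentError("hand trajectory does not cover the trial span")
    dt_ms = 1000.0 / config.frame_rate
    frame_times = np.arange(0.0, t_end, dt_ms)
    T = frame_times.size
    H, W = config.fov_height_px, config.fov_width_px

    static = np.full((H, W), config.background, dtype=np.float64)
    for roi in truth:
        if roi.rows.size and (roi.rows.max() >= H or roi.cols.max() >= W):
            raise AlignmentError("ROI footprint outside the configured FOV")
        static[roi.rows, roi.cols] += roi.baseline_f0 * roi.weights

    frames = np.empty((T, H, W), dtype=np.float32)
    frames[:] = static.astype(np.float32)
    flat = frames.reshape(T, -1)
    dt_s = dt_ms / 1000.0
    bump = _cis_bump(frame_times, trials) if any(r.cis_gain for r in truth) else None
    for roi in truth:
        drive = roi_drive(roi, hand, trials, frame_times, cis_bump=bump)
        if not np.any(drive):
            continue
        c = calcium_from_drive(drive, dt_s, roi.tau_decay_s)
        idx = roi.rows * W + roi.cols
        flat[:, idx] += c[:, None].astype(np.float32) * (
            roi.baseline_f0 * roi.weights
        ).astype(np.float32)[None, :]

    # rigid in-plane motion jitter (applied before sensor noise)
    if jitter_shifts is not None:
        shifts = np.asarray(jitter_shifts, dtype=float)
        if shifts.shape != (T, 2):
            raise AlignmentError(f"jitter_shifts must have shape ({T}, 2)")
    elif config.motion_jitter_px > 0:
        j = config.motion_jitter_px
        if config.subpixel_jitter:
            shifts = rng.uniform(-j, j, size=(T, 2))
        else:
            shifts = rng.integers(-j, j + 1, size=(T, 2)).astype(float)
    else:
        shifts = np.zeros((T, 2))

    if np.any(shifts):
        integer = np.all(shifts == np.round(shifts))
        if integer:
            # batch frames sharing the same shift: one roll per unique shift
            uniq, inverse = np.unique(shifts.astype(int), axis=0, return_inverse=True)
            for g, (dr, dc) in enumerate(uniq):
                if dr == 0 and dc == 0:
                    continue
                idx = np.flatnonzero(inverse == g)
                frames[idx] = np.roll(frames[idx], (int(dr), int(dc)), axis=(1, 2))
        else:
            for n in range(T):
                dr, dc = shifts[n]
                if dr == 0 and dc == 0:
                    continue
                frames[n] = _ndimage.shift(
                    frames[n], (dr, dc), order=1, mode="grid-wrap"
                )

    if config.noise_model == "gaussian":
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        np.multiply(noise, np.sqrt(frames, dtype=np.float32), out=noise)
        frames += config.noise_scale * noise
        np.clip(frames, 0.0, None, out=frames)
    elif config.noise_model == "poisson":
        frames = rng.poisson(frames).astype(np.float32)

    return ImagingMovie(
        frames=frames,
        frame_times_ms=frame_times,
        frame_rate=config.frame_rate,
        shifts=shifts,
    )


def render_control_movie(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    trials: pd.DataFrame | None = None,
    hand: HandTrajectory | None = None,
) -> tuple[ImagingMovie, list[GroundTruthROI], pd.DataFrame, HandTrajectory]:
    """Control-mode FOV: bright autofluorescent puncta, zero task modulation.

    The task, noise and jitter models are identical to a standard session; only
    the sources differ (no velocity or condition-independent drive), so any
    decoder run on this movie should perform at chance.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    if trials is None or hand is None:
        trials, hand = generate_trials(config, rng)
    truth = generate_ground_truth(config, rng, control=True)
    movie = render_movie(truth, trials, hand, config, rng)
    return movie, truth, trials, hand


def simulate_session(
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    control: bool = False,
) -> SimulatedSession:
    """Convenience wrapper: behavior + ground truth + movie in one call."""
    rng = config.rng() if rng is None else rng
    trials, hand = generate_trials(config, rng)
    truth = generate_ground_truth(config, rng, control=control)
    movie = render_movie(truth, trials, hand, config, rng)
    return SimulatedSession(config=config, trials=trials, hand=hand, truth=truth, movie=movie)
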