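"""Movie and trace preprocessing: registration, blurring, dF/F, z-scoring.

Registration is rigid only (translation by FFT cross-correlation); the
synthetic jitter model is rigid, so non-rigid block-wise alignment is out of
scope here.  dF/F uses an iterative time-varying baseline: a rolling
low-percentile filter, smoothed, re-applied to the transient-clipped trace
until it converges.  Z-scored responses are referenced to a pooled pre-trial
baseline period in which the hand is stationary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as _ndimage
from skimage.registration import phase_cross_correlation

from .errors import InputError, NumericError
from .synth import ImagingMovie

__all__ = [
    "RegisteredMovie",
    "DffTrace",
    "register_rigid",
    "gaussian_blur",
    "compute_dff",
    "zscore_responses",
]


@dataclass
class RegisteredMovie:
    """Motion-corrected movie plus the per-frame shifts that were removed."""

    movie: ImagingMovie
    estimated_shifts: np.ndarray  # (T, 2) (drow, dcol) estimated scene shifts

    @property
    def frames(self) -> np.ndarray:
        return self.movie.frames

    @property
    def frame_times_ms(self) -> np.ndarray:
        return self.movie.frame_times_ms


@dataclass
class DffTrace:
    values: np.ndarray    # dF/F per frame
    baseline: np.ndarray  # F0(t), same length


def register_rigid(
    movie: ImagingMovie,
    reference: np.ndarray | None = None,
    upsample_factor: int = 1,
) -> RegisteredMovie:
    """Estimate and remove per-frame rigid translation.

    Each frame is cross-correlated (FFT) against ``reference`` (default: the
    mean frame); the estimated shift is inverted with a circular shift
    (integer) or a first-order interpolated shift (subpixel, when
    ``upsample_factor > 1``).
    """
    if movie.n_frames == 0:
        raise InputError("cannot register an empty movie")
    frames = movie.frames
    if reference is None:
        reference = frames.mean(axis=0)
    reference = np.asarray(reference, dtype=np.float32)
    if reference.shape != movie.fov_shape:
        raise InputError("reference shape does not match the movie FOV")

    T = movie.n_frames
    shifts = np.zeros((T, 2))
    out = np.empty_like(frames)
    for n in range(T):
        shift, _, _ = phase_cross_correlation(
            reference, frames[n], upsample_factor=upsample_factor,
            normalization=None,
        )
        # phase_cross_correlation returns the shift that maps frame -> reference,
        # i.e. minus the scene displacement applied to this frame
        shifts[n] = -shift
        if np.all(shift == np.round(shift)):
            out[n] = np.roll(frames[n], tuple(int(s) for s in shift), axis=(0, 1))
        else:
            out[n] = _ndimage.shift(frames[n], shift, order=1, mode="grid-wrap")
    registered = ImagingMovie(
        frames=out,
        frame_times_ms=movie.frame_times_ms,
        frame_rate=movie.frame_rate,
        shifts=None,
    )
    return RegisteredMovie(movie=registered, estimated_shifts=shifts)


def gaussian_blur(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Normalized Gaussian low-pass of one frame (reflect boundary, 4-sigma kernel).

    ``sigma_px = 0`` is the identity; the kernel integrates to 1 so constant
    frames are preserved exactly.
    """
    if sigma_px < 0:
        raise InputError("sigma must be non-negative")
    frame = np.asarray(frame)
    if sigma_px == 0:
        return frame.copy()
    return _ndimage.gaussian_filter(
        frame.astype(np.float64), sigma=sigma_px, mode="reflect", truncate=4.0
    ).astype(frame.dtype)


def _rolling_percentile_baseline(
    trace: np.ndarray, window: int, percentile: float
) -> np.ndarray:
    f0 = _ndimage.percentile_filter(trace, percentile, size=window, mode="reflect")
    # smooth the staircase left by the order-statistic filter
    return _ndimage.uniform_filter1d(f0, size=max(window // 2, 1), mode="reflect")


def compute_dff(
    trace: np.ndarray,
    frame_rate: float,
    window_s: float = 30.0,
    percentile: float = 10.0,
    max_iter: int = 3,
    tol: float = 1e-3,
) -> DffTrace:
    """dF/F with an iterative time-varying baseline.

    F0(t) is a rolling ``percentile`` filter over a ``window_s`` window,
    smoothed, and re-estimated on the transient-clipped trace
    ``min(F, F0)`` until the relative change falls below ``tol`` (at most
    ``max_iter`` passes).  dF/F = (F - F0) / F0.
    """
    trace = np.asarray(trace, dtype=np.float64)
    window = int(round(window_s * frame_rate))
    if trace.size <= window:
        raise InputError(
            f"trace ({trace.size} frames) not longer than the baseline window ({window})"
        )
    window = max(window, 3)
    work = trace
    f0 = _rolling_percentile_baseline(work, window, percentile)
    for _ in range(max_iter - 1):
        work = np.minimum(trace, f0)
        f0_new = _rolling_percentile_baseline(work, window, percentile)
        rel = np.max(np.abs(f0_new - f0)) / max(np.max(np.abs(f0)), 1e-12)
        f0 = f0_new
        if rel < tol:
            break
    if np.any((f0 <= 0) & (trace > 0)):
        raise NumericError(
            "non-positive baseline estimate on a positive trace; "
            "check window length and percentile"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(f0 != 0, (trace - f0) / f0, 0.0)
    return DffTrace(values=dff, baseline=f0)


def zscore_responses(
    traces: np.ndarray,
    frame_times_ms: np.ndarray,
    trials: pd.DataFrame,
    baseline_window_ms: tuple[float, float] = (-300.0, 0.0),
    align_column: str = "target_onset_ms",
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score ROI traces against a pooled pre-trial baseline.

    The baseline pool for each ROI is every frame falling in
    ``baseline_window_ms`` relative to ``align_column`` on any trial (the hand
    is stationary there).  Uses the sample (n-1) standard deviation.  ROIs with
    zero baseline SD are returned as NaN rows and flagged.

    Returns ``(z, flagged)`` where ``flagged`` is a boolean per-ROI mask of
    excluded (zero-SD) ROIs.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=np.float64))
    events = trials[align_column].to_numpy()
    mask = np.zeros(frame_times_ms.size, dtype=bool)
    for ev in events:
        if np.isfinite(ev):
            mask |= (frame_times_ms >= ev + baseline_window_ms[0]) & (
                frame_times_ms < ev + baseline_window_ms[1]
            )
    if not np.any(mask):
        raise InputError("no frames fall inside the pre-trial baseline windows")
    base = traces[:, mask]
    mu = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)
    flagged = sd == 0
    if np.any(flagged):
        import warnings

        warnings.warn(
            f"{int(flagged.sum())} ROI(s) have zero baseline SD; z undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (traces - mu[:, None]) / sd[:, None]
    z[flagged] = np.nan
    return z, flagged
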