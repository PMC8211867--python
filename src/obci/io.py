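"""Readers and writers for the pipeline's on-disk artifacts.

Movies travel in two forms: a 16-bit multi-frame TIFF for interchange (values
rounded, clipped at the uint16 range) and a compressed ``.npz`` container that
round-trips the float frames and timestamps exactly.  Tables (trials, hand
trajectory, shift logs, tuning results) are CSV; ground truth and masks are
JSON (masks additionally as 16-bit label-image TIFF).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .synth import HandTrajectory, ImagingMovie

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_movie_npz",
    "read_movie_npz",
    "write_trials_csv",
    "read_trials_csv",
    "write_hand_csv",
    "read_hand_csv",
    "write_shifts_csv",
    "read_shifts_csv",
    "validate_io_roundtrip",
]

TRIAL_CSV_COLUMNS = [
    "trial_id", "target_index", "target_angle_deg", "target_onset_ms",
    "go_cue_ms", "movement_onset_ms", "target_acquire_ms", "trial_end_ms",
    "reaction_time_ms", "success",
]
HAND_CSV_COLUMNS = ["timestamp_ms", "x_cm", "y_cm", "vx_cmps", "vy_cmps"]


def write_movie_tiff(movie: ImagingMovie, path: str | Path) -> None:
    """Single-channel 16-bit multi-frame TIFF (rounded, clipped to uint16)."""
    data = np.clip(np.round(movie.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack",
                     metadata={"frame_rate_hz": movie.frame_rate})


def read_movie_tiff(path: str | Path, frame_rate: float) -> ImagingMovie:
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # truncated / malformed file
        raise InputError(f"cannot read TIFF movie {path}: {exc}") from exc
    frames = np.atleast_3d(frames)
    if frames.ndim != 3:
        raise InputError(f"expected a (T, H, W) TIFF stack, got shape {frames.shape}")
    dt = 1000.0 / frame_rate
    return ImagingMovie(
        frames=frames.astype(np.float32),
        frame_times_ms=np.arange(frames.shape[0]) * dt,
        frame_rate=frame_rate,
    )


def write_movie_npz(movie: ImagingMovie, path: str | Path) -> None:
    """Exact float container: frames + timestamps (+ applied jitter shifts)."""
    payload = dict(
        frames=movie.frames,
        frame_times_ms=movie.frame_times_ms,
        frame_rate=np.float64(movie.frame_rate),
    )
    if movie.shifts is not None:
        payload["shifts"] = movie.shifts
    np.savez_compressed(path, **payload)


def read_movie_npz(path: str | Path) -> ImagingMovie:
    try:
        with np.load(path) as z:
            return ImagingMovie(
                frames=z["frames"],
                frame_times_ms=z["frame_times_ms"],
                frame_rate=float(z["frame_rate"]),
                shifts=z["shifts"] if "shifts" in z else None,
            )
    except InputError:
        raise
    except Exception as exc:
        raise InputError(f"cannot read movie container {path}: {exc}") from exc


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot read trial table {path}: {exc}") from exc
    missing = set(TRIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"trial table {path} lacks columns: {sorted(missing)}")
    return df


def write_hand_csv(hand: HandTrajectory, path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp_ms": hand.timestamps_ms,
            "x_cm": hand.position_cm[:, 0],
            "y_cm": hand.position_cm[:, 1],
            "vx_cmps": hand.velocity_cmps[:, 0],
            "vy_cmps": hand.velocity_cmps[:, 1],
        }
    ).to_csv(path, index=False)


def read_hand_csv(path: str | Path) -> HandTrajectory:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InputError(f"cannot read hand trajectory {path}: {exc}") from exc
    missing = set(HAND_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"hand trajectory {path} lacks columns: {sorted(missing)}")
    return HandTrajectory(
        timestamps_ms=df["timestamp_ms"].to_numpy(float),
        position_cm=df[["x_cm", "y_cm"]].to_numpy(float),
        velocity_cmps=df[["vx_cmps", "vy_cmps"]].to_numpy(float),
    )


def write_shifts_csv(shifts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(shifts, columns=["drow_px", "dcol_px"]).to_csv(path, index=False)


def read_shifts_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["drow_px", "dcol_px"]].to_numpy(float)


def validate_io_roundtrip(outdir: str | Path) -> dict[str, bool]:
    """Self-check of every writer/reader pair on small synthetic artifacts.

    Integer data must round-trip bit-exactly; float data within 1e-12.
    Returns ``{artifact_name: passed}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, bool] = {}
    rng = np.random.default_rng(0)

    frames = rng.integers(0, 1000, size=(4, 16, 16)).astype(np.float32)
    movie = ImagingMovie(
        frames=frames, frame_times_ms=np.arange(4) * 33.0, frame_rate=30.3,
        shifts=np.zeros((4, 2)),
    )
    write_movie_tiff(movie, outdir / "rt_movie.tif")
    back = read_movie_tiff(outdir / "rt_movie.tif", frame_rate=30.3)
    results["movie_tiff"] = bool(np.array_equal(back.frames, frames))

    write_movie_npz(movie, outdir / "rt_movie.npz")
    back2 = read_movie_npz(outdir / "rt_movie.npz")
    results["movie_npz"] = bool(
        np.array_equal(back2.frames, frames)
        and np.allclose(back2.frame_times_ms, movie.frame_times_ms, atol=1e-12)
    )

    trials = pd.DataFrame(
        {c: [0, 1] for c in TRIAL_CSV_COLUMNS}
    ).astype({"trial_id": int, "target_index": int, "success": bool})
    write_trials_csv(trials, outdir / "rt_trials.csv")
    back3 = read_trials_csv(outdir / "rt_trials.csv")
    results["trials_csv"] = bool(
        all(np.allclose(back3[c], trials[c], atol=1e-12) for c in TRIAL_CSV_COLUMNS)
    )

    hand = HandTrajectory(
        timestamps_ms=np.arange(5) * 16.0 + 0.5,
        position_cm=rng.normal(size=(5, 2)),
        velocity_cmps=rng.normal(size=(5, 2)),
    )
    write_hand_csv(hand, outdir / "rt_hand.csv")
    back4 = read_hand_csv(outdir / "rt_hand.csv")
    results["hand_csv"] = bool(
        np.allclose(back4.position_cm, hand.position_cm, atol=1e-12)
        and np.allclose(back4.velocity_cmps, hand.velocity_cmps, atol=1e-12)
    )
    return results
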