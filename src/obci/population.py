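"""Population-level axes and projections.

Three axes over the direction-tuned ROI population: a condition-independent
signal (CIS) axis — here the first principal axis of the across-direction mean
trajectory, a deliberate simplification of demixed PCA, which is exact when
directional components cancel in the cross-condition mean — and the targeted
dimensionality reduction (TDR) x/y axes, the rows of the Moore-Penrose
pseudoinverse of the ROI x 2 velocity-coefficient matrix.  The triple is
successively orthonormalized (Gram-Schmidt, CIS first) before projecting
single-trial and trial-averaged trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, InsufficientDataError

__all__ = [
    "PopulationAxes",
    "trial_tensor",
    "compute_cis",
    "compute_tdr_axes",
    "orthonormalize_axes",
    "project_trajectories",
    "variance_spectrum",
]


@dataclass
class PopulationAxes:
    """Unit CIS / TDR-X / TDR-Y vectors over ROIs."""

    cis: np.ndarray
    tdr_x: np.ndarray
    tdr_y: np.ndarray
    orthonormalized: bool = False

    def matrix(self) -> np.ndarray:
        """(3, n_rois) stack in projection order."""
        return np.vstack([self.cis, self.tdr_x, self.tdr_y])


def trial_tensor(
    traces: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    window_ms: tuple[float, float] = (-300.0, 400.0),
    align_column: str = "movement_onset_ms",
    step_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Movement-aligned single-trial tensor.

    Returns ``(tensor, rel_times, targets)`` with tensor shaped
    (n_trials, n_rois, n_times); traces are linearly interpolated onto a
    uniform grid in ``window_ms`` around the alignment event (default grid
    step: the frame period).
    """
    traces = np.atleast_2d(traces)
    if step_ms is None:
        step_ms = float(np.median(np.diff(frame_times)))
    rel = np.arange(window_ms[0], window_ms[1] + step_ms / 2, step_ms)
    events = trials[align_column].to_numpy()
    valid = np.isfinite(events)
    tens = np.empty((int(valid.sum()), traces.shape[0], rel.size))
    for i, ev in enumerate(events[valid]):
        t = ev + rel
        for r in range(traces.shape[0]):
            tens[i, r] = np.interp(t, frame_times, traces[r])
    return tens, rel, trials["target_index"].to_numpy()[valid]


def compute_cis(avg_tensor: np.ndarray) -> np.ndarray:
    """Condition-independent signal axis from an (ROI x time x direction) tensor.

    The across-direction mean trajectory (ROI x time) is centered over time
    and its first principal axis over ROIs taken as the CIS; the sign is
    chosen so the peak deflection of the CIS time course is positive.
    """
    A = np.asarray(avg_tensor, dtype=float)
    if A.ndim != 3:
        raise InputError("expected an (ROI, time, direction) tensor")
    if A.shape[0] < 3:
        raise InsufficientDataError("need at least 3 ROIs for the CIS")
    mean_traj = A.mean(axis=2)               # (ROI, time)
    centered = mean_traj - mean_traj.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(centered, full_matrices=False)
    cis = U[:, 0]
    course = cis @ centered
    if course[np.argmax(np.abs(course))] < 0:
        cis = -cis
    return cis


def compute_tdr_axes(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """TDR axes: rows of the pseudoinverse of the (ROI x 2) coefficient matrix,
    unit-normalized, oriented to correlate positively with their coefficient
    column."""
    B = np.asarray(beta, dtype=float)
    if B.ndim != 2 or B.shape[1] != 2:
        raise InputError("beta must be an (n_rois, 2) matrix")
    if B.shape[0] < 2 or np.linalg.matrix_rank(B) < 2:
        raise InsufficientDataError("beta matrix must have rank 2 (>= 2 tuned ROIs)")
    P = np.linalg.pinv(B)  # (2, n_rois)
    tdr_x = P[0] / np.linalg.norm(P[0])
    tdr_y = P[1] / np.linalg.norm(P[1])
    if tdr_x @ B[:, 0] < 0:
        tdr_x = -tdr_x
    if tdr_y @ B[:, 1] < 0:
        tdr_y = -tdr_y
    return tdr_x, tdr_y


def orthonormalize_axes(
    cis: np.ndarray, tdr_x: np.ndarray, tdr_y: np.ndarray, tol: float = 1e-10
) -> PopulationAxes:
    """Gram-Schmidt in the order (CIS, TDR-X, TDR-Y); the CIS is unchanged."""
    names = ("cis", "tdr_x", "tdr_y")
    vecs = [np.asarray(v, dtype=float) for v in (cis, tdr_x, tdr_y)]
    out: list[np.ndarray] = []
    for name, v in zip(names, vecs):
        w = v.copy()
        for u in out:
            w = w - (u @ w) * u
        norm = np.linalg.norm(w)
        if norm < tol * max(np.linalg.norm(v), 1.0):
            raise InputError(f"axis {name!r} is linearly dependent on earlier axes")
        out.append(w / norm)
    return PopulationAxes(cis=out[0], tdr_x=out[1], tdr_y=out[2], orthonormalized=True)


def project_trajectories(
    traces: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    axes: PopulationAxes,
    window_ms: tuple[float, float] = (-300.0, 400.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Project movement-aligned trials onto (CIS, TDR-X, TDR-Y).

    Returns ``(single, avg, rel_times, directions)``: single-trial projections
    (n_trials, 3, n_times), trial-averaged projections per direction
    (n_directions, 3, n_times), the relative time grid, and the per-trial
    direction labels.
    """
    if not axes.orthonormalized:
        raise InputError("axes must be orthonormalized before projection")
    tens, rel, targets = trial_tensor(traces, frame_times, trials, window_ms)
    M = axes.matrix()  # (3, n_rois)
    single = np.einsum("dr,nrt->ndt", M, tens)
    dirs = np.sort(np.unique(targets))
    avg = np.stack([single[targets == k].mean(axis=0) for k in dirs])
    return single, avg, rel, targets


def variance_spectrum(
    data: np.ndarray,
) -> np.ndarray:
    """PCA eigenvalue scree of a (samples x features) matrix.

    For movies the caller flattens (trials * time) along the first dimension
    and all pixels along the second.  Eigenvalues of the feature covariance
    (ddof = n-1), descending.
    """
    X = np.asarray(data, dtype=np.float64)
    if X.ndim == 3:  # (T, H, W) movie -> (T, H*W)
        X = X.reshape(X.shape[0], -1)
    if X.ndim != 2:
        raise InputError("expected a 2-D (samples x features) matrix or a movie stack")
    Xc = X - X.mean(axis=0, keepdims=True)
    # eigenvalues via the Gram matrix on the smaller side
    n, p = Xc.shape
    if n <= p:
        G = Xc @ Xc.T
    else:
        G = Xc.T @ Xc
    ev = np.linalg.eigvalsh(G)[::-1] / max(n - 1, 1)
    return np.clip(ev, 0.0, None)
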