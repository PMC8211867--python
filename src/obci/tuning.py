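"""Per-ROI tuning statistics for the delayed center-out reach task.

Covers: event responsiveness (rank-sum of pre- vs post-event trial means),
direction tuning (one-way ANOVA on post-movement-onset window means), tuning
onset (Kruskal-Wallis on a 10 ms sliding grid, five consecutive significant
windows), preferred-direction estimation (OLS of dF/F on 50 ms time-lagged
hand velocity, PD = atan2(beta_y, beta_x)), a within-session tuning-stability
shuffle test (early vs late session quartiles, 1000 label reshufflings), and
a within-ROI tuning-heterogeneity test (k-means on per-pixel velocity
coefficients scored by the Calinski-Harabasz criterion, with 30%-membership
and 60-degree centroid-separation rules).

Rank-sum and Kruskal-Wallis tests use the normal / chi-square approximation
with tie correction (``scipy.stats.mannwhitneyu(method="asymptotic")`` and
``scipy.stats.kruskal``); exact small-sample rank-sum is available via
``method="exact"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .errors import InputError, InsufficientDataError
from .synth import HandTrajectory

__all__ = [
    "EventWindows",
    "VelocityFit",
    "circular_diff_deg",
    "event_responsiveness",
    "direction_anova",
    "tuning_onset",
    "fit_velocity_regression",
    "stability_shuffle_test",
    "heterogeneity_test",
    "analyze_tuning",
]

SIGNIFICANCE_LEVEL = 0.01

# effect-size floor for the heterogeneity search: a k>=2 split must score a
# Calinski-Harabasz value of at least CH_FLOOR_PER_POINT * n_pixels to beat
# k=1 (an isotropic single cluster split in two scores ~0.5 * n)
CH_FLOOR_PER_POINT = 1.0


@dataclass
class EventWindows:
    """Pre/post comparison windows (ms relative to each event)."""

    target_pre: tuple[float, float] = (-150.0, 0.0)
    target_post: tuple[float, float] = (0.0, 150.0)
    go_pre: tuple[float, float] = (-150.0, 0.0)
    go_post: tuple[float, float] = (0.0, 150.0)
    move_pre: tuple[float, float] = (-450.0, -100.0)
    move_post: tuple[float, float] = (0.0, 350.0)
    direction: tuple[float, float] = (0.0, 350.0)  # post movement onset

    def __post_init__(self) -> None:
        for pre, post in (
            (self.target_pre, self.target_post),
            (self.go_pre, self.go_post),
            (self.move_pre, self.move_post),
        ):
            if pre[1] > post[0]:
                raise InputError("pre and post windows must not overlap")


@dataclass
class VelocityFit:
    """OLS fit of a trace on 2-D hand velocity."""

    beta_x: float
    beta_y: float
    intercept: float
    pd_deg: float
    tuning_strength: float


def circular_diff_deg(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Absolute circular difference between angles in degrees, in [0, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    return np.abs(d)


# ---------------------------------------------------------------------------
# Window means
# ---------------------------------------------------------------------------


def _window_means(
    trace: np.ndarray,
    frame_times: np.ndarray,
    events: np.ndarray,
    window: tuple[float, float],
) -> np.ndarray:
    """Per-trial mean of the trace in ``window`` around each event (NaN if no
    frame falls inside the recording for that trial)."""
    out = np.full(events.size, np.nan)
    t0, t1 = window
    for i, ev in enumerate(events):
        if not np.isfinite(ev):
            continue
        m = (frame_times >= ev + t0) & (frame_times < ev + t1)
        if np.any(m):
            out[i] = trace[m].mean()
    return out


def event_responsiveness(
    trace: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    windows: EventWindows | None = None,
    method: str = "asymptotic",
) -> dict[str, float]:
    """Two-sided rank-sum p-values for responsiveness to each task event.

    For every trial the mean fluorescence in the pre-event and post-event
    window is extracted, and the two across-trial distributions are compared.
    Returns ``{"p_target", "p_go", "p_move"}``.
    """
    windows = windows or EventWindows()
    events = {
        "target": ("target_onset_ms", windows.target_pre, windows.target_post),
        "go": ("go_cue_ms", windows.go_pre, windows.go_post),
        "move": ("movement_onset_ms", windows.move_pre, windows.move_post),
    }
    out: dict[str, float] = {}
    for name, (col, pre_w, post_w) in events.items():
        ev = trials[col].to_numpy()
        pre = _window_means(trace, frame_times, ev, pre_w)
        post = _window_means(trace, frame_times, ev, post_w)
        valid = np.isfinite(pre) & np.isfinite(post)
        if valid.sum() < 5:
            raise InsufficientDataError(
                f"fewer than 5 trials with valid {name} windows"
            )
        _, p = _stats.mannwhitneyu(
            pre[valid], post[valid], alternative="two-sided", method=method
        )
        out[f"p_{name}"] = float(p)
    return out


def direction_anova(
    trace: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float] = (0.0, 350.0),
    align_column: str = "movement_onset_ms",
) -> float:
    """One-way ANOVA p-value for a main effect of reach direction.

    Groups are per-trial mean fluorescence in ``window`` after the alignment
    event, split by target; tuned iff p < 0.01.
    """
    means = _window_means(trace, frame_times, trials[align_column].to_numpy(), window)
    groups = []
    for k in np.sort(trials["target_index"].unique()):
        g = means[(trials["target_index"] == k).to_numpy()]
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise InsufficientDataError(f"direction group {k} has fewer than 2 trials")
        groups.append(g)
    _, p = _stats.f_oneway(*groups)
    return float(p)


def tuning_onset(
    trace: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    align_column: str = "movement_onset_ms",
    t_range_ms: tuple[float, float] = (-200.0, 600.0),
    step_ms: float = 10.0,
    n_consecutive: int = 5,
    alpha: float = SIGNIFICANCE_LEVEL,
) -> float | None:
    """Onset of direction tuning: Kruskal-Wallis on a sliding 10 ms grid.

    Each trial's trace is linearly interpolated onto a grid of times relative
    to the alignment event; at each gridpoint a Kruskal-Wallis test across
    direction groups is run, and the onset is the earliest time at which
    ``n_consecutive`` consecutive windows reject at ``alpha``.  Returns None
    if that never happens.
    """
    events = trials[align_column].to_numpy()
    targets = trials["target_index"].to_numpy()
    valid = np.isfinite(events)
    if valid.sum() < 2 * len(np.unique(targets)):
        raise InsufficientDataError("not enough trials with a valid alignment event")
    grid = np.arange(t_range_ms[0], t_range_ms[1] + step_ms / 2, step_ms)
    aligned = np.empty((valid.sum(), grid.size))
    for i, ev in enumerate(events[valid]):
        aligned[i] = np.interp(ev + grid, frame_times, trace)
    tg = targets[valid]
    uniq = np.unique(tg)
    run = 0
    for j in range(grid.size):
        samples = [aligned[tg == k, j] for k in uniq]
        try:
            import warnings as _warnings

            with _warnings.catch_warnings():
                # all-tied samples divide by zero in the tie correction
                _warnings.simplefilter("ignore", RuntimeWarning)
                _, p = _stats.kruskal(*samples)
            if not np.isfinite(p):
                p = 1.0
        except ValueError:  # all values identical in every group
            p = 1.0
        if p < alpha:
            run += 1
            if run == n_consecutive:
                return float(grid[j - n_consecutive + 1])
        else:
            run = 0
    return None


# ---------------------------------------------------------------------------
# Velocity regression / preferred direction
# ---------------------------------------------------------------------------


def _velocity_design(
    hand: HandTrajectory, frame_times: np.ndarray, lag_ms: float
) -> np.ndarray:
    """Design matrix [vx, vy, 1] with the trace leading the design by lag_ms,
    i.e. column t holds v(t - lag)."""
    v = hand.velocity_at(np.asarray(frame_times, dtype=float) - lag_ms)
    return np.column_stack([v, np.ones(v.shape[0])])


def fit_velocity_regression(
    trace: np.ndarray,
    hand: HandTrajectory,
    frame_times: np.ndarray,
    lag_ms: float = 50.0,
    frame_mask: np.ndarray | None = None,
) -> VelocityFit:
    """OLS of a trace on 50 ms time-lagged 2-D hand velocity.

    PD is the angle of (beta_x, beta_y) mapped to [0, 360); tuning strength is
    the coefficient-vector norm (dF/F per cm/s).
    """
    trace = np.asarray(trace, dtype=float)
    X = _velocity_design(hand, frame_times, lag_ms)
    y = trace
    if frame_mask is not None:
        X, y = X[frame_mask], y[frame_mask]
    if np.linalg.matrix_rank(X) < 3:
        raise InputError("rank-deficient velocity design (no 2-D movement in window)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    bx, by, b0 = beta
    pd_deg = float(np.rad2deg(np.arctan2(by, bx)) % 360.0)
    return VelocityFit(
        beta_x=float(bx), beta_y=float(by), intercept=float(b0),
        pd_deg=pd_deg, tuning_strength=float(np.hypot(bx, by)),
    )


def _trial_frame_mask(
    frame_times: np.ndarray, trials: pd.DataFrame, trial_idx: np.ndarray
) -> np.ndarray:
    m = np.zeros(frame_times.size, dtype=bool)
    for _, tr in trials.iloc[trial_idx].iterrows():
        m |= (frame_times >= tr["target_onset_ms"]) & (frame_times < tr["trial_end_ms"])
    return m


def _pd_from_suffstats(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve batched 3x3 normal equations and return PD angles (degrees)."""
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    return np.rad2deg(np.arctan2(beta[..., 1], beta[..., 0])) % 360.0


def stability_shuffle_test(
    trace: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    hand: HandTrajectory,
    lag_ms: float = 50.0,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    min_trials_per_dir: int = 2,
) -> tuple[float, float]:
    """Within-session preferred-direction drift test.

    PD is fit separately on the first and last 25% of trials; the absolute
    circular PD difference is compared against a null built from
    ``n_shuffles`` random reshufflings of the early/late labels (permuted at
    the trial level).  Returns ``(p_value, delta_pd_deg)``; drift is
    significant iff the observed difference exceeds 99% of shuffles.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = len(trials)
    q = max(n // 4, 1)
    early_idx = np.arange(q)
    late_idx = np.arange(n - q, n)
    for idx, name in ((early_idx, "early"), (late_idx, "late")):
        counts = trials.iloc[idx]["target_index"].value_counts()
        K = trials["target_index"].nunique()
        if len(counts) < K or counts.min() < min_trials_per_dir:
            raise InsufficientDataError(
                f"{name} quartile lacks {min_trials_per_dir} trials per direction"
            )

    X = _velocity_design(hand, frame_times, lag_ms)
    y = np.asarray(trace, dtype=float)
    both = np.concatenate([early_idx, late_idx])
    # per-trial sufficient statistics for OLS: A_t = X^T X, b_t = X^T y
    A_t = np.empty((both.size, 3, 3))
    b_t = np.empty((both.size, 3))
    for i, t_idx in enumerate(both):
        m = _trial_frame_mask(frame_times, trials, np.array([t_idx]))
        Xt, yt = X[m], y[m]
        A_t[i] = Xt.T @ Xt
        b_t[i] = Xt.T @ yt

    n_early = early_idx.size
    sel_obs = np.zeros(both.size, dtype=bool)
    sel_obs[:n_early] = True

    def pds(selection: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # selection: (..., n_trials) boolean; returns (pd_early, pd_late)
        A_e = np.einsum("...n,nij->...ij", selection.astype(float), A_t)
        b_e = np.einsum("...n,ni->...i", selection.astype(float), b_t)
        inv = (~selection).astype(float)
        A_l = np.einsum("...n,nij->...ij", inv, A_t)
        b_l = np.einsum("...n,ni->...i", inv, b_t)
        return _pd_from_suffstats(A_e, b_e), _pd_from_suffstats(A_l, b_l)

    pd_e, pd_l = pds(sel_obs)
    delta_obs = float(circular_diff_deg(pd_e, pd_l))

    perm = np.argsort(rng.random((n_shuffles, both.size)), axis=1)
    sel = perm < n_early
    pd_e0, pd_l0 = pds(sel)
    null = circular_diff_deg(pd_e0, pd_l0)
    p = float((1 + np.sum(null >= delta_obs)) / (n_shuffles + 1))
    return p, delta_obs


# ---------------------------------------------------------------------------
# Within-ROI heterogeneity
# ---------------------------------------------------------------------------


def heterogeneity_test(
    pixel_traces: np.ndarray,
    hand: HandTrajectory,
    frame_times: np.ndarray,
    lag_ms: float = 50.0,
    k_max: int = 5,
    min_fraction: float = 0.30,
    min_pd_sep_deg: float = 60.0,
    rng: np.random.Generator | None = None,
) -> tuple[bool, int, np.ndarray]:
    """Multiple tuning clusters within one ROI's pixels?

    Each pixel's trace is regressed on lagged hand velocity; the (beta_x,
    beta_y) coefficients are clustered with k-means for k = 2..``k_max`` and
    scored by the Calinski-Harabasz criterion.  k = 1 is selected when the
    best score fails the effect-size floor (``CH_FLOOR_PER_POINT`` per pixel),
    since the criterion is undefined at k = 1.  The ROI is heterogeneous iff
    the optimal k > 1, at least two clusters each hold >= 30% of the pixels,
    and the largest pairwise circular difference of centroid PDs is >= 60
    degrees.

    Returns ``(heterogeneous, n_clusters, labels)``.
    """
    P = np.atleast_2d(np.asarray(pixel_traces, dtype=float))
    if P.shape[0] < 10:
        raise InsufficientDataError("heterogeneity test needs an ROI of >= 10 pixels")
    X = _velocity_design(hand, frame_times, lag_ms)
    if np.linalg.matrix_rank(X) < 3:
        raise InputError("rank-deficient velocity design")
    beta, *_ = np.linalg.lstsq(X, P.T, rcond=None)  # (3, n_pixels)
    coords = beta[:2].T  # (n_pixels, 2)
    if not np.all(np.isfinite(coords)) or np.allclose(coords.std(axis=0), 0):
        import warnings

        warnings.warn("degenerate pixel coefficients; ROI treated as homogeneous",
                      RuntimeWarning, stacklevel=2)
        return False, 1, np.zeros(P.shape[0], dtype=int)

    seed = None if rng is None else int(rng.integers(2**31 - 1))
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(P.shape[0], dtype=int)
    for k in range(2, min(k_max, P.shape[0] - 1) + 1):
        km = KMeans(n_clusters=k, n_init=5, random_state=seed)
        labels = km.fit_predict(coords)
        if len(np.unique(labels)) < k:
            continue
        score = calinski_harabasz_score(coords, labels)
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    if best_k == 1 or best_score < CH_FLOOR_PER_POINT * coords.shape[0]:
        return False, 1, np.zeros(P.shape[0], dtype=int)

    counts = np.bincount(best_labels, minlength=best_k)
    big = np.flatnonzero(counts >= min_fraction * coords.shape[0])
    if big.size < 2:
        return False, best_k, best_labels
    centroids = np.vstack([coords[best_labels == c].mean(axis=0) for c in big])
    pds = np.rad2deg(np.arctan2(centroids[:, 1], centroids[:, 0])) % 360.0
    sep = max(
        float(circular_diff_deg(pds[i], pds[j]))
        for i in range(big.size) for j in range(i + 1, big.size)
    )
    return bool(sep >= min_pd_sep_deg), best_k, best_labels


# ---------------------------------------------------------------------------
# Session-level convenience
# ---------------------------------------------------------------------------


def analyze_tuning(
    traces: np.ndarray,
    frame_times: np.ndarray,
    trials: pd.DataFrame,
    hand: HandTrajectory,
    windows: EventWindows | None = None,
    lag_ms: float = 50.0,
    compute_onset: bool = True,
    compute_stability: bool = False,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Run the per-ROI battery and return one row per ROI.

    Columns: responsiveness p-values, direction-ANOVA p, tuning flag
    (p < 0.01), velocity-regression coefficients, PD, tuning strength, onset,
    and (optionally) the stability-shuffle p and PD drift.
    """
    traces = np.atleast_2d(traces)
    ok = trials[trials["success"]].reset_index(drop=True)
    rows = []
    for i in range(traces.shape[0]):
        tr = traces[i]
        rec: dict = {"roi": i}
        rec.update(event_responsiveness(tr, frame_times, ok, windows))
        rec["p_direction"] = direction_anova(tr, frame_times, ok)
        rec["direction_tuned"] = rec["p_direction"] < SIGNIFICANCE_LEVEL
        fit = fit_velocity_regression(tr, hand, frame_times, lag_ms)
        rec.update(
            beta_x=fit.beta_x, beta_y=fit.beta_y, intercept=fit.intercept,
            pd_deg=fit.pd_deg, tuning_strength=fit.tuning_strength,
        )
        rec["onset_ms"] = (
            tuning_onset(tr, frame_times, ok) if compute_onset else None
        )
        if compute_stability:
            p_stab, dpd = stability_shuffle_test(
                tr, frame_times, ok, hand, lag_ms, n_shuffles, rng
            )
            rec["stability_p"] = p_stab
            rec["delta_pd_deg"] = dpd
        rows.append(rec)
    return pd.DataFrame(rows)
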