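"""Reach-direction decoding from imaging frames.

Online path (raw pixels): per-target templates are the across-trial average of
lightly blurred frames from a fixed integration window (``T_int``) starting a
fixed latency (``T_skip``) after the go cue; a trial is decoded by the
pixel-wise minimum-mean-squared-error rule

    argmin_k  sum_ij (X_ij - Y_ijk)^2

where X is the blurred window-average image of the current trial.  The
emulation is strictly causal: no frame after the integration window can
influence the decision.  Ties are broken toward the lowest target index.

Offline path (dF/F pixels): a linear multiclass SVM with 5-fold
cross-validation on causal 200 ms window averages, each pixel standardized on
the training folds only.  Pixel-masking and dendritic-pixel analyses reuse
this offline decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .errors import InputError, InsufficientDataError
from .preprocess import gaussian_blur
from .rois import ROIMaskSet, classify_dendritic
from .synth import ImagingMovie

__all__ = [
    "TemplateSet",
    "DecodeOutcome",
    "SessionSummary",
    "select_window_frames",
    "trial_window_image",
    "train_templates",
    "decode_trial",
    "run_session",
    "binomial_session_test",
    "decode_score_timecourse",
    "pixel_dff",
    "offline_svm_decode",
    "pixel_masking_analysis",
    "dendritic_pixel_analysis",
]

DEFAULT_T_SKIP_MS = 300.0   # midpoint of the 200-400 ms post-go operating range
DEFAULT_T_INT_MS = 132.0    # four frame periods at 30.3 Hz
DEFAULT_BLUR_SIGMA_PX = 3.0


@dataclass
class TemplateSet:
    """Per-target mean blurred window images plus the decoder's timing."""

    templates: np.ndarray        # (K, H, W)
    t_skip_ms: float
    t_int_ms: float
    sigma_px: float
    n_training_trials: np.ndarray  # (K,)

    @property
    def n_targets(self) -> int:
        return self.templates.shape[0]


@dataclass
class DecodeOutcome:
    trial_id: int
    true_k: int
    decoded_k: int
    scores: np.ndarray  # (K,) squared-error vs each template

    @property
    def success(self) -> bool:
        return self.decoded_k == self.true_k


@dataclass
class SessionSummary:
    n_success: int
    n_fail: int
    chance: float

    @property
    def n_trials(self) -> int:
        return self.n_success + self.n_fail

    @property
    def success_rate_pct(self) -> float:
        return 100.0 * self.n_success / self.n_trials

    @property
    def p_binomial(self) -> float:
        return binomial_session_test(self.n_success, self.n_fail, self.chance)[1]


# ---------------------------------------------------------------------------
# Online MMSE decoder
# ---------------------------------------------------------------------------


def select_window_frames(
    frame_times_ms: np.ndarray,
    go_cue_ms: float,
    t_skip_ms: float,
    t_int_ms: float,
) -> np.ndarray:
    """Indices of frames whose start times fall in
    [go + T_skip, go + T_skip + T_int).  Only full frames are considered, so
    an empty result means the window ran past the recording."""
    t0 = go_cue_ms + t_skip_ms
    return np.flatnonzero((frame_times_ms >= t0) & (frame_times_ms < t0 + t_int_ms))


def trial_window_image(
    movie: ImagingMovie,
    go_cue_ms: float,
    t_skip_ms: float,
    t_int_ms: float,
    sigma_px: float,
) -> np.ndarray | None:
    """Blur-then-average image over the integration window (None if no frame)."""
    idx = select_window_frames(movie.frame_times_ms, go_cue_ms, t_skip_ms, t_int_ms)
    if idx.size == 0:
        return None
    acc = np.zeros(movie.fov_shape, dtype=np.float64)
    for i in idx:
        acc += gaussian_blur(movie.frames[i].astype(np.float64), sigma_px)
    return acc / idx.size


def train_templates(
    movie: ImagingMovie,
    trials: pd.DataFrame,
    t_skip_ms: float = DEFAULT_T_SKIP_MS,
    t_int_ms: float = DEFAULT_T_INT_MS,
    sigma_px: float = DEFAULT_BLUR_SIGMA_PX,
    n_targets: int | None = None,
) -> TemplateSet:
    """Accumulate per-target templates from the given training trials.

    Each trial contributes its blurred window-average image to the running
    average of its target.  Raises if any target has no usable trial.
    """
    if n_targets is None:
        n_targets = int(trials["target_index"].max()) + 1
    H, W = movie.fov_shape
    acc = np.zeros((n_targets, H, W), dtype=np.float64)
    counts = np.zeros(n_targets, dtype=int)
    for tr in trials.itertuples():
        img = trial_window_image(movie, tr.go_cue_ms, t_skip_ms, t_int_ms, sigma_px)
        if img is None:
            warnings.warn(
                f"trial {tr.trial_id}: no full frame in the integration window; skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        acc[tr.target_index] += img
        counts[tr.target_index] += 1
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise InsufficientDataError(
            f"no training trials for target(s) {missing.tolist()}"
        )
    return TemplateSet(
        templates=acc / counts[:, None, None],
        t_skip_ms=t_skip_ms, t_int_ms=t_int_ms, sigma_px=sigma_px,
        n_training_trials=counts,
    )


def decode_trial(
    X: np.ndarray, templates: TemplateSet, trial_id: int = -1, true_k: int = -1
) -> DecodeOutcome:
    """Pixel-wise MMSE classification of one window-average image.

    ``score_k = sum_ij (X_ij - Y_ijk)^2``; the decoded target is the argmin,
    with ties broken toward the lowest target index (np.argmin's convention).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape != templates.templates.shape[1:]:
        raise InputError("image shape does not match the templates")
    diff = templates.templates - X[None]
    scores = np.einsum("kij,kij->k", diff, diff)
    return DecodeOutcome(
        trial_id=trial_id, true_k=true_k,
        decoded_k=int(np.argmin(scores)), scores=scores,
    )


def run_session(
    movie: ImagingMovie,
    trials: pd.DataFrame,
    t_skip_ms: float = DEFAULT_T_SKIP_MS,
    t_int_ms: float = DEFAULT_T_INT_MS,
    sigma_px: float = DEFAULT_BLUR_SIGMA_PX,
    n_train_per_target: int = 10,
    permute_training_labels: np.random.Generator | None = None,
) -> tuple[SessionSummary, pd.DataFrame]:
    """Train-then-test emulation of one online decode session.

    The training block is the chronological prefix of successful trials that
    first gives every target ``n_train_per_target`` trials (mirroring training
    on the first block of a session); all later successful trials are decoded.
    ``permute_training_labels`` randomly permutes the target labels of the
    training trials only — the chance-level control.
    """
    ok = trials[trials["success"]].reset_index(drop=True)
    K = int(trials["target_index"].max()) + 1
    counts = np.zeros(K, dtype=int)
    n_train = 0
    for tr in ok.itertuples():
        counts[tr.target_index] += 1
        n_train += 1
        if np.all(counts >= n_train_per_target):
            break
    if not np.all(counts >= 1):
        raise InsufficientDataError("not enough trials to cover every target in training")
    train = ok.iloc[:n_train]
    test = ok.iloc[n_train:]
    if len(test) == 0:
        raise InsufficientDataError("no trials left to decode after the training block")

    if permute_training_labels is not None:
        train = train.copy()
        train["target_index"] = permute_training_labels.permutation(
            train["target_index"].to_numpy()
        )

    templates = train_templates(movie, train, t_skip_ms, t_int_ms, sigma_px, n_targets=K)
    outcomes = []
    for tr in test.itertuples():
        X = trial_window_image(movie, tr.go_cue_ms, t_skip_ms, t_int_ms, sigma_px)
        if X is None:
            warnings.warn(
                f"trial {tr.trial_id}: integration window outside recording; skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        out = decode_trial(X, templates, trial_id=tr.trial_id, true_k=tr.target_index)
        outcomes.append(
            dict(trial_id=out.trial_id, true_k=out.true_k,
                 decoded_k=out.decoded_k, success=out.success,
                 **{f"score_{k}": out.scores[k] for k in range(K)})
        )
    df = pd.DataFrame(outcomes)
    n_s = int(df["success"].sum())
    summary = SessionSummary(n_success=n_s, n_fail=len(df) - n_s, chance=1.0 / K)
    return summary, df


def binomial_session_test(
    n_success: int, n_fail: int, chance: float
) -> tuple[float, float]:
    """Session success rate (%) and exact two-sided binomial p vs chance."""
    if n_success < 0 or n_fail < 0:
        raise InputError("counts must be non-negative")
    n = n_success + n_fail
    if n < 1:
        raise InputError("need at least one trial")
    p = _stats.binomtest(n_success, n, chance, alternative="two-sided").pvalue
    return 100.0 * n_success / n, float(p)


def decode_score_timecourse(
    movie: ImagingMovie,
    trials: pd.DataFrame,
    templates: TemplateSet,
    align_column: str = "movement_onset_ms",
    window_ms: tuple[float, float] = (-500.0, 700.0),
    n_avg_frames: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decoder score vs time: causal rolling-``n_avg_frames`` average image at
    every frame, scored against each template, aligned per trial.

    Returns ``(scores, rel_times, targets)`` with scores shaped
    (n_trials, K, n_times); the first ``n_avg_frames - 1`` frames of the
    session are undefined and emitted as NaN.
    """
    T = movie.n_frames
    P = movie.fov_shape[0] * movie.fov_shape[1]
    blurred = np.empty((T, P), dtype=np.float64)
    for t in range(T):
        blurred[t] = gaussian_blur(
            movie.frames[t].astype(np.float64), templates.sigma_px
        ).ravel()
    csum = np.cumsum(blurred, axis=0)
    rolling = np.full_like(blurred, np.nan)
    rolling[n_avg_frames - 1:] = (
        csum[n_avg_frames - 1:] - np.vstack([np.zeros((1, P)), csum[:-n_avg_frames]])
    ) / n_avg_frames
    Y = templates.templates.reshape(templates.n_targets, P)
    # ||R - Y_k||^2 expanded; NaN rows propagate
    r2 = np.einsum("tp,tp->t", rolling, rolling)
    score = r2[:, None] - 2 * rolling @ Y.T + np.einsum("kp,kp->k", Y, Y)[None, :]

    dt = float(np.median(np.diff(movie.frame_times_ms)))
    rel = np.arange(window_ms[0], window_ms[1] + dt / 2, dt)
    events = trials[align_column].to_numpy()
    valid = np.isfinite(events)
    out = np.full((int(valid.sum()), templates.n_targets, rel.size), np.nan)
    for i, ev in enumerate(events[valid]):
        idx = np.searchsorted(movie.frame_times_ms, ev + rel) - 1
        good = (idx >= 0) & (idx < T)
        out[i, :, good] = score[idx[good]]
    return out, rel, trials["target_index"].to_numpy()[valid]


# ---------------------------------------------------------------------------
# Offline SVM decoding
# ---------------------------------------------------------------------------


def pixel_dff(movie: ImagingMovie, percentile: float = 10.0) -> np.ndarray:
    """Per-pixel dF/F with a static low-percentile baseline, (T, H*W).

    The offline classifier standardizes every pixel on the training folds, so
    a static baseline is sufficient at session length; the iterative
    time-varying estimate is reserved for ROI traces.
    """
    F = movie.frames.reshape(movie.n_frames, -1).astype(np.float64)
    f0 = np.percentile(F, percentile, axis=0)
    f0 = np.maximum(f0, 1e-6)
    return (F - f0) / f0


def _window_features(
    dff: np.ndarray,
    frame_times: np.ndarray,
    events: np.ndarray,
    t_rel_ms: float,
    window_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal window average per trial: frames in (ev + t_rel - window, ev + t_rel]."""
    feats, keep = [], []
    for i, ev in enumerate(events):
        if not np.isfinite(ev):
            continue
        t1 = ev + t_rel_ms
        m = (frame_times > t1 - window_ms) & (frame_times <= t1)
        if not np.any(m):
            continue
        feats.append(dff[m].mean(axis=0))
        keep.append(i)
    return np.asarray(feats), np.asarray(keep, dtype=int)


def _svm_cv_accuracy(
    X: np.ndarray, y: np.ndarray, n_folds: int = 5, seed: int = 0
) -> float:
    """5-fold CV accuracy of a linear multiclass SVM; per-feature
    standardization is fit inside each training fold (no leakage).

    With zero features (everything masked) the classifier degenerates to a
    majority-class guess, i.e. chance on a balanced design.
    """
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("need at least two classes")
    if np.min(np.bincount(y)) < n_folds:
        raise InsufficientDataError("fewer trials per class than CV folds")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    if X.ndim == 2 and X.shape[1] == 0:
        from sklearn.dummy import DummyClassifier

        clf = DummyClassifier(strategy="most_frequent")
        X = np.zeros((len(y), 1))
    else:
        clf = make_pipeline(
            StandardScaler(),
            LinearSVC(C=1.0, multi_class="ovr", max_iter=5000),
        )
    return float(cross_val_score(clf, X, y, cv=cv).mean())


def offline_svm_decode(
    movie: ImagingMovie,
    trials: pd.DataFrame,
    alignment: str = "move",
    times_ms: np.ndarray | None = None,
    window_ms: float = 200.0,
    n_folds: int = 5,
    seed: int = 0,
    dff: np.ndarray | None = None,
    pixel_subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cross-validated decode accuracy vs time.

    At every timepoint the dF/F frames inside a causal ``window_ms`` window
    are averaged per trial, pixels standardized on training folds, and a
    linear multiclass SVM scored with ``n_folds``-fold cross-validation.
    Only successful trials are used.  ``pixel_subset`` restricts features to
    a flat-index subset of pixels.
    """
    if alignment not in ("go", "move"):
        raise InputError("alignment must be 'go' or 'move'")
    col = "go_cue_ms" if alignment == "go" else "movement_onset_ms"
    ok = trials[trials["success"]].reset_index(drop=True)
    if len(ok) < n_folds:
        raise InsufficientDataError("fewer successful trials than CV folds")
    if dff is None:
        dff = pixel_dff(movie)
    if pixel_subset is not None:
        dff = dff[:, pixel_subset]
    if times_ms is None:
        times_ms = np.arange(-200.0, 601.0, 100.0)
    events = ok[col].to_numpy()
    labels = ok["target_index"].to_numpy()
    rows = []
    for t_rel in np.atleast_1d(times_ms):
        X, keep = _window_features(dff, movie.frame_times_ms, events, t_rel, window_ms)
        if X.shape[0] == 0:
            rows.append(dict(time_ms=float(t_rel), accuracy=np.nan, n_trials=0))
            continue
        acc = _svm_cv_accuracy(X, labels[keep], n_folds, seed)
        rows.append(dict(time_ms=float(t_rel), accuracy=acc, n_trials=len(keep)))
    return pd.DataFrame(rows)


def pixel_masking_analysis(
    movie: ImagingMovie,
    trials: pd.DataFrame,
    square_sizes: list[int],
    n_regions: int = 15,
    time_ms: float = 200.0,
    alignment: str = "move",
    window_ms: float = 200.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Decode accuracy vs fraction of pixels retained.

    For each square size, ``n_regions`` squares are sampled uniformly from the
    FOV; all pixels outside a square are masked (dropped) and the offline SVM
    decoder is run at ``time_ms`` relative to the alignment event.  A square
    covering the full FOV reproduces the unmasked accuracy exactly.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    H, W = movie.fov_shape
    dff = pixel_dff(movie)
    rows = []
    for size in square_sizes:
        if size > H or size > W:
            raise InputError(f"square size {size} exceeds the FOV")
        n_reg = 1 if size == 0 or (size == H and size == W) else n_regions
        for _ in range(n_reg):
            sel = np.zeros((H, W), dtype=bool)
            if size > 0:
                r0 = int(rng.integers(0, H - size + 1))
                c0 = int(rng.integers(0, W - size + 1))
                sel[r0:r0 + size, c0:c0 + size] = True
            flat = np.flatnonzero(sel.ravel())
            res = offline_svm_decode(
                movie, trials, alignment, np.array([time_ms]), window_ms,
                seed=seed, dff=dff, pixel_subset=flat,
            )
            rows.append(dict(
                square_size=size,
                retained_fraction=flat.size / (H * W),
                masked_fraction=1.0 - flat.size / (H * W),
                accuracy=float(res["accuracy"].iloc[0]),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dendritic-pixel analysis
# ---------------------------------------------------------------------------


def dendritic_pixel_analysis(
    movie: ImagingMovie,
    trials: pd.DataFrame,
    masks: ROIMaskSet,
    templates: TemplateSet | None = None,
    time_ms: float = 200.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Do dendritic pixels carry the decodable signal?

    (a) Per-pixel peak-to-peak range across the per-target training templates
    and per-pixel dF/F SD across all timepoints, compared between dendritic
    pixels (inside any aspect-ratio-classified dendritic ROI) and the rest by
    a two-sided rank-sum test.  (b) Offline decode accuracy using dendritic
    pixels only, all pixels, and a count-matched random selection of
    non-dendritic pixels.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    H, W = movie.fov_shape
    dend = np.zeros((H, W), dtype=bool)
    for m in masks:
        label, _ = classify_dendritic(m)
        if label == "dendritic":
            dend[m.rows, m.cols] = True
    if not dend.any():
        raise InputError("no dendritic pixels in the mask set")
    dend_flat = dend.ravel()

    if templates is None:
        ok = trials[trials["success"]]
        templates = train_templates(movie, ok.iloc[: min(len(ok), 40)])
    Y = templates.templates.reshape(templates.n_targets, -1)
    ptp = Y.max(axis=0) - Y.min(axis=0)

    dff = pixel_dff(movie)
    sd = dff.std(axis=0)

    _, p_ptp = _stats.mannwhitneyu(
        ptp[dend_flat], ptp[~dend_flat], alternative="two-sided"
    )
    _, p_sd = _stats.mannwhitneyu(
        sd[dend_flat], sd[~dend_flat], alternative="two-sided"
    )

    n_dend = int(dend_flat.sum())
    non_idx = np.flatnonzero(~dend_flat)
    rand_idx = rng.choice(non_idx, size=min(n_dend, non_idx.size), replace=False)

    def acc(subset):
        return float(
            offline_svm_decode(
                movie, trials, "move", np.array([time_ms]), seed=seed,
                dff=dff, pixel_subset=subset,
            )["accuracy"].iloc[0]
        )

    return dict(
        n_dendritic_pixels=n_dend,
        ptp_dendritic_median=float(np.median(ptp[dend_flat])),
        ptp_other_median=float(np.median(ptp[~dend_flat])),
        p_ptp=float(p_ptp),
        sd_dendritic_median=float(np.median(sd[dend_flat])),
        sd_other_median=float(np.median(sd[~dend_flat])),
        p_sd=float(p_sd),
        accuracy_dendritic=acc(np.flatnonzero(dend_flat)),
        accuracy_all=acc(np.arange(H * W)),
        accuracy_random_matched=acc(rand_idx),
    )


# ---------------------------------------------------------------------------
# Chance-level calibration experiment
# ---------------------------------------------------------------------------


def shuffled_label_chance_experiment(
    n_targets: int,
    n_sessions: int = 20,
    n_test_trials: int = 500,
    seed: int = 1,
    fov_px: int = 32,
    n_train_per_target: int = 10,
    t_skip_ms: float = DEFAULT_T_SKIP_MS,
    t_int_ms: float = DEFAULT_T_INT_MS,
    sigma_px: float = DEFAULT_BLUR_SIGMA_PX,
) -> pd.DataFrame:
    """Decode accuracy of the MMSE decoder with permuted training labels.

    Generates ``n_sessions`` seeded synthetic sessions, permutes the target
    labels of the training block uniformly at random, trains templates, and
    decodes ``n_test_trials`` held-out trials per session.  With destroyed
    label-template correspondence the expected accuracy is the chance level
    1/K.  FOV size does not enter the chance rate; a small FOV keeps the
    experiment fast.

    Returns one row per session: ``seed``, ``accuracy_pct``, ``n_test``.
    """
    from .synth import SessionConfig, simulate_session, stage_rng

    # extra n_train_per_target covers training-prefix overshoot so that at
    # least n_test_trials remain after the training block
    n_per_target = 2 * n_train_per_target + int(np.ceil(n_test_trials / n_targets))
    rows = []
    for i in range(n_sessions):
        rng = stage_rng(seed, f"chance-K{n_targets}-session{i}")
        cfg = SessionConfig(
            fov_height_px=fov_px, fov_width_px=fov_px,
            n_targets=n_targets, n_trials_per_target=n_per_target,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        sess = simulate_session(cfg, rng)
        summary, outcomes = run_session(
            sess.movie, sess.trials, t_skip_ms, t_int_ms, sigma_px,
            n_train_per_target, permute_training_labels=rng,
        )
        outcomes = outcomes.iloc[:n_test_trials]
        acc = 100.0 * outcomes["success"].mean()
        rows.append(dict(seed=seed + i, accuracy_pct=acc, n_test=len(outcomes)))
    return pd.DataFrame(rows)
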