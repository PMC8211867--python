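"""ROI footprints: trace extraction, shape classification, duplicates, clustering.

ROI *detection* is deliberately out of scope — footprints come from the
generator's ground truth or from user-supplied masks (label images or JSON
footprint lists).  What lives here is everything computed *on* footprints:
weighted trace extraction, the dendrite-vs-other shape classifier (aspect
ratio of the weighted pixel covariance, dendritic iff > 2), flagging of
putative same-neuron duplicates by trace correlation, and a density-based
clustering check on trial-averaged response vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .errors import InputError, InsufficientDataError
from .preprocess import RegisteredMovie
from .synth import GroundTruthROI, ImagingMovie

__all__ = [
    "ROIMask",
    "ROIMaskSet",
    "TraceMatrix",
    "aspect_ratio",
    "classify_dendritic",
    "extract_traces",
    "detect_duplicates",
    "cluster_response_check",
]

DENDRITIC_ASPECT_THRESHOLD = 2.0
# variance of a unit pixel; regularizes 1-px-wide masks against infinite ratios
PIXEL_VARIANCE = 1.0 / 12.0


@dataclass
class ROIMask:
    """One spatial footprint: pixel coordinates (row, col) and weights."""

    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.rows.shape != self.cols.shape or self.rows.shape != self.weights.shape:
            raise InputError("rows, cols and weights must have equal length")
        if np.any(self.weights < 0):
            raise InputError("mask weights must be non-negative")

    @property
    def area_px(self) -> int:
        return int(self.rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        w = self.weights / self.weights.sum()
        return float(self.rows @ w), float(self.cols @ w)

    @classmethod
    def from_ground_truth(cls, roi: GroundTruthROI) -> "ROIMask":
        return cls(rows=roi.rows, cols=roi.cols, weights=roi.weights,
                   label=roi.shape_class)


@dataclass
class ROIMaskSet:
    """Ordered collection of footprints tied to one FOV geometry."""

    masks: list[ROIMask]
    fov_shape: tuple[int, int]

    def __post_init__(self) -> None:
        H, W = self.fov_shape
        for m in self.masks:
            if m.area_px and (
                m.rows.min() < 0 or m.cols.min() < 0
                or m.rows.max() >= H or m.cols.max() >= W
            ):
                raise InputError("mask pixel outside the FOV")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def __getitem__(self, i: int) -> ROIMask:
        return self.masks[i]

    @classmethod
    def from_ground_truth(
        cls, rois: Sequence[GroundTruthROI], fov_shape: tuple[int, int]
    ) -> "ROIMaskSet":
        return cls([ROIMask.from_ground_truth(r) for r in rois], fov_shape)

    def to_label_image(self) -> np.ndarray:
        """16-bit label image; later masks overwrite earlier on overlap, 0 = background."""
        img = np.zeros(self.fov_shape, dtype=np.uint16)
        for i, m in enumerate(self.masks):
            img[m.rows, m.cols] = i + 1
        return img

    @classmethod
    def from_label_image(cls, img: np.ndarray) -> "ROIMaskSet":
        img = np.asarray(img)
        masks = []
        for lbl in range(1, int(img.max()) + 1):
            r, c = np.nonzero(img == lbl)
            if r.size:
                masks.append(ROIMask(rows=r, cols=c, weights=np.ones(r.size)))
        return cls(masks, img.shape)

    def to_json(self, path) -> None:
        payload = {
            "fov_shape": list(self.fov_shape),
            "masks": [
                {
                    "rows": m.rows.tolist(),
                    "cols": m.cols.tolist(),
                    "weights": m.weights.tolist(),
                    "label": m.label,
                }
                for m in self.masks
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ROIMaskSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [ROIMask(**m) for m in payload["masks"]],
            tuple(payload["fov_shape"]),
        )


@dataclass
class TraceMatrix:
    """ROI x frame matrix of extracted (raw or dF/F) traces."""

    values: np.ndarray          # (n_rois, T)
    frame_times_ms: np.ndarray  # (T,)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def extract_traces(
    movie: ImagingMovie | RegisteredMovie, masks: ROIMaskSet
) -> TraceMatrix:
    """Weighted mean of each mask's pixels in every frame."""
    frames = movie.frames
    T, H, W = frames.shape
    if masks.fov_shape != (H, W):
        raise InputError("mask set FOV does not match the movie")
    flat = frames.reshape(T, -1)
    out = np.empty((len(masks), T), dtype=np.float64)
    for i, m in enumerate(masks):
        if m.area_px == 0:
            raise InputError(f"mask {i} is empty")
        w = m.weights / m.weights.sum()
        out[i] = flat[:, m.rows * W + m.cols] @ w
    times = movie.frame_times_ms if hasattr(movie, "frame_times_ms") else np.arange(T)
    return TraceMatrix(values=out, frame_times_ms=np.asarray(times, dtype=float))


def aspect_ratio(mask: ROIMask) -> float:
    """Elongation of a footprint: sqrt of the eigenvalue ratio of the weighted
    pixel-coordinate covariance, with the variance of a unit pixel (1/12 px^2)
    added per axis so 1-px-wide masks stay finite."""
    if mask.area_px < 2:
        return float("nan")
    w = mask.weights / mask.weights.sum()
    xy = np.column_stack([mask.rows, mask.cols]).astype(float)
    mu = w @ xy
    d = xy - mu
    cov = (d * w[:, None]).T @ d + PIXEL_VARIANCE * np.eye(2)
    lam = np.linalg.eigvalsh(cov)  # ascending
    return float(np.sqrt(lam[1] / lam[0]))


def classify_dendritic(mask: ROIMask) -> tuple[str, float]:
    """Dendritic/axonal iff aspect ratio > 2; masks under 2 px are 'other'."""
    if mask.area_px < 2:
        return "other", float("nan")
    ratio = aspect_ratio(mask)
    return ("dendritic" if ratio > DENDRITIC_ASPECT_THRESHOLD else "other"), ratio


def detect_duplicates(
    traces: TraceMatrix | np.ndarray, rho_threshold: float = 0.8
) -> list[tuple[int, int, float]]:
    """Flag ROI pairs whose traces correlate at or above ``rho_threshold``.

    Pearson correlation over all frames; one-sided (anti-correlated pairs are
    not duplicates).  Flag only — all ROIs are retained.  Pairs involving a
    constant trace are skipped with a warning.
    """
    X = traces.values if isinstance(traces, TraceMatrix) else np.asarray(traces)
    if X.shape[0] < 2:
        raise InputError("need at least 2 traces")
    sd = X.std(axis=1)
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} constant trace(s); correlation undefined, "
            "their pairs were skipped",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(X)
    pairs = []
    n = X.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                continue
            if rho[i, j] >= rho_threshold:
                pairs.append((i, j, float(rho[i, j])))
    return pairs


def _kdist_eps(X: np.ndarray, k: int = 4, percentile: float = 95.0) -> float:
    """eps from the k-distance curve: the 95th percentile of k-NN distances.

    Covering almost every point's k-neighborhood keeps a uniform-density
    continuum density-connected (one cluster) while leaving well-separated
    groups apart, which is exactly the distinction the response-continuum
    check needs."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0]))
    nn.fit(X)
    dist, _ = nn.kneighbors(X)
    kd = dist[:, -1]
    return float(np.percentile(kd, percentile))


def cluster_response_check(
    response_vectors: np.ndarray,
    eps: float | None = None,
    min_samples: int = 4,
) -> tuple[np.ndarray, int, int]:
    """Density-based clustering of per-ROI response vectors.

    Supports the sanity check that trial-averaged responses form a continuum
    (a single density-connected cluster) rather than distinct separable
    groups.  ``eps`` defaults to a k-distance elbow heuristic (k = 4).

    Returns ``(labels, n_clusters, n_noise)``; label -1 marks noise points.
    """
    X = np.asarray(response_vectors, dtype=np.float64)
    if X.ndim != 2:
        raise InputError("response vectors must be a 2-D array (roi x feature)")
    if X.shape[0] < 5:
        raise InsufficientDataError("need at least 5 ROIs for the clustering check")
    if eps is None:
        eps = _kdist_eps(X, k=min_samples)
        # identical vectors give a zero k-distance curve
        eps = max(eps, 1e-12)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(X)
    n_clusters = int(len(set(labels)) - (1 if -1 in labels else 0))
    n_noise = int(np.sum(labels == -1))
    return labels, n_clusters, n_noise
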