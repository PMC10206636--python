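"""Ventilation-defect segmentation and VDP computation.

Two segmentation methods operate on the voxel intensities inside a thoracic
cavity mask:

* **Adaptive thresholding** — a voxel is "ventilation defect" if its intensity
  is strictly below ``factor * Mean_5-80``, where ``Mean_5-80`` is the mean of
  cavity intensities between the 5th and 80th intensity percentiles.
* **k-means clustering** — cavity intensities are binned into ``k`` clusters
  (default 5) by 1-D Lloyd iteration from a deterministic quantile
  initialization; the lowest-center cluster(s) are the defect.

Either way, the ventilation defect percent (VDP) is the defect volume as a
percentage of the thoracic cavity volume.

The two methods are exposed as scikit-learn style estimators
(:class:`AdaptiveThresholdSegmenter`, :class:`VentilationKMeans`) operating on
the 1-D cavity intensity sample; the module-level functions wrap them for
volume/mask inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .io import CavityMask, VolumeGrid, check_same_grid

logger = logging.getLogger(__name__)

#: Smallest cavity (voxels) accepted by the adaptive threshold: below this the
#: 5th-80th percentile rank window is empty or unstable.
MIN_CAVITY_VOXELS = 20


@dataclass
class ThresholdParams:
    """Parameters of the adaptive threshold: ``factor * Mean_{lower-upper}``."""

    factor: float = 0.5
    lower_percentile: float = 5.0
    upper_percentile: float = 80.0

    def __post_init__(self) -> None:
        if not (0 <= self.lower_percentile < self.upper_percentile <= 100):
            raise ValueError(
                f"require 0 <= lower < upper <= 100, got "
                f"({self.lower_percentile}, {self.upper_percentile})"
            )
        if self.factor <= 0:
            raise ValueError(f"factor must be > 0, got {self.factor}")


@dataclass
class KMeansParams:
    """Parameters of the 1-D intensity k-means segmentation."""

    k: int = 5
    max_iter: int = 300
    tol: float = 1e-6  # convergence threshold, as a fraction of cavity intensity range
    defect_clusters: int = 1  # lowest-center clusters labeled defect

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if not (1 <= self.defect_clusters < self.k):
            raise ValueError(
                f"defect_clusters must satisfy 1 <= defect_clusters < k, "
                f"got {self.defect_clusters} with k={self.k}"
            )


@dataclass
class DefectSegmentation:
    """Binary defect map plus method metadata."""

    defect_mask: np.ndarray
    method: str  # "threshold" | "kmeans"
    threshold_value: Optional[float] = None
    cluster_centers: Optional[np.ndarray] = None
    iterations_used: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.defect_mask = np.asarray(self.defect_mask).astype(bool)
        if self.method not in ("threshold", "kmeans"):
            raise ValueError(f"method must be 'threshold' or 'kmeans', got {self.method!r}")
        if self.cluster_centers is not None:
            c = np.asarray(self.cluster_centers, dtype=float)
            if np.any(np.diff(c) <= 0):
                raise ValueError("cluster_centers must be strictly ascending")
            self.cluster_centers = c

    def sidecar(self) -> dict:
        """JSON-serializable method metadata."""
        meta = {
            "method": self.method,
            "iterations_used": int(self.iterations_used),
            "converged": bool(self.converged),
        }
        if self.threshold_value is not None:
            meta["threshold_value"] = float(self.threshold_value)
        if self.cluster_centers is not None:
            meta["cluster_centers"] = [float(c) for c in self.cluster_centers]
        return meta


@dataclass
class VDPResult:
    """Whole-lung ventilation defect percent with volumes and provenance."""

    vdp_percent: float
    defect_volume_ml: float
    cavity_volume_ml: float
    method: str
    modality: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.vdp_percent <= 100.0):
            raise ValueError(f"VDP {self.vdp_percent} outside [0, 100]")
        if self.defect_volume_ml > self.cavity_volume_ml + 1e-12:
            raise ValueError("defect volume exceeds cavity volume")
        expected = 100.0 * self.defect_volume_ml / self.cavity_volume_ml
        if abs(self.vdp_percent - expected) > 1e-9:
            raise ValueError(
                f"inconsistent VDP: {self.vdp_percent} vs "
                f"100*defect/cavity = {expected}"
            )


def _percentile_rank_window(n: int, lower: float, upper: float) -> tuple[int, int]:
    """1-based rank bounds (lo, hi) such that the window is lo <= r <= hi.

    The window keeps ascending ordinal ranks r with ``lower/100 * n < r <=
    upper/100 * n``. Products that land within 1e-9 of an integer are snapped
    to it so that float representation of the percentiles cannot shift the
    window by one rank.
    """
    def snap(x: float) -> float:
        r = round(x)
        return float(r) if abs(x - r) < 1e-9 else x

    lo = int(math.floor(snap(n * lower / 100.0))) + 1
    hi = int(math.floor(snap(n * upper / 100.0)))
    return lo, hi


class AdaptiveThresholdSegmenter(BaseEstimator):
    """Adaptive-threshold defect segmentation of a 1-D intensity sample.

    ``fit`` computes the threshold ``factor * Mean_{lower-upper}`` from the
    intensity sample; ``predict`` labels intensities 1 (defect, strictly below
    the threshold) or 0 (ventilated).

    Parameters
    ----------
    factor : float, default 0.5
        Multiplier applied to the windowed mean.
    lower_percentile, upper_percentile : float, defaults 5 and 80
        Percentile window over which the mean is taken. The window is a rank
        window: ascending 1-based ranks r with lower/100*N < r <= upper/100*N,
        ties ordered by ordinal rank (no percentile interpolation).

    Attributes
    ----------
    threshold_ : float
        The fitted threshold, in signal units.
    mean_window_ : float
        The windowed mean the threshold was derived from.
    """

    def __init__(self, factor: float = 0.5, lower_percentile: float = 5.0,
                 upper_percentile: float = 80.0):
        self.factor = factor
        self.lower_percentile = lower_percentile
        self.upper_percentile = upper_percentile

    def _params(self) -> ThresholdParams:
        return ThresholdParams(self.factor, self.lower_percentile, self.upper_percentile)

    def fit(self, X, y=None):
        self._params()  # validate
        x = np.asarray(X, dtype=float).ravel()
        n = x.size
        if n < MIN_CAVITY_VOXELS:
            raise ValueError(
                f"cavity too small for adaptive threshold: {n} voxels "
                f"(minimum {MIN_CAVITY_VOXELS})"
            )
        lo, hi = _percentile_rank_window(n, self.lower_percentile, self.upper_percentile)
        if hi < lo:
            raise ValueError(
                f"empty percentile window ({self.lower_percentile}, "
                f"{self.upper_percentile}) for n={n}"
            )
        ordered = np.sort(x, kind="stable")
        window = ordered[lo - 1 : hi]
        self.mean_window_ = float(window.mean())
        self.threshold_ = float(self.factor * self.mean_window_)
        self.n_samples_ = n
        return self

    def predict(self, X) -> np.ndarray:
        """1 for defect (intensity strictly below the threshold), else 0."""
        check_is_fitted(self, "threshold_")
        x = np.asarray(X, dtype=float)
        return (x < self.threshold_).astype(int)


class VentilationKMeans(ClusterMixin, BaseEstimator):
    """1-D k-means intensity clustering with a deterministic initialization.

    Lloyd iterations on the intensity sample from three deterministic
    initializations — the ``(2i-1)/(2k)`` mass quantiles (i = 1..k), the same
    quantiles of the distinct values, and evenly spaced points over the value
    range — keeping the fixed point with the lowest within-cluster sum of
    squares. Multi-start matters when one intensity mode holds most of the
    mass (a severe-defect lung): mass quantiles alone then seed several
    centers inside that mode and Lloyd cannot escape the split. No random
    seed is involved, so the fit is reproducible across runs and platforms.
    Ties in assignment go to the lower-center cluster; an empty cluster is
    re-seeded at the sample point farthest from its current center. At the
    fixed point every point is assigned to its nearest center and every
    center is the mean of its cluster.

    Attributes
    ----------
    cluster_centers_ : ndarray, shape (k,)
        Fitted centers, strictly ascending.
    labels_ : ndarray
        Cluster index per training sample (0 = lowest center).
    n_iter_ : int
    converged_ : bool
    inertia_ : float
        Within-cluster sum of squares at the fixed point.
    """

    def __init__(self, n_clusters: int = 5, max_iter: int = 300, tol: float = 1e-6,
                 defect_clusters: int = 1):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.tol = tol
        self.defect_clusters = defect_clusters

    def _params(self) -> KMeansParams:
        return KMeansParams(self.n_clusters, self.max_iter, self.tol, self.defect_clusters)

    def fit(self, X, y=None):
        self._params()  # validate
        x = np.asarray(X, dtype=float).ravel()
        k = self.n_clusters
        uniq = np.unique(x)
        if uniq.size < k:
            raise ValueError(
                "degenerate intensity distribution: fewer than "
                f"{k} distinct intensities in the cavity"
            )
        q = (2 * np.arange(1, k + 1) - 1) / (2.0 * k)
        inits = [
            np.quantile(x, q),  # mass quantiles (primary)
            np.quantile(uniq, q),  # quantiles of distinct values
            x.min() + q * (x.max() - x.min()),  # even spread over the range
        ]
        best = None
        for centers0 in inits:
            run = self._lloyd(x, np.asarray(centers0, dtype=float))
            if best is None or run[4] < best[4] - 1e-12:
                best = run
        centers, labels, n_iter, converged, _inertia, objective_path = best
        self.objective_path_ = objective_path

        # report centers ascending; remap labels accordingly
        order = np.argsort(centers, kind="stable")
        centers_sorted = centers[order]
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[labels]

        self.cluster_centers_ = centers_sorted
        self.labels_ = labels
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.inertia_ = float(np.sum((x - centers_sorted[labels]) ** 2))
        return self

    def _lloyd(self, x: np.ndarray, centers: np.ndarray):
        """One Lloyd run to a fixed point; returns (centers, labels, n_iter,
        converged, inertia, objective_path)."""
        k = self.n_clusters
        abs_tol = self.tol * float(x.max() - x.min())
        converged = False
        n_iter = 0
        shift = np.inf
        objective_path = []
        labels = self._assign(x, centers)
        for n_iter in range(1, self.max_iter + 1):
            new_centers = centers.copy()
            for j in range(k):
                sel = labels == j
                if sel.any():
                    new_centers[j] = x[sel].mean()
            # re-seed empty clusters at the point farthest from its center,
            # lowest cluster index first
            for j in range(k):
                if not (labels == j).any():
                    far = np.argmax(np.abs(x - new_centers[j]))
                    new_centers[j] = x[far]
            shift = float(np.max(np.abs(new_centers - centers)))
            centers = new_centers
            new_labels = self._assign(x, centers)
            objective_path.append(float(np.sum((x - centers[new_labels]) ** 2)))
            if shift <= abs_tol and np.array_equal(new_labels, labels):
                labels = new_labels
                converged = True
                break
            labels = new_labels
        if not converged:
            logger.warning(
                "k-means did not converge within %d iterations (last shift %.3g)",
                self.max_iter, shift,
            )
        inertia = float(np.sum((x - centers[labels]) ** 2))
        return centers, labels, n_iter, converged, inertia, objective_path

    @staticmethod
    def _assign(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
        """Nearest-center assignment; ties go to the lower-center cluster."""
        order = np.argsort(centers, kind="stable")
        d = np.abs(x[:, None] - centers[order][None, :])
        # argmin returns the first (lowest-center) index on ties
        return order[np.argmin(d, axis=1)]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        x = np.asarray(X, dtype=float).ravel()
        d = np.abs(x[:, None] - self.cluster_centers_[None, :])
        return np.argmin(d, axis=1)

    def defect_labels(self) -> np.ndarray:
        """Boolean per-sample flag: in one of the defect (lowest) clusters."""
        check_is_fitted(self, "labels_")
        return self.labels_ < self.defect_clusters


# ---------------------------------------------------------------------------
# volume/mask wrappers


def compute_adaptive_threshold(volume: VolumeGrid, cavity: CavityMask,
                               params: Optional[ThresholdParams] = None) -> float:
    """Threshold = factor x mean of cavity intensities in the percentile window."""
    params = params or ThresholdParams()
    check_same_grid(volume, cavity)
    seg = AdaptiveThresholdSegmenter(
        params.factor, params.lower_percentile, params.upper_percentile
    ).fit(volume.intensities[cavity.mask])
    return seg.threshold_


def segment_threshold(volume: VolumeGrid, cavity: CavityMask,
                      params: Optional[ThresholdParams] = None) -> DefectSegmentation:
    """Adaptive-threshold segmentation: cavity voxels strictly below threshold."""
    params = params or ThresholdParams()
    check_same_grid(volume, cavity)
    est = AdaptiveThresholdSegmenter(
        params.factor, params.lower_percentile, params.upper_percentile
    ).fit(volume.intensities[cavity.mask])
    defect = np.zeros(volume.shape, dtype=bool)
    defect[cavity.mask] = est.predict(volume.intensities[cavity.mask]).astype(bool)
    return DefectSegmentation(
        defect_mask=defect,
        method="threshold",
        threshold_value=est.threshold_,
    )


def segment_kmeans(volume: VolumeGrid, cavity: CavityMask,
                   params: Optional[KMeansParams] = None) -> DefectSegmentation:
    """k-means segmentation: lowest-center cluster(s) of cavity intensities."""
    params = params or KMeansParams()
    check_same_grid(volume, cavity)
    est = VentilationKMeans(
        n_clusters=params.k, max_iter=params.max_iter, tol=params.tol,
        defect_clusters=params.defect_clusters,
    ).fit(volume.intensities[cavity.mask])
    defect = np.zeros(volume.shape, dtype=bool)
    defect[cavity.mask] = est.defect_labels()
    return DefectSegmentation(
        defect_mask=defect,
        method="kmeans",
        cluster_centers=est.cluster_centers_,
        iterations_used=est.n_iter_,
        converged=est.converged_,
    )


def compute_vdp(seg: DefectSegmentation, cavity: CavityMask,
                volume: VolumeGrid) -> VDPResult:
    """VDP = 100 x defect volume / thoracic cavity volume."""
    check_same_grid(volume, cavity)
    if seg.defect_mask.shape != cavity.shape:
        raise ValueError(
            f"segmentation shape {seg.defect_mask.shape} != cavity {cavity.shape}"
        )
    if np.any(seg.defect_mask & ~cavity.mask):
        raise ValueError("defect voxel outside the thoracic cavity (invariant breach)")
    n_defect = int(seg.defect_mask.sum())
    n_cavity = cavity.n_voxels
    vv = cavity.voxel_volume_ml
    return VDPResult(
        vdp_percent=100.0 * n_defect / n_cavity,
        defect_volume_ml=n_defect * vv,
        cavity_volume_ml=n_cavity * vv,
        method=seg.method,
        modality=volume.modality,
    )
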