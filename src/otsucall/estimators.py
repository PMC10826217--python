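"""Scikit-learn-style estimators wrapping the calling pipeline.

``CNVDetector`` is a transductive per-bin anomaly detector in the spirit of
:class:`sklearn.neighbors.LocalOutlierFactor`: ``fit`` segments the profile,
clusters the segments and thresholds the categories, after which the fitted
attributes expose every intermediate product and ``predict()`` returns the
per-bin labels of the fitted data.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator

from . import classify as _cls
from .profile import RDProfile
from .segmentation import SegParams, segment

__all__ = ["AdaptiveSegmenter", "CNVDetector"]


def _as_profile(X, bin_size: int, chrom: str) -> RDProfile:
    if isinstance(X, RDProfile):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D read-depth vector, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty read-depth vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("read-depth vector contains non-finite values")
    if arr.min() < 0:
        raise ValueError("read-depth values must be non-negative")
    return RDProfile(chrom=chrom, bin_size=bin_size, values=arr)


class AdaptiveSegmenter(BaseEstimator):
    """Breakpoint detector for a binned read-depth signal.

    Parameters
    ----------
    k : int
        Maximum one-sided window size in bins.
    w_min : float
        Weight threshold terminating window accumulation.
    boxplot_mult : float
        IQR multiplier of the candidate gate.
    bin_size : int
        Bin width used when ``X`` is a bare vector.

    Attributes
    ----------
    breakpoints_ : ndarray of int
        Bin indices starting a new segment.
    segments_ : list of (int, int)
        Half-open index ranges partitioning the profile.
    diff_ : ndarray
        Mean-difference profile (normalized scale).
    bounds_ : (float, float)
        Lower/upper boxplot fence applied to ``diff_``.
    """

    def __init__(self, k: int = 50, w_min: float = math.exp(-10.0),
                 boxplot_mult: float = 3.5, noise_target: float | None = 0.15,
                 bin_size: int = 1000):
        self.k = k
        self.w_min = w_min
        self.boxplot_mult = boxplot_mult
        self.noise_target = noise_target
        self.bin_size = bin_size

    def fit(self, X, y=None):
        profile = _as_profile(X, self.bin_size, "seq")
        seg = segment(profile, SegParams(self.k, self.w_min, self.boxplot_mult,
                                         self.noise_target))
        self.segmentation_ = seg
        self.breakpoints_ = np.asarray(seg.breakpoints, dtype=int)
        self.segments_ = list(seg.segments)
        self.diff_ = seg.diff
        self.bounds_ = seg.bounds
        self.n_features_in_ = profile.n_bins
        return self

    def fit_predict(self, X, y=None):
        """Per-bin segment labels (0-based, increasing along the profile)."""
        self.fit(X)
        labels = np.empty(self.n_features_in_, dtype=int)
        for sid, (a, b) in enumerate(self.segments_):
            labels[a:b] = sid
        return labels


class CNVDetector(BaseEstimator):
    """Full read-depth CNV caller: segmentation + t-test clustering + Otsu.

    Parameters
    ----------
    bin_size : int
        Bin width in bases (used for coordinates and when ``X`` is a vector).
    k, w_min, boxplot_mult :
        Segmentation parameters, see :class:`AdaptiveSegmenter`.
    alpha : float
        Significance level of the Welch t-test used to cluster segments.
    suppress : bool
        Apply extreme-value suppression to the distance array before Otsu.
    chrom : str
        Contig name attached to calls when ``X`` is a bare vector.

    Attributes
    ----------
    profile_ : RDProfile
    segmentation_ : Segmentation
    categories_ : CategoryTable
    u_normal_ : float
        Estimated copy-neutral read depth.
    distances_ : DistanceArray
        Sorted (and possibly suppressed) category distances fed to Otsu.
    otsu_ : OtsuResult
    calls_ : list of CNVCall
    labels_ : ndarray of int
        Per retained bin: 0 normal, +1 gain, -1 loss.
    """

    def __init__(self, bin_size: int = 1000, k: int = 50,
                 w_min: float = math.exp(-10.0), alpha: float = 0.05,
                 boxplot_mult: float = 3.5, noise_target: float | None = 0.15,
                 suppress: bool = True, chrom: str = "seq"):
        self.bin_size = bin_size
        self.k = k
        self.w_min = w_min
        self.alpha = alpha
        self.boxplot_mult = boxplot_mult
        self.noise_target = noise_target
        self.suppress = suppress
        self.chrom = chrom

    def fit(self, X, y=None):
        profile = _as_profile(X, self.bin_size, self.chrom)
        values = profile.values
        seg = segment(profile, SegParams(self.k, self.w_min, self.boxplot_mult,
                                         self.noise_target))
        table = _cls.merge_segments_ttest(
            [values[a:b] for a, b in seg.segments], alpha=self.alpha)
        table.u_normal = _cls.estimate_normal_rd(
            table, global_mean=float(values.mean()))
        d = _cls.distance_array(table)
        if self.suppress:
            d = _cls.suppress_extremes(d)
        otsu = _cls.otsu_threshold(d)
        calls = _cls.call_cnvs(profile, seg, table, otsu)

        labels = np.zeros(profile.n_bins, dtype=int)
        abnormal = set(int(c) for c in otsu.class1)
        for cat_idx in abnormal:
            sign = 1 if table.u[cat_idx] > table.u_normal else -1
            for sid in table.categories[cat_idx].segment_ids:
                a, b = seg.segments[sid]
                labels[a:b] = sign

        self.profile_ = profile
        self.segmentation_ = seg
        self.categories_ = table
        self.u_normal_ = table.u_normal
        self.distances_ = d
        self.otsu_ = otsu
        self.calls_ = calls
        self.labels_ = labels
        self.n_features_in_ = profile.n_bins
        return self

    def predict(self, X=None):
        """Per-bin labels of the fitted profile (0 normal, +1 gain, -1 loss).

        The detector is transductive: it labels the data it was fitted on.
        Pass ``X`` (or call :meth:`fit_predict`) to fit and label in one step.
        """
        if X is not None:
            self.fit(X)
        if not hasattr(self, "labels_"):
            raise AttributeError("CNVDetector is not fitted yet; call fit first")
        return self.labels_

    def fit_predict(self, X, y=None):
        return self.fit(X).predict()
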