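"""Adaptive weighted-mean segmentation of a read-depth profile.

At every bin boundary the algorithm compares a robust *right-sided* mean
anchored just after the boundary with a robust *left-sided* mean anchored
just before it. Each one-sided mean weights nearby bins by

    omega(m | anchor) = exp(-sum of squared successive RD differences
                             along the path from the anchor to m)

so the weight decays slowly inside a constant-copy-number run and collapses
as soon as the path crosses a jump. The boundary-wise difference of the two
means (the ``Diff`` profile) peaks at copy-number breakpoints; candidates are
gated by a wide boxplot fence (Q3 + 3.5*IQR and Q1 - 3.5*IQR) and each
maximal run of consecutive candidates contributes the location of its
extremum as one breakpoint.

The accumulated exponent is monotone along the path, so the weight sequence
is nonincreasing; truncating at ``w_min`` is therefore equivalent to dropping
every point whose weight falls below it, which makes the whole Diff profile
computable with O(N*k) vectorized work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profile import RDProfile

__all__ = [
    "SegParams",
    "Segmentation",
    "one_sided_mean",
    "mean_diff_profile",
    "boxplot_bounds",
    "detect_breakpoints",
    "segment",
]


@dataclass
class SegParams:
    """Tuning knobs of the segmenter.

    k : maximum one-sided window size in bins (anchor included).
    w_min : weight below which window accumulation stops.
    boxplot_mult : IQR multiplier of the candidate gate (3.5 by construction
        of the method; override only for experimentation).
    noise_target : target per-bin noise level of the weight kernel. Before
        computing weights the mean-normalized profile is rescaled so that a
        robust estimate of its per-bin noise (median absolute successive
        difference) lands at this value, which keeps the kernel bandwidth
        comparable across coverages: noisy low-coverage data get wider,
        more-averaging windows, clean high-coverage data get sharper ones.
        Set to None to disable the rescaling.
    scale_max : upper cap of the rescaling factor (guards near-noiseless data).
    """

    k: int = 50
    w_min: float = math.exp(-10.0)
    boxplot_mult: float = 3.5
    noise_target: float | None = 0.15
    scale_max: float = 4.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not (0.0 < self.w_min < 1.0):
            raise ValueError(f"w_min must be in (0, 1), got {self.w_min}")
        if self.boxplot_mult <= 0:
            raise ValueError("boxplot_mult must be positive")
        if self.noise_target is not None and self.noise_target <= 0:
            raise ValueError("noise_target must be positive or None")
        if self.scale_max <= 0:
            raise ValueError("scale_max must be positive")


@dataclass
class Segmentation:
    """Breakpoints and the induced partition of the bin index range [0, N).

    ``breakpoints[j] = b`` marks a boundary between bin ``b-1`` and bin ``b``;
    bin ``b`` starts the right-hand segment. ``diff[t]`` is the mean-difference
    value at the boundary between bins ``t`` and ``t+1`` (computed on the
    mean-normalized, kernel-rescaled profile). ``segments`` are half-open
    index ranges; ``kernel_scale`` is the rescaling factor that was applied.
    """

    breakpoints: np.ndarray
    segments: list
    diff: np.ndarray
    bounds: tuple = (0.0, 0.0)
    kernel_scale: float = 1.0

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def _one_sided_means(r: np.ndarray, k: int, w_min: float):
    """Vectorized right- and left-sided weighted means at every anchor."""
    n = r.size
    cum = np.concatenate(([0.0], np.cumsum(np.diff(r) ** 2)))
    num_r = r.astype(float).copy()
    den_r = np.ones(n)
    num_l = r.astype(float).copy()
    den_l = np.ones(n)
    for d in range(1, min(k, n)):
        w = np.exp(-(cum[d:n] - cum[: n - d]))
        w[w < w_min] = 0.0
        num_r[: n - d] += w * r[d:]
        den_r[: n - d] += w
        num_l[d:] += w * r[: n - d]
        den_l[d:] += w
    return num_r / den_r, num_l / den_l


def one_sided_mean(r, i: int, side: str, params: SegParams | None = None) -> float:
    """Robust one-sided weighted mean anchored at index ``i``.

    The anchor has weight 1; each further point's weight is the exponential of
    minus the accumulated squared successive differences along the path, and
    accumulation stops once the weight drops below ``params.w_min`` or the
    window reaches ``params.k`` points.
    """
    if params is None:
        params = SegParams()
    r = np.asarray(r, dtype=float)
    n = r.size
    if not 0 <= i < n:
        raise IndexError(f"anchor {i} out of range for length {n}")
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    step = 1 if side == "right" else -1
    num = float(r[i])
    den = 1.0
    acc = 0.0
    for d in range(1, params.k):
        m = i + step * d
        if m < 0 or m >= n:
            break
        acc += (r[m] - r[m - step]) ** 2
        w = math.exp(-acc)
        if w < params.w_min:
            break
        num += w * r[m]
        den += w
    return num / den


def mean_diff_profile(r, params: SegParams | None = None) -> np.ndarray:
    """Boundary-wise difference of right- and left-sided robust means.

    Element ``t`` is the value at the boundary between bins ``t`` and ``t+1``:
    right mean anchored at ``t+1`` minus left mean anchored at ``t``. Returns
    an empty vector for profiles shorter than 2 bins.
    """
    if params is None:
        params = SegParams()
    r = np.asarray(r, dtype=float)
    if r.size < 2:
        return np.empty(0)
    u_right, u_left = _one_sided_means(r, params.k, params.w_min)
    return u_right[1:] - u_left[:-1]


def boxplot_bounds(diff, mult: float = 3.5):
    """Wide boxplot fence ``(Q1 - mult*IQR, Q3 + mult*IQR)`` of a vector."""
    diff = np.asarray(diff, dtype=float)
    if diff.size == 0:
        raise ValueError("cannot compute boxplot bounds of an empty vector")
    q1, q3 = np.percentile(diff, [25, 75])
    iqr = q3 - q1
    return (q1 - mult * iqr, q3 + mult * iqr)


def _run_extrema(diff: np.ndarray, candidates: np.ndarray, take_max: bool) -> list:
    idx = np.flatnonzero(candidates)
    if idx.size == 0:
        return []
    out = []
    for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
        vals = diff[run]
        pos = int(np.argmax(vals)) if take_max else int(np.argmin(vals))
        out.append(int(run[pos]))  # argmax/argmin return the leftmost tie
    return out


def detect_breakpoints(diff, bounds, atol: float = 0.0) -> list:
    """Locations of run extrema among out-of-fence Diff values.

    Positions with ``diff > upper`` form candidate runs; each maximal run of
    consecutive candidates yields the position of its maximum (leftmost on
    ties). Runs below ``lower`` symmetrically yield run minima. Indices are
    positions in ``diff`` and are returned strictly increasing. ``atol``
    widens the fence by an absolute margin so that floating-point dust does
    not fire when the interquartile range collapses to zero.
    """
    diff = np.asarray(diff, dtype=float)
    lower, upper = bounds
    hits = _run_extrema(diff, diff > upper + atol, take_max=True)
    hits += _run_extrema(diff, diff < lower - atol, take_max=False)
    return sorted(hits)


def _kernel_scale(r: np.ndarray, params: SegParams) -> float:
    """Rescaling factor standardizing the per-bin noise seen by the kernel.

    The noise level is estimated as the median absolute successive difference
    (robust to the small fraction of positions that are true jumps); the
    factor is capped and defaults to 1 on (near-)noiseless profiles.
    """
    if params.noise_target is None:
        return 1.0
    sigma = float(np.median(np.abs(np.diff(r)))) / (0.6745 * math.sqrt(2.0))
    if sigma < 1e-12:
        # noiseless signal: the kernel can afford maximal sharpness
        return params.scale_max
    return min(params.noise_target / sigma, params.scale_max)


def segment(profile: RDProfile, params: SegParams | None = None) -> Segmentation:
    """Partition a profile into contiguous constant-copy-number segments.

    The profile is normalized by its global mean and rescaled to the kernel's
    target noise level before the weight and mean computations (so the weight
    decay scale is comparable across coverages); segments afterwards refer to
    the original values by index range.
    """
    if params is None:
        params = SegParams()
    values = profile.values
    n = values.size
    if n < 2:
        segs = [(0, n)] if n else []
        return Segmentation(np.empty(0, dtype=int), segs, np.empty(0))
    mean = values.mean()
    r = values / mean if mean > 0 else values.astype(float)
    scale = _kernel_scale(r, params)
    r = r * scale
    diff = mean_diff_profile(r, params)
    bounds = boxplot_bounds(diff, mult=params.boxplot_mult)
    atol = 1e-9 * max(1.0, float(np.max(np.abs(diff))) if diff.size else 1.0)
    hits = detect_breakpoints(diff, bounds, atol=atol)
    breakpoints = np.asarray([t + 1 for t in hits], dtype=int)
    edges = [0, *breakpoints.tolist(), n]
    segments = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    return Segmentation(breakpoints, segments, diff, bounds, kernel_scale=scale)
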