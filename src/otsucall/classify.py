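"""Separate abnormal (CNV) segments from copy-neutral ones.

Segments are first clustered into read-depth categories by greedy
agglomeration: the pair of current categories with the largest Welch
two-sided t-test p-value is merged (pooling their per-bin values) while that
p-value exceeds ``alpha``. Each category gets a representative mean ``u_i``
and an occurrence probability ``p_i = n_i / n`` counted over segments.

Categories are then mapped to distances ``|u_i - u_normal|`` from the
copy-neutral depth, sorted ascending, optionally clamped at the mean
distance (extreme-value suppression, which stops one huge-amplitude gain
from dragging the threshold past low-amplitude events), and split by the
Otsu criterion: the threshold index maximizing the between-class variance

    sigma^2(k) = w0*w1*(mu1 - mu0)^2 = (mu_T*w(k) - mu(k))^2 / (w(k)*(1 - w(k)))

Categories beyond the threshold are abnormal; their segments become CNV
calls, typed gain or loss by the sign of ``u_i - u_normal``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .profile import RDProfile
from .segmentation import Segmentation

__all__ = [
    "Category",
    "CategoryTable",
    "DistanceArray",
    "OtsuResult",
    "CNVCall",
    "merge_segments_ttest",
    "estimate_normal_rd",
    "distance_array",
    "suppress_extremes",
    "otsu_threshold",
    "call_cnvs",
]

_ZERO_VAR = 1e-18
_MEAN_TIE = 1e-9


@dataclass
class Category:
    """One read-depth class: the segments pooled into it and their summary stats."""

    segment_ids: list
    n_values: int
    mean: float
    m2: float  # sum of squared deviations from the mean

    @property
    def var(self) -> float:
        return self.m2 / (self.n_values - 1) if self.n_values > 1 else 0.0


@dataclass
class CategoryTable:
    """Clustered RD categories with representative means and probabilities.

    ``p[i]`` is the fraction of *segments* belonging to category ``i`` (sums
    to 1); ``u[i]`` is the mean of all per-bin RD values pooled into it.
    """

    categories: list
    u: np.ndarray
    p: np.ndarray
    u_normal: float | None = None

    @property
    def m(self) -> int:
        return len(self.categories)

    def n_bins(self) -> np.ndarray:
        return np.asarray([c.n_values for c in self.categories])


@dataclass
class DistanceArray:
    """Category distances from the copy-neutral depth, sorted ascending.

    ``perm[j]`` is the category index occupying sorted position ``j``; ``p``
    is co-permuted with the distances.
    """

    x: np.ndarray
    p: np.ndarray
    perm: np.ndarray


@dataclass
class OtsuResult:
    """Optimal split of the sorted distance array.

    ``k_star`` categories (sorted positions ``0..k_star-1``) form the normal
    side ``class0``; the rest (``class1``) are abnormal. ``k_star`` is None
    when no split exists (fewer than two categories, or zero between-class
    variance everywhere).
    """

    k_star: int | None
    sigma2: float
    class0: np.ndarray
    class1: np.ndarray
    sigma2_all: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class CNVCall:
    """A declared copy-number variant (1-based inclusive coordinates)."""

    chrom: str
    start: int
    end: int
    type: str  # "gain" or "loss"
    rd_mean: float


# ---------------------------------------------------------------------------
# t-test clustering
# ---------------------------------------------------------------------------

def _welch_p(n1, m1, v1, n2, m2, v2) -> float:
    """Two-sided Welch t-test p-value from summary statistics."""
    if v1 <= _ZERO_VAR and v2 <= _ZERO_VAR:
        return 1.0 if abs(m1 - m2) < _MEAN_TIE else 0.0
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2.0 * stats.t.sf(abs(t), df))


def _pool(a: Category, b: Category) -> Category:
    """Exact pooled summary statistics (parallel variance update)."""
    n = a.n_values + b.n_values
    delta = b.mean - a.mean
    mean = a.mean + delta * b.n_values / n
    m2 = a.m2 + b.m2 + delta ** 2 * a.n_values * b.n_values / n
    return Category(sorted(a.segment_ids + b.segment_ids), n, mean, m2)


def _summary(seg_id: int, vals: np.ndarray) -> Category:
    return Category([seg_id], vals.size, float(vals.mean()),
                    float(((vals - vals.mean()) ** 2).sum()))


def merge_segments_ttest(segment_values, alpha: float = 0.05) -> CategoryTable:
    """Cluster segments into RD categories by greedy Welch-t agglomeration.

    Parameters
    ----------
    segment_values : sequence of 1-D arrays
        Per-bin RD values of each segment, in genomic order.
    alpha : float
        Significance level; the pair with the largest p-value is merged while
        that p-value exceeds ``alpha``.

    Segments with fewer than 2 values cannot be tested and are attached to
    the category whose representative mean is nearest.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    arrs = [np.asarray(v, dtype=float) for v in segment_values]
    n_total = len(arrs)
    if n_total == 0:
        raise ValueError("no segments to cluster")

    classes = [_summary(i, a) for i, a in enumerate(arrs) if a.size >= 2]
    singletons = [i for i, a in enumerate(arrs) if a.size < 2]

    if not classes:
        # all segments are single-bin: group exactly-equal means
        for i in singletons:
            v = arrs[i]
            for c in classes:
                if abs(c.mean - float(v[0])) < _MEAN_TIE:
                    merged = _pool(c, _summary(i, v))
                    c.segment_ids, c.n_values, c.mean, c.m2 = (
                        merged.segment_ids, merged.n_values, merged.mean, merged.m2)
                    break
            else:
                classes.append(_summary(i, v))
        singletons = []

    # greedy agglomeration: repeatedly merge the most-similar pair,
    # re-testing the pooled class against all others after each merge
    def pair_p(a: Category, b: Category) -> float:
        return _welch_p(a.n_values, a.mean, a.var, b.n_values, b.mean, b.var)

    nc = len(classes)
    active = [True] * nc
    pmat = np.full((nc, nc), -np.inf)
    for i in range(nc):
        for j in range(i + 1, nc):
            pmat[i, j] = pair_p(classes[i], classes[j])
    while sum(active) >= 2:
        flat = int(np.argmax(pmat))
        i, j = divmod(flat, nc)
        if pmat[i, j] <= alpha:
            break
        classes[i] = _pool(classes[i], classes[j])
        active[j] = False
        pmat[j, :] = -np.inf
        pmat[:, j] = -np.inf
        for o in range(nc):
            if o == i or not active[o]:
                continue
            lo, hi = min(i, o), max(i, o)
            pmat[lo, hi] = pair_p(classes[i], classes[o])
    classes = [c for c, a in zip(classes, active) if a]

    for i in singletons:
        v = arrs[i]
        dists = [abs(c.mean - float(v.mean())) for c in classes]
        nearest = int(np.argmin(dists))
        classes[nearest] = _pool(classes[nearest], _summary(i, v))

    classes.sort(key=lambda c: c.segment_ids[0])
    u = np.asarray([c.mean for c in classes])
    p = np.asarray([len(c.segment_ids) / n_total for c in classes])
    return CategoryTable(classes, u, p)


# ---------------------------------------------------------------------------
# normal depth, distances, Otsu
# ---------------------------------------------------------------------------

def estimate_normal_rd(table: CategoryTable, global_mean: float | None = None) -> float:
    """Copy-neutral RD: the representative mean of the category with the most bins.

    The diploid state dominates genomic mass, so the mass-weighted modal
    category is a robust stand-in for the neutral depth. Ties go to the
    category whose mean is closest to the global mean RD.
    """
    if table.m == 0:
        raise ValueError("empty category table")
    masses = table.n_bins()
    if global_mean is None:
        global_mean = float(np.average(table.u, weights=np.maximum(masses, 1)))
    top = np.flatnonzero(masses == masses.max())
    if top.size > 1:
        top = top[np.argsort(np.abs(table.u[top] - global_mean), kind="stable")[:1]]
    return float(table.u[int(top[0])])


def distance_array(table: CategoryTable) -> DistanceArray:
    """Absolute category distances from ``u_normal``, sorted ascending.

    Probabilities are co-permuted so index ``j`` of ``p`` still refers to the
    category at sorted position ``j``.
    """
    if table.u_normal is None:
        raise ValueError("table.u_normal is not set; call estimate_normal_rd first")
    x = np.abs(table.u - table.u_normal)
    perm = np.argsort(x, kind="stable")
    return DistanceArray(x[perm], table.p[perm], perm)


def suppress_extremes(d: DistanceArray) -> DistanceArray:
    """Clamp distances above the mean distance to the mean.

    Mitigates the skew of very-high-amplitude gains: only the values nearest
    the extreme are affected, and an ascending array stays ascending.
    """
    if d.x.size == 0:
        return DistanceArray(d.x.copy(), d.p.copy(), d.perm.copy())
    mean = d.x.mean()
    return DistanceArray(np.minimum(d.x, mean), d.p.copy(), d.perm.copy())


def otsu_threshold(d: DistanceArray) -> OtsuResult:
    """Split the sorted distance array by maximal between-class variance.

    Evaluates ``sigma^2(k)`` for every split ``k = 1..m-1`` via the closed
    form ``(mu_T*w - mu)^2 / (w*(1-w))``, skipping splits where a class has
    zero probability, and keeps the smallest maximizing ``k``. If no valid
    split has positive between-class variance everything is declared normal.
    """
    m = d.x.size
    eps = 1e-12
    if m < 2:
        return OtsuResult(None, 0.0, d.perm.copy(), np.empty(0, dtype=int))
    w = np.cumsum(d.p)
    mu = np.cumsum(d.x * d.p)
    mu_t = mu[-1]
    sigma2_all = np.full(m - 1, np.nan)
    best_k, best_s = None, 0.0
    for k in range(1, m):
        wk = w[k - 1]
        if wk <= eps or wk >= 1.0 - eps:
            continue
        s = (mu_t * wk - mu[k - 1]) ** 2 / (wk * (1.0 - wk))
        sigma2_all[k - 1] = s
        if best_k is None or s > best_s:
            best_k, best_s = k, s
    if best_k is None or best_s <= 0.0:
        return OtsuResult(None, 0.0, d.perm.copy(), np.empty(0, dtype=int), sigma2_all)
    return OtsuResult(best_k, float(best_s), d.perm[:best_k].copy(),
                      d.perm[best_k:].copy(), sigma2_all)


# ---------------------------------------------------------------------------
# calls
# ---------------------------------------------------------------------------

def call_cnvs(
    profile: RDProfile,
    segmentation: Segmentation,
    table: CategoryTable,
    otsu: OtsuResult,
) -> list:
    """Turn every segment of an abnormal category into a CNV call.

    Type is gain when the category mean exceeds ``u_normal``, loss otherwise.
    Adjacent same-type calls separated only by masked bins are merged.
    Coordinates are emitted 1-based inclusive.
    """
    if otsu.k_star is None or otsu.class1.size == 0:
        return []
    if table.u_normal is None:
        raise ValueError("table.u_normal is not set")
    retained = profile.retained_bins()
    bs = profile.bin_size
    raw = []  # (a, b, type, rd_mean) in compacted bin indices
    for cat_idx in sorted(int(c) for c in otsu.class1):
        typ = "gain" if table.u[cat_idx] > table.u_normal else "loss"
        for seg_id in table.categories[cat_idx].segment_ids:
            a, b = segmentation.segments[seg_id]
            if b <= a:
                continue
            raw.append((a, b, typ, float(profile.values[a:b].mean())))
    raw.sort()
    merged = []
    for a, b, typ, rd in raw:
        if merged and merged[-1][2] == typ and merged[-1][1] == a:
            pa, pb, ptyp, prd = merged[-1]
            n_prev, n_new = pb - pa, b - a
            merged[-1] = (pa, b, typ, (prd * n_prev + rd * n_new) / (n_prev + n_new))
        else:
            merged.append((a, b, typ, rd))
    calls = []
    for a, b, typ, rd in merged:
        start = int(retained[a]) * bs + 1
        end = (int(retained[b - 1]) + 1) * bs
        calls.append(CNVCall(profile.chrom, start, end, typ, rd))
    return calls
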