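"""Binarization of continuous expression profiles with significance filtering.

Single-cell log-normalized counts are converted gene-by-gene to binary
activity calls.  The default strategy (``basc_a``) follows the
step-function family of binarization algorithms: the sorted expression
values are approximated by optimal step functions with increasing numbers of
discontinuities (quadratic-error dynamic program), the strongest
discontinuity of each step function is located, and the binarization
threshold is placed at the median of those locations.  Significance of the
step structure is assessed by a bootstrap test: the observed
discontinuity statistic (computed on values min-max normalized to [0, 1])
is compared against the same statistic on uniform null samples of the same
size.  Genes whose Benjamini-Hochberg adjusted q-value fails the ``alpha``
cutoff are dropped from downstream reconstruction.

A cheap validated fallback (``kmeans2``: optimal two-cluster split of the
sorted values, threshold at the midpoint of the cluster means) is provided
behind the same interface.

Calls are ``value > threshold``; equality resolves to 0.  Thresholding is
scale-equivariant: binarizing ``a*x + b`` (a > 0) yields identical calls and
identical p-values for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "binarize_gene",
    "binarize_matrix",
    "BinaryMatrix",
    "GeneBinarizer",
]

# Null distributions of the discontinuity statistic depend only on
# (method, n, n_boot, seed); cache them so a whole matrix pays the
# bootstrap cost once per cell count.
_NULL_CACHE: dict[tuple, np.ndarray] = {}

#: Step functions with up to this many discontinuities enter the fit.  The
#: dynamic program is O(D * n**2); beyond a few dozen discontinuities the
#: strongest jumps of further step functions stabilize, so capping keeps
#: large cell counts tractable without moving the threshold noticeably.
MAX_DISCONTINUITIES = 50


def _segment_costs(v: np.ndarray) -> np.ndarray:
    """C[a, b] = quadratic error of approximating sorted v[a..b] by its mean."""
    n = v.shape[0]
    s1 = np.concatenate(([0.0], np.cumsum(v)))
    s2 = np.concatenate(([0.0], np.cumsum(v * v)))
    a = np.arange(n)[:, None]
    b = np.arange(n)[None, :]
    length = b - a + 1
    seg_sum = s1[b + 1] - s1[a]
    seg_sq = s2[b + 1] - s2[a]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = seg_sq - seg_sum * seg_sum / length
    cost[length <= 0] = np.inf
    return np.maximum(cost, 0.0)


def _optimal_step_functions(v: np.ndarray, max_d: int = MAX_DISCONTINUITIES):
    """Optimal step fits of sorted ``v`` for 1..min(n-2, max_d) discontinuities.

    Yields, per discontinuity count d, the breakpoint indices (a break at
    index b separates v[b] from v[b+1]) obtained by dynamic programming on
    the segment quadratic-error costs.
    """
    n = v.shape[0]
    dmax = min(n - 2, max_d)
    cost = _segment_costs(v)
    # shifted cost: cshift[i, j] = cost of a segment starting at i+1 ending at j
    cshift = np.full((n, n), np.inf)
    cshift[:-1, :] = cost[1:, :]
    E = cost[0, :].copy()  # E[j]: best error covering v[0..j], current d segments
    argmins = []  # argmins[d-1][j]: end of previous segment for d breaks
    for _d in range(1, dmax + 1):
        M = E[:, None] + cshift
        B = np.argmin(M, axis=0)
        E = M[B, np.arange(n)]
        argmins.append(B)
    breaks_per_d = []
    for d in range(1, dmax + 1):
        breaks = []
        j = n - 1
        for dd in range(d, 0, -1):
            j = int(argmins[dd - 1][j])
            breaks.append(j)
        breaks_per_d.append(sorted(breaks))
    return breaks_per_d


def _strongest_discontinuities(v: np.ndarray, breaks_per_d) -> tuple[np.ndarray, np.ndarray]:
    """Per step function: location and height of its strongest discontinuity.

    A discontinuity is strong when a high jump between adjacent segment
    means coincides with a low two-segment (binarization) error at that
    position; scoring by jump height alone would let single-point outlier
    gaps in the tails win for step functions with many discontinuities.
    """
    n = v.shape[0]
    s1 = np.concatenate(([0.0], np.cumsum(v)))
    s2 = np.concatenate(([0.0], np.cumsum(v * v)))

    def seg_mean(a: int, b: int) -> float:
        return (s1[b + 1] - s1[a]) / (b - a + 1)

    # two-segment quadratic error of splitting the whole vector after index b
    idx = np.arange(1, n)
    low = s2[idx] - s1[idx] ** 2 / idx
    high = (s2[n] - s2[idx]) - (s1[n] - s1[idx]) ** 2 / (n - idx)
    split_error = np.full(n, np.inf)
    split_error[: n - 1] = low + high

    locations = []
    heights = []
    for breaks in breaks_per_d:
        bounds = [-1, *breaks, n - 1]
        best_score, best_h, best_b = -np.inf, 0.0, breaks[0]
        for t in range(len(breaks)):
            b = bounds[t + 1]
            h = seg_mean(b + 1, bounds[t + 2]) - seg_mean(bounds[t] + 1, b)
            e = split_error[b]
            score = h / e if e > 0 else np.inf
            if score > best_score:
                best_score, best_h, best_b = score, h, b
        locations.append(best_b)
        heights.append(best_h)
    return np.array(locations), np.array(heights)


def _basc_fit(v_sorted: np.ndarray) -> tuple[int, float]:
    """(median strongest-discontinuity index, mean normalized jump height)."""
    breaks_per_d = _optimal_step_functions(v_sorted)
    locs, heights = _strongest_discontinuities(v_sorted, breaks_per_d)
    locs_sorted = np.sort(locs)
    median_loc = int(locs_sorted[(len(locs_sorted) - 1) // 2])
    vrange = v_sorted[-1] - v_sorted[0]
    stat = float(np.mean(heights) / vrange)
    return median_loc, stat


def _kmeans2_fit(v_sorted: np.ndarray) -> tuple[int, float]:
    """Optimal 1-D two-cluster split; statistic = normalized mean separation."""
    n = v_sorted.shape[0]
    s1 = np.concatenate(([0.0], np.cumsum(v_sorted)))
    s2 = np.concatenate(([0.0], np.cumsum(v_sorted * v_sorted)))
    idx = np.arange(1, n)  # split before position idx
    low_sum, low_n = s1[idx], idx
    high_sum, high_n = s1[n] - s1[idx], n - idx
    sse = (
        s2[idx]
        - low_sum**2 / low_n
        + (s2[n] - s2[idx])
        - high_sum**2 / high_n
    )
    split = int(idx[np.argmin(sse)])
    mlow = low_sum[split - 1] / split
    mhigh = (s1[n] - s1[split]) / (n - split)
    vrange = v_sorted[-1] - v_sorted[0]
    stat = float((mhigh - mlow) / vrange)
    return split - 1, stat


_FITTERS = {"basc_a": _basc_fit, "kmeans2": _kmeans2_fit}


def _null_statistics(method: str, n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (method, n, n_boot, seed)
    cached = _NULL_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    fit = _FITTERS[method]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        sample = np.sort(rng.random(n))
        stats[b] = fit(sample)[1]
    _NULL_CACHE[key] = stats
    return stats


def binarize_gene(
    values,
    method: str = "basc_a",
    n_boot: int = 999,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Binarize one gene's expression vector.

    Returns ``(calls, threshold, p)`` where ``calls = values > threshold``
    and ``p`` is the bootstrap p-value for the null of no step structure.
    A constant vector is non-binarizable: all-zero calls and ``p = 1``.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.shape[0] < 3:
        raise ValueError("binarization needs a 1-D vector of length >= 3")
    if not np.isfinite(v).all():
        raise ValueError("expression values must be finite")
    if method not in _FITTERS:
        raise ValueError(f"unknown binarization method {method!r}")
    vs = np.sort(v)
    if vs[-1] == vs[0]:
        return np.zeros(v.shape[0], dtype=np.uint8), float(vs[0]), 1.0
    loc, stat = _FITTERS[method](vs)
    threshold = float((vs[loc] + vs[loc + 1]) / 2.0)
    null = _null_statistics(method, v.shape[0], n_boot, seed)
    p = float((1 + np.sum(null >= stat)) / (n_boot + 1))
    calls = (v > threshold).astype(np.uint8)
    return calls, threshold, p


@dataclass
class BinaryMatrix:
    """Binary calls for the genes that binarized significantly.

    ``binary`` is a retained-genes x cells 0/1 DataFrame; ``stats`` covers
    every input gene (threshold, p, q, retained flag).
    """

    binary: pd.DataFrame
    stats: pd.DataFrame

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.binary.index)

    @property
    def cells(self) -> tuple[str, ...]:
        return tuple(self.binary.columns)

    def values(self) -> np.ndarray:
        return self.binary.to_numpy(dtype=np.uint8)


def binarize_matrix(
    expr: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "basc_a",
    n_boot: int = 999,
    seed: int = 0,
) -> BinaryMatrix:
    """Binarize a genes x cells matrix and drop non-significant genes.

    Per-gene bootstrap p-values are adjusted across genes with the
    Benjamini-Hochberg procedure; genes with ``q >= alpha`` are dropped.
    Raises if no gene survives.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    calls = np.zeros(expr.shape, dtype=np.uint8)
    thresholds = np.zeros(expr.shape[0])
    pvals = np.ones(expr.shape[0])
    for i, (_, row) in enumerate(expr.iterrows()):
        calls[i], thresholds[i], pvals[i] = binarize_gene(
            row.to_numpy(dtype=float), method=method, n_boot=n_boot, seed=seed
        )
    qvals = _sstats.false_discovery_control(pvals, method="bh")
    retained = qvals < alpha
    stats = pd.DataFrame(
        {
            "threshold": thresholds,
            "p": pvals,
            "q": qvals,
            "retained": retained,
        },
        index=expr.index,
    )
    if not retained.any():
        raise ValueError("no gene binarized significantly; nothing to reconstruct")
    binary = pd.DataFrame(
        calls[retained], index=expr.index[retained], columns=expr.columns
    )
    return BinaryMatrix(binary=binary, stats=stats)


class GeneBinarizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer view of the binarization stage.

    Follows the sklearn convention of samples x features, i.e. cells in rows
    and genes in columns.  ``fit`` estimates per-gene thresholds and
    bootstrap p/q-values; ``transform`` returns 0/1 calls for the retained
    genes.

    Parameters
    ----------
    method : {"basc_a", "kmeans2"}
        Step-fit strategy; ``basc_a`` is the default.
    alpha : float
        FDR level for the retained-gene filter.
    n_boot : int
        Bootstrap resamples for the significance test.
    random_state : int
        Seed of the bootstrap null.
    """

    def __init__(
        self,
        method: str = "basc_a",
        alpha: float = 0.05,
        n_boot: int = 999,
        random_state: int = 0,
    ):
        self.method = method
        self.alpha = alpha
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D cells x genes array")
        frame = pd.DataFrame(X.T)  # genes x cells, the library convention
        result = binarize_matrix(
            frame,
            alpha=self.alpha,
            method=self.method,
            n_boot=self.n_boot,
            seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1]
        self.thresholds_ = result.stats["threshold"].to_numpy()
        self.pvalues_ = result.stats["p"].to_numpy()
        self.qvalues_ = result.stats["q"].to_numpy()
        self.retained_ = result.stats["retained"].to_numpy()
        return self

    def transform(self, X):
        check_is_fitted(self, "thresholds_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        calls = (X > self.thresholds_[None, :]).astype(np.uint8)
        return calls[:, self.retained_]
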