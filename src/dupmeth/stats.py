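"""Statistical tests used throughout the pipeline.

Wraps scipy for the classical tests (exact binomial tail, Mann-Whitney U,
Kruskal-Wallis, Spearman) and implements Dunn's pairwise post-hoc test and
the Holm step-down adjustment directly, with the conventions pinned down:

- The binomial sign test is one-tailed: P(X >= k | n, p0) with p0 = 1/2.
- Mann-Whitney uses midranks for ties; p comes from the normal
  approximation with tie-corrected variance and continuity correction by
  default; exact enumeration is available for small samples.
- Dunn's z uses the pooled midranks of all groups and the standard tie
  term; pairwise p-values are two-sided and Holm-adjusted.
- Spearman is the Pearson correlation of midranks with a t approximation
  on n-2 df.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from dupmeth.model import TestResult


def binomial_one_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k) for X ~ Bin(n, p0).

    This is the sign test used for parental/daughter comparisons: k is the
    number of trios favouring the alternative direction out of n non-tied
    trios, under a null of p0 = 1/2.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, {n}], got {k}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0,1), got {p0}")
    return float(sps.binomtest(k, n, p0, alternative="greater").pvalue)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    two_sided: bool = True,
    method: str = "normal",
) -> TestResult:
    """Mann-Whitney U test of x vs y.

    U is the statistic for the first sample (number of (x_i, y_j) pairs
    with x_i > y_j, ties counted half). ``method`` is "normal"
    (tie-corrected variance, continuity correction; the default, suitable
    for the sample sizes this pipeline sees) or "exact" (permutation
    enumeration, small samples without ties only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    alternative = "two-sided" if two_sided else "greater"
    scipy_method = {"normal": "asymptotic", "exact": "exact"}[method]
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=scipy_method)
    return TestResult(
        method=f"mann-whitney-{method}",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(len(x), len(y)),
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) along the
    ascending sort, which makes the adjusted sequence monotone and never
    below the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _pooled_midranks(groups: Mapping[str, np.ndarray]) -> tuple[dict[str, np.ndarray], float]:
    """Midranks of the pooled sample per group, plus the Dunn tie term.

    The tie term is sum(t^3 - t) / (12 * (N - 1)) over tie groups of size t.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    out = {}
    offset = 0
    for g in labels:
        k = len(groups[g])
        out[g] = ranks[offset : offset + k]
        offset += k
    return out, tie_term


def kruskal_dunn_holm(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H across k >= 2 groups, plus Dunn's pairwise post hoc.

    Pairwise z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with T the tie term; two-sided pairwise p-values are Holm-adjusted
    across the k(k-1)/2 pairs. When every pooled value is identical the
    omnibus and all pairwise p-values are 1 by convention.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in arrays.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")

    pooled = np.concatenate(list(arrays.values()))
    labels = list(arrays)
    ns = tuple(len(arrays[g]) for g in labels)
    degenerate = bool(np.all(pooled == pooled[0]))

    if degenerate:
        h_stat, kw_p = 0.0, 1.0
    else:
        res = sps.kruskal(*arrays.values())
        h_stat, kw_p = float(res.statistic), float(res.pvalue)

    rank_groups, tie_term = _pooled_midranks(arrays)
    n_total = len(pooled)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairwise: dict[tuple[str, str], tuple[float, float, float]] = {}
    pairs = list(combinations(labels, 2))
    raw = []
    zs = []
    for gi, gj in pairs:
        if degenerate or var_base <= 0:
            z = 0.0
        else:
            se = np.sqrt(var_base * (1.0 / len(arrays[gi]) + 1.0 / len(arrays[gj])))
            z = float((rank_groups[gi].mean() - rank_groups[gj].mean()) / se)
        zs.append(z)
        raw.append(float(2.0 * sps.norm.sf(abs(z))))
    adjusted = holm_adjust(raw)
    for (gi, gj), z, p_raw, p_adj in zip(pairs, zs, raw, adjusted):
        pairwise[(gi, gj)] = (z, p_raw, float(p_adj))

    return TestResult(
        method="kruskal-dunn-holm",
        statistic=h_stat,
        p_value=kw_p,
        n=ns,
        pairwise=pairwise,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with a t-approximation p-value.

    Returns rho = NaN and p = None when either vector is constant (the
    correlation is undefined); callers report that outcome rather than
    treating it as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(method="spearman", statistic=float("nan"), p_value=None, n=(len(x),))
    rho, p = sps.spearmanr(x, y)
    return TestResult(method="spearman", statistic=float(rho), p_value=float(p), n=(len(x),))
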