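"""Statistical machinery against independent oracles."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupmeth.stats import (
    binomial_one_tailed,
    holm_adjust,
    kruskal_dunn_holm,
    mann_whitney_u,
    spearman,
)


def exact_binomial_tail(k: int, n: int) -> Fraction:
    """Arbitrary-precision oracle: sum_{i>=k} C(n,i) / 2^n."""
    return Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n)


class TestBinomial:
    def test_full_tail_is_one(self):
        assert binomial_one_tailed(0, 7) == pytest.approx(1.0)

    def test_all_successes_closed_form(self):
        assert binomial_one_tailed(10, 10) == pytest.approx(0.5**10)

    @pytest.mark.parametrize("k,n", [(32, 50), (97, 148), (3, 5), (0, 1), (7, 9)])
    def test_matches_rational_arithmetic_oracle(self, k, n):
        assert binomial_one_tailed(k, n) == pytest.approx(
            float(exact_binomial_tail(k, n)), rel=1e-12
        )

    def test_symmetric_split_exceeds_half(self):
        assert binomial_one_tailed(6, 12) > 0.5

    def test_complementarity_exact(self):
        # P(X>=k) + P(X<=k-1) = 1, checked in rational arithmetic
        for n in (1, 5, 12):
            for k in range(1, n + 1):
                assert exact_binomial_tail(k, n) + (
                    1 - exact_binomial_tail(k, n)
                ) == Fraction(1)
                assert binomial_one_tailed(k, n) + sum(
                    comb(n, i) for i in range(0, k)
                ) / 2**n == pytest.approx(1.0, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_one_tailed(5, 4)
        with pytest.raises(ValueError):
            binomial_one_tailed(0, 0)


def exact_mann_whitney_p(x, y):
    """Enumerate all label assignments of the pooled sample (no ties)."""
    pooled = sorted(x + y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi)

    observed = u_stat(x, y)
    n_extreme = 0
    n_total = 0
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        n_total += 1
        # two-sided: as or more extreme in either direction
        if abs(u - nx * len(y) / 2) >= abs(observed - nx * len(y) / 2):
            n_extreme += 1
    return n_extreme / n_total


class TestMannWhitney:
    def test_extreme_separation_small_sample(self):
        # x={1,2}, y={3,4}: U=0; enumeration over C(4,2)=6 placements
        # gives two-sided p = 2/6 = 1/3
        res = mann_whitney_u([1, 2], [3, 4], method="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert exact_mann_whitney_p([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_p_one_under_enumeration(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3], method="normal")
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 4, 6], [2, 3, 5]),
            ([10, 20, 30, 40], [15, 25, 35]),
            ([1, 2, 7, 8], [3, 4, 5, 6]),
        ],
    )
    def test_exact_p_matches_enumeration_oracle(self, x, y):
        res = mann_whitney_u(x, y, method="exact")
        assert res.p_value == pytest.approx(exact_mann_whitney_p(x, y))

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(5)
        x = rng.beta(2, 6, size=500)
        y = rng.beta(6, 2, size=500)
        assert mann_whitney_u(x, y).p_value < 1e-6

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.02]) == pytest.approx([0.02])

    def test_hand_worked_step_down(self):
        # sorted: 0.01, 0.03, 0.04 -> 3*0.01=0.03, 2*0.03=0.06, max(.,1*0.04)=0.06
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones_stay_one(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, size=12)
        ours = holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert ours == pytest.approx(theirs)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10))
    def test_adjusted_never_below_raw_and_monotone(self, p_list):
        adjusted = holm_adjust(p_list)
        assert (adjusted >= np.asarray(p_list) - 1e-15).all()
        order = np.argsort(p_list, kind="mergesort")
        assert (np.diff(adjusted[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.0, 0.5])


def manual_dunn_z(groups):
    """From-scratch Dunn z oracle: pooled ranks, no-tie variance."""
    labels = list(groups)
    pooled = [v for g in labels for v in groups[g]]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    for rank, idx in enumerate(order, start=1):
        ranks[idx] = float(rank)
    n_total = len(pooled)
    mean_ranks, sizes, offset = {}, {}, 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = sum(ranks[offset : offset + k]) / k
        sizes[g] = k
        offset += k
    out = {}
    for gi, gj in combinations(labels, 2):
        se = (n_total * (n_total + 1) / 12 * (1 / sizes[gi] + 1 / sizes[gj])) ** 0.5
        out[(gi, gj)] = (mean_ranks[gi] - mean_ranks[gj]) / se
    return out


class TestKruskalDunn:
    def test_identical_constant_groups_all_p_one(self):
        res = kruskal_dunn_holm({"a": [5, 5, 5], "b": [5, 5], "c": [5, 5, 5, 5]})
        assert res.p_value == pytest.approx(1.0)
        for _, (_, p_raw, p_adj) in res.pairwise.items():
            assert p_raw == pytest.approx(1.0) and p_adj == pytest.approx(1.0)

    def test_hand_sized_z_matches_manual_rank_computation(self):
        groups = {
            "g1": [1.2, 3.4, 5.1, 7.7],
            "g2": [2.2, 4.9, 8.8, 9.1],
            "g3": [0.5, 6.6, 10.2, 11.5],
        }
        res = kruskal_dunn_holm(groups)
        manual = manual_dunn_z(groups)
        for pair, z_manual in manual.items():
            z_ours = res.pairwise[pair][0]
            assert z_ours == pytest.approx(z_manual, rel=1e-12)

    def test_two_group_rejection_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(17)
        agreements = 0
        for _ in range(40):
            shift = rng.uniform(0.0, 1.2)
            x = rng.normal(0, 1, size=25)
            y = rng.normal(shift, 1, size=25)
            dunn_p = kruskal_dunn_holm({"x": x, "y": y}).pairwise[("x", "y")][1]
            mw_p = mann_whitney_u(x, y).p_value
            if (dunn_p < 0.05) == (mw_p < 0.05):
                agreements += 1
        assert agreements >= 36  # borderline cases may disagree, rarely

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_dunn_holm({"a": [1.0], "b": []})

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            kruskal_dunn_holm({"a": [1.0, 2.0]})

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i * 0.3, 1, size=12) for i in range(4)}
        res = kruskal_dunn_holm(groups)
        for _, (_, p_raw, p_adj) in res.pairwise.items():
            assert p_adj >= p_raw - 1e-15


class TestSpearman:
    def test_perfect_monotone_is_one(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.statistic == pytest.approx(1.0)

    def test_matches_rank_formula_without_ties(self):
        rng = np.random.default_rng(8)
        x = rng.permutation(6).astype(float)
        y = rng.permutation(6).astype(float)
        res = spearman(x, y)
        # classical formula 1 - 6*sum(d^2)/(n(n^2-1)) for untied data
        rank = lambda v: np.argsort(np.argsort(v)) + 1  # noqa: E731
        d = rank(x) - rank(y)
        expected = 1 - 6 * float(d @ d) / (6 * 35)
        assert res.statistic == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.statistic) and res.p_value is None

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])
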