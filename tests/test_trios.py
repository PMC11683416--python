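"""Trio construction and sign tests."""

from __future__ import annotations

import pytest

from dupmeth.model import GeneModel, OrthologGroup, Transcript
from dupmeth.trios import (
    assign_parental_daughter,
    build_trios,
    compare_metric_across_goc,
    is_retrogene,
    select_trio_pair,
    sign_test_copy_vs_outgroup,
    sign_test_daughter_vs_parental,
)


def _group(members_a, members_b):
    return OrthologGroup(frozenset(members_a), frozenset(members_b))


def _gene_with_exons(gene_id, n_exons):
    exons = tuple((1000 * k + 1, 1000 * k + 200) for k in range(n_exons))
    return GeneModel(
        gene_id=gene_id, species="sp", chrom="c1", strand="+",
        gene_start=exons[0][0], gene_end=exons[-1][1],
        transcripts=(Transcript(f"{gene_id}.t", exons),),
    )


class TestPairSelection:
    def test_two_member_group_returns_that_pair(self):
        group = _group({"a1", "a2"}, {"b1"})
        pair = select_trio_pair(group, {"a1": 0.3, "a2": 0.8})
        assert pair == ("a1", "a2")

    def test_maximal_difference_pair_wins(self):
        # levels 0.1, 0.5, 0.6: exhaustive enumeration picks (0.1, 0.6)
        group = _group({"a1", "a2", "a3"}, {"b1"})
        pair = select_trio_pair(group, {"a1": 0.1, "a2": 0.5, "a3": 0.6})
        assert pair == ("a1", "a3")

    def test_all_members_missing_rejects(self):
        group = _group({"a1", "a2"}, {"b1"})
        assert select_trio_pair(group, {}) is None

    def test_one_member_with_data_rejects(self):
        group = _group({"a1", "a2", "a3"}, {"b1"})
        assert select_trio_pair(group, {"a2": 0.4}) is None

    def test_tie_breaks_to_smallest_id_pair(self):
        group = _group({"a1", "a2", "a3", "a4"}, {"b1"})
        # four pairs are tied at |delta| = 1.0; the lexicographically
        # smallest sorted pair wins
        pair = select_trio_pair(group, {"a1": 0.0, "a2": 1.0, "a3": 0.0, "a4": 1.0})
        assert pair == ("a1", "a2")


class TestParentalDaughter:
    def test_highest_goc_is_parental(self):
        trio = assign_parental_daughter(("x", "y"), {"x": 100, "y": 0}, "out", "sp", "colon")
        assert trio.parental_gene == "x" and trio.daughter_gene == "y"

    def test_equal_goc_rejected(self):
        assert assign_parental_daughter(("x", "y"), {"x": 50, "y": 50}, "out", "sp", "colon") is None

    def test_75_beats_25(self):
        trio = assign_parental_daughter(("x", "y"), {"x": 25, "y": 75}, "out", "sp", "colon")
        assert trio.parental_gene == "y"
        assert trio.parental_goc == 75 and trio.daughter_goc == 25

    def test_missing_goc_rejected(self):
        assert assign_parental_daughter(("x", "y"), {"x": 50}, "out", "sp", "colon") is None


class TestRetrogene:
    @pytest.mark.parametrize(
        "gene_exons,paralog_exons,expected",
        [(1, 3, True), (1, 2, False), (2, 5, False), (1, 8, True), (3, 3, False)],
    )
    def test_single_exon_with_multi_exon_paralog(self, gene_exons, paralog_exons, expected):
        gene = _gene_with_exons("g", gene_exons)
        paralog = _gene_with_exons("p", paralog_exons)
        assert is_retrogene(gene, paralog) is expected


class TestSignTests:
    def _trios(self, n):
        return [
            assign_parental_daughter(
                (f"p{i}", f"d{i}"), {f"p{i}": 100, f"d{i}": 0}, f"o{i}", "sp", "colon"
            )
            for i in range(n)
        ]

    def test_moderately_asymmetric_counts(self):
        # 32 daughter-higher vs 18 parental-higher -> p ~ 0.033
        trios = self._trios(50)
        values = {}
        for i, trio in enumerate(trios):
            values[trio.daughter_gene] = 0.9 if i < 32 else 0.1
            values[trio.parental_gene] = 0.5
        res = sign_test_daughter_vs_parental(trios, values, "promoter_meth")
        assert (res.n_daughter_higher, res.n_parental_higher) == (32, 18)
        assert res.p_one_tailed == pytest.approx(0.0325, abs=5e-4)

    def test_ties_excluded_from_n(self):
        trios = self._trios(10)
        values = {}
        for i, trio in enumerate(trios):
            values[trio.daughter_gene] = 0.5 if i < 4 else 0.9
            values[trio.parental_gene] = 0.5
        res = sign_test_daughter_vs_parental(trios, values, "promoter_meth")
        assert res.n_ties == 4 and res.n == 6

    def test_lower_direction_metrics_flip_the_tail(self):
        # every daughter lower: significant for cpg_oe ("daughter lower")
        trios = self._trios(10)
        values = {}
        for trio in trios:
            values[trio.daughter_gene] = 0.2
            values[trio.parental_gene] = 0.8
        res = sign_test_daughter_vs_parental(trios, values, "cpg_oe")
        assert res.n_parental_higher == 10
        assert res.p_one_tailed == pytest.approx(0.5**10)

    def test_outgroup_all_higher_closed_form(self):
        trios = self._trios(10)
        copy_values = {t.daughter_gene: 0.9 for t in trios}
        outgroup_values = {t.outgroup_gene: 0.3 for t in trios}
        res = sign_test_copy_vs_outgroup(trios, copy_values, outgroup_values, "daughter")
        assert res.p_one_tailed == pytest.approx(9.765625e-4)

    def test_no_data_reports_undefined(self):
        res = sign_test_daughter_vs_parental(self._trios(5), {}, "promoter_meth")
        assert res.p_one_tailed is None and res.n == 0

    def test_bad_copy_role_rejected(self):
        with pytest.raises(ValueError, match="copy_role"):
            sign_test_copy_vs_outgroup(self._trios(2), {}, {}, "cousin")


class TestAcrossGOC:
    def test_perfect_monotone_decrease(self):
        goc = {f"g{i}": s for i, s in enumerate([0, 25, 50, 75, 100])}
        metric = {f"g{i}": 1.0 - 0.2 * i for i in range(5)}
        out = compare_metric_across_goc(goc, metric)
        assert out["spearman"].statistic == pytest.approx(-1.0)

    def test_constant_metric_undefined(self):
        goc = {f"g{i}": s for i, s in enumerate([0, 25, 50, 75, 100])}
        metric = {f"g{i}": 0.5 for i in range(5)}
        out = compare_metric_across_goc(goc, metric)
        assert out["spearman"].p_value is None

    def test_single_stratum_reports_undefined(self):
        out = compare_metric_across_goc({"a": 100, "b": 100}, {"a": 0.1, "b": 0.9})
        assert out["kruskal_dunn"] is None
        assert out["spearman"].p_value is None


class TestOnSyntheticData:
    def test_every_trio_has_strictly_ordered_goc(self, analysis):
        trios = analysis.trios
        assert len(trios) > 0
        assert (trios.parental_goc > trios.daughter_goc).all()

    def test_retrogene_excluded_set_is_subset(self, analysis):
        st = analysis.sign_tests
        paired = st.pivot_table(
            index=["species", "tissue", "metric", "comparison"],
            columns="variant", values="n", aggfunc="first",
        ).dropna()
        assert (paired["no_retrogenes"] <= paired["all"]).all()

    def test_daughters_labelled_mostly_correctly(self, analysis, dataset):
        # GOC orientation recovers the true daughter in most trios under
        # relocation-dominant placement
        truth = dataset.truth.set_index("gene_id")
        trios = analysis.trios[analysis.trios.tissue == "colon"]
        correct = sum(
            truth.loc[t.daughter_gene, "role"] == "daughter" for t in trios.itertuples()
        )
        assert correct / len(trios) > 0.8

    def test_negative_methylation_and_positive_expression_goc_correlation(self, analysis):
        gc = analysis.goc_correlations
        meth = gc[(gc.metric == "promoter_meth") & (gc.tissue == "colon")]
        expr = gc[(gc.metric == "expression") & (gc.tissue == "colon")]
        assert (meth.spearman_rho < 0).all()
        assert (expr.spearman_rho > 0).all()
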