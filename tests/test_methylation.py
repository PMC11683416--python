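"""Site filters, region definitions, and the region-mean estimator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from dupmeth.methylation import (
    body_region,
    filter_cpg_sites,
    promoter_region,
    quantify_methylation,
    region_methylation,
    remove_overlapping_genes,
    select_longest_transcript,
)
from dupmeth.model import GeneModel, MaskRegions, Transcript


def _gene(gene_id, chrom, strand, exons, biotype="protein_coding", extra_transcripts=()):
    transcripts = (Transcript(f"{gene_id}.t1", tuple(exons)), *extra_transcripts)
    starts = [t.span[0] for t in transcripts]
    ends = [t.span[1] for t in transcripts]
    return GeneModel(
        gene_id=gene_id, species="sp", chrom=chrom, strand=strand,
        gene_start=min(starts), gene_end=max(ends), biotype=biotype,
        transcripts=transcripts,
    )


def _sites(rows, tissues=("colon",)):
    data = {"chrom": [r[0] for r in rows], "pos": [r[1] for r in rows]}
    for i, t in enumerate(tissues):
        data[f"meth:{t}"] = [r[2 + 2 * i] for r in rows]
        data[f"total:{t}"] = [r[3 + 2 * i] for r in rows]
    return pd.DataFrame(data)


class TestFilter:
    TISSUES = ("t1", "t2", "t3")

    def _three_tissue_site(self, totals):
        row = ["chr1", 100]
        for total in totals:
            row.extend([0, total])
        return _sites([tuple(row)], self.TISSUES)

    def test_boundary_coverage_is_inclusive(self):
        kept = filter_cpg_sites(self._three_tissue_site((5, 5, 5)), self.TISSUES, 5)
        assert len(kept) == 1

    def test_one_low_tissue_removes_site(self):
        kept = filter_cpg_sites(self._three_tissue_site((5, 4, 9)), self.TISSUES, 5)
        assert len(kept) == 0

    def test_masked_position_removed_despite_coverage(self):
        mask = MaskRegions({"chr1": [(100, 100)]})
        kept = filter_cpg_sites(
            self._three_tissue_site((50, 50, 50)), self.TISSUES, 5, mask=mask
        )
        assert len(kept) == 0

    def test_per_tissue_variant_filters_independently(self):
        out = filter_cpg_sites(
            self._three_tissue_site((5, 4, 9)), self.TISSUES, 5, require_all_tissues=False
        )
        assert len(out["t1"]) == 1 and len(out["t2"]) == 0 and len(out["t3"]) == 1

    def test_empty_tissue_set_is_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            filter_cpg_sites(self._three_tissue_site((5, 5, 5)), (), 5)


class TestLongestTranscript:
    def test_single_transcript(self):
        gene = _gene("g", "chr1", "+", [(100, 399)])
        assert select_longest_transcript(gene).transcript_id == "g.t1"

    def test_summed_exon_length_wins(self):
        # 300 bp single exon vs 100 + 250 = 350 bp in two exons
        extra = Transcript("g.t2", ((100, 199), (500, 749)))
        gene = _gene("g", "chr1", "+", [(100, 399)], extra_transcripts=(extra,))
        assert select_longest_transcript(gene).transcript_id == "g.t2"

    def test_tie_breaks_to_lexicographically_smallest_id(self):
        t2 = Transcript("t2", ((100, 399),))
        t10 = Transcript("t10", ((100, 399),))
        gene = GeneModel("g", "sp", "chr1", "+", 100, 399, transcripts=(t2, t10))
        assert select_longest_transcript(gene).transcript_id == "t10"


class TestOverlapRemoval:
    def test_disjoint_genes_kept(self):
        genes = [_gene("a", "chr1", "+", [(100, 200)]), _gene("b", "chr1", "+", [(300, 400)])]
        assert len(remove_overlapping_genes(genes)) == 2

    def test_nested_pair_both_removed(self):
        genes = [_gene("a", "chr1", "+", [(100, 500)]), _gene("b", "chr1", "-", [(200, 300)])]
        assert remove_overlapping_genes(genes) == []

    def test_overlap_chain_removes_all_three(self):
        # A overlaps B, B overlaps C, A and C disjoint -> all removed
        genes = [
            _gene("a", "chr1", "+", [(100, 250)]),
            _gene("b", "chr1", "+", [(200, 400)]),
            _gene("c", "chr1", "+", [(350, 600)]),
        ]
        assert remove_overlapping_genes(genes) == []

    def test_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            genes = []
            for i in range(12):
                start = int(rng.integers(1, 2000))
                genes.append(_gene(f"g{i}", "chr1", "+", [(start, start + int(rng.integers(50, 500)))]))
            kept = {g.gene_id for g in remove_overlapping_genes(genes)}
            bad = set()
            for g in genes:
                for h in genes:
                    if g.gene_id != h.gene_id and g.gene_start <= h.gene_end and h.gene_start <= g.gene_end:
                        bad.add(g.gene_id)
            assert kept == {g.gene_id for g in genes} - bad

    def test_same_span_on_different_chromosomes_kept(self):
        genes = [_gene("a", "chr1", "+", [(100, 200)]), _gene("b", "chr2", "+", [(100, 200)])]
        assert len(remove_overlapping_genes(genes)) == 2


class TestRegions:
    def test_plus_strand_promoter(self):
        gene = _gene("g", "chr1", "+", [(2000, 5000)])
        assert promoter_region(gene) == (500, 1999)

    def test_minus_strand_promoter(self):
        gene = _gene("g", "chr1", "-", [(1000, 2000)])
        assert promoter_region(gene) == (2001, 3500)

    def test_promoter_clipped_at_chromosome_start(self):
        gene = _gene("g", "chr1", "+", [(1000, 2000)])
        assert promoter_region(gene) == (1, 999)

    def test_plus_strand_body_is_transcript_span(self):
        gene = _gene("g", "chr1", "+", [(2000, 3000), (4000, 5000)])
        assert body_region(gene) == (2000, 5000)

    def test_minus_strand_body_is_transcript_span(self):
        gene = _gene("g", "chr1", "-", [(2000, 3000), (4000, 5000)])
        assert body_region(gene) == (2000, 5000)

    def test_single_base_transcript_body(self):
        gene = _gene("g", "chr1", "+", [(2000, 2000)])
        assert body_region(gene) == (2000, 2000)

    def test_promoter_and_body_always_disjoint(self, dataset):
        for gene in dataset.genes_a[:100]:
            p = promoter_region(gene)
            b = body_region(gene)
            assert p[1] < b[0] or b[1] < p[0]


class TestRegionMean:
    def test_unweighted_mean_of_site_fractions(self):
        sites = _sites(
            [("chr1", 10, 1, 5), ("chr1", 20, 2, 5), ("chr1", 30, 3, 5)]
        )
        level, n = region_methylation(sites, "chr1", (1, 100), "colon")
        assert n == 3
        assert level == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_mean_is_per_site_not_pooled(self):
        # deep unmethylated site + shallow methylated site: per-site mean
        # is 0.5, pooled read fraction would be 10/110
        sites = _sites([("chr1", 10, 0, 100), ("chr1", 20, 10, 10)])
        level, _ = region_methylation(sites, "chr1", (1, 100), "colon")
        assert level == pytest.approx(0.5)
        assert level != pytest.approx(10 / 110)

    def test_empty_region_is_missing(self):
        sites = _sites([("chr1", 10, 1, 5)])
        level, n = region_methylation(sites, "chr1", (500, 600), "colon")
        assert level is None and n == 0

    def test_estimator_recovers_known_level(self):
        # 20 CpGs at true level 0.7, coverage 30: the estimate must fall
        # within a few binomial standard errors of the truth
        rng = np.random.default_rng(3)
        totals = rng.poisson(30, size=20) + 1
        meths = rng.binomial(totals, 0.7)
        sites = _sites([("chr1", 10 + 2 * i, int(m), int(t)) for i, (m, t) in enumerate(zip(meths, totals))])
        level, n = region_methylation(sites, "chr1", (1, 100), "colon")
        se = np.sqrt(0.7 * 0.3 / (20 * 30))
        assert n == 20
        assert abs(level - 0.7) < 4 * se

    def test_parameter_recovery_on_synthetic_dataset(self, dataset, analysis):
        # estimated promoter levels must track the simulation truth
        truth = dataset.truth[dataset.truth.species == "speciesA"].set_index("gene_id")
        ma = analysis.methylation_a
        sub = ma[(ma.tissue == "colon") & ma.promoter_level.notna() & (ma.n_promoter_cpgs >= 10)]
        rho = spearmanr(
            sub.promoter_level.to_numpy(),
            truth.loc[sub.gene_id, "true_prom:colon"].to_numpy(),
        ).statistic
        assert rho >= 0.9

    def test_levels_always_in_unit_interval(self, analysis):
        for frame in (analysis.methylation_a, analysis.methylation_b):
            levels = frame[["promoter_level", "body_level"]].to_numpy()
            finite = levels[~np.isnan(levels)]
            assert ((finite >= 0) & (finite <= 1)).all()


def test_quantify_matches_single_region_calls(dataset):
    """quantify_methylation agrees with per-gene region_methylation calls."""
    genes = dataset.genes_a[:20]
    sites = dataset.cpg_a
    table = quantify_methylation(genes, sites, ("colon",))
    for gene in genes:
        row = table[(table.gene_id == gene.gene_id) & (table.tissue == "colon")].iloc[0]
        level, n = region_methylation(sites, gene.chrom, promoter_region(gene), "colon")
        if level is None:
            assert np.isnan(row.promoter_level) and row.n_promoter_cpgs == 0
        else:
            assert row.promoter_level == pytest.approx(level)
            assert row.n_promoter_cpgs == n
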