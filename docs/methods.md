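# Methods

## Analysis model

The pipeline compares promoter (and gene-body) methylation of duplicated
genes between two species whose lineages split long enough ago that
recent duplications are lineage-specific.

**Gene universe and classification.** A gene is a *duplicate* iff it has
at least one within-species paralog edge in the homology table, a
*singleton* otherwise. Ortholog classes are read off the connected
components of the bipartite cross-species ortholog graph: a component
with (|A|, |B|) members is one-to-one (1,1), one-to-many (1, ≥2),
many-to-one (≥2, 1) or many-to-many (≥2, ≥2). Components rather than
per-pair annotation strings make the classifier independent of any
particular database's labels; when a table carries such labels they can
be cross-checked externally. Genes without ortholog edges are excluded
from ortholog-class analyses but retained for singleton/duplicate
analyses. Ohnologs (whole-genome-duplication relicts, supplied as a plain
id list) define an extra "duplicates excluding ohnologs" stratum.

**Methylation quantification.** Inputs are per-CpG cytosine reports
(chrom, pos, strand, methylated/unmethylated counts) per tissue. Reverse-
strand records are pooled onto the forward-strand C of the CpG, conserving
read mass. A site is retained iff covered by ≥ `min_coverage` reads in
*every* tissue of the species' tissue set (defaults 5 and 3 for the two
species; a per-tissue-independent variant sits behind a flag) and not at
a masked position (C/T polymorphisms; the mask BED is the boundary — MAF
filtering happens upstream of this package). Per gene, the longest
transcript (summed exon length, ties to the smallest transcript id) fixes
the TSS as its 5′-most base. The promoter is the 1,500 bp upstream of the
TSS excluding the TSS, clipped at position 1; the gene body is the
transcript span from the TSS to the 3′ end — the two regions are disjoint
by construction. A region's level is the **unweighted mean of per-site
fractional methylation** (not a pooled read ratio; the two differ under
variable depth), missing when the region holds no retained site.
Overlapping genes (span intersection on the same chromosome, either
strand) are removed pairwise before quantification.

**GOC score.** Per chromosome, genes are ordered by (start, end, id),
protein-coding only by default. The GOC score of a focal gene against its
ortholog is 25 × (number of the focal gene's up-to-4 closest neighbours
having an ortholog among the ortholog gene's up-to-4 closest neighbours).
The denominator is fixed at 4, so chromosome-end genes can never exceed
50; this keeps the five-value codomain {0, 25, 50, 75, 100}. Matching is
permissive (any ortholog of the neighbour in the window counts) and
directional (the reverse direction is computable but unused). When the
homology table ships GOC values (as Ensembl exports do) a config switch
uses them verbatim instead of recomputing, since an external database's
own scores are needed to reproduce its gene assignments exactly.

**Trios and sign tests.** From every many-to-one group: if more than two
copies exist in the duplicated species, the two with the largest promoter
methylation difference in the tissue under study are kept (ties to the
lexicographically smallest pair); the higher-GOC copy is the parental,
the lower the daughter; equal-GOC pairs are rejected. Trio sets are
therefore tissue-specific, which is why trio counts vary across tissues.
Retrogenes (single-exon copy whose paralog has ≥3 exons, on longest
transcripts) trigger trio-level exclusion in the "no_retrogenes" variant
when *either* copy is one. Each comparison (daughter vs parental;
daughter or parental vs the outgroup ortholog, in tissues shared between
the species) is an exact one-tailed binomial sign test at p₀ = ½ with
exact ties excluded from n. The alternative direction is fixed a priori:
daughter **higher** for promoter/body methylation, daughter **lower** for
CpG_o/e and expression.

**CpG_o/e.** For a promoter sequence with L′ non-N bases,
`(n_CpG/(L′−1)) / ((n_C/L′)(n_G/L′))`; the literature's other convention
`L′·n_CpG/(n_C·n_G)` sits behind a switch. Undefined (reported, not 0)
when n_C = 0, n_G = 0 or L′ < 2; case-insensitive; non-ACGTN symbols are
rejected. Unmasked sequence is assumed.

**Statistics.** Binomial tails are exact (`scipy.stats.binomtest`);
Mann-Whitney uses midranks, tie-corrected variance and continuity
correction (exact enumeration is reserved for small-sample oracle tests —
at the sample sizes this pipeline sees the approximation is standard and
determinism matters more than exactness); Kruskal-Wallis is
tie-corrected; Dunn's pairwise z uses pooled midranks and the standard
tie term with two-sided p-values, Holm-adjusted across all pairs
(one-sidedness lives only in the binomial sign tests); Spearman is the
rank Pearson correlation with a t approximation on n−2 df, reported as
undefined for constant vectors. When all pooled values are identical the
omnibus and pairwise p-values are 1 by convention.

## Synthetic data generator

`simulate_two_species` emulates the statistical structure the analysis
assumes, with ground truth recorded per gene copy:

- `n_ancestral_genes` (500) genes laid out in shared order across
  `n_chromosomes` (4), exon/intron structure drawn per gene (3–8 exons),
  intergenic spacing wide enough that promoter regions never overlap a
  neighbouring gene, so every CpG belongs to exactly one gene.
- Ancestral promoter methylation m₀ ~ Beta(`meth_prior` = (2,2)); per
  tissue, truth = clip(m₀ + N(0, `tissue_noise_sd` = 0.05)), shared
  across species so orthologs inherit the ancestral state.
- Duplication per species with probability
  `dup_rate`·(1 + `dup_meth_bias`·m₀) clamped to [0,1]
  (defaults 0.2 and 1 — the duplication-prefers-methylated-genes bias has
  no published magnitude; 1 makes the most methylated genes twice as
  likely to duplicate, a visible but not overwhelming bias).
- The parental copy keeps position and truth; the daughter gains
  `daughter_delta` (0.2, clamped) and stays in tandem with probability
  `tandem_prob` (0.25) or relocates to a uniform random slot. Adjacent
  gene pairs swap with probability `shuffle_rate` (0.02), adding GOC
  noise. Relocated daughters are emitted single-exon (retrogenes) with
  probability `retro_prob` (0.15).
- Gene-body truth is a 50/50 mix of the promoter truth and independent
  Beta(2,2) noise, giving the weak positive promoter–body correlation
  real data show.
- WGBS reads per site and tissue: total ~ Poisson(`coverage_mean` = 20),
  methylated ~ Binomial(total, truth). Promoter CpG count is
  `promoter_len`·`cpg_base_density`·(1 − `cpg_deamination_coef`·historical
  methylation) with defaults 1500·0.04·(1 − 0.5·m); emitted promoter
  sequences plant CG dinucleotides at exactly those site offsets on a
  random A/T-rich background, so sequence CpG_o/e falls with historical
  methylation. A fraction `mask_frac` (0.01) of CpG positions is masked.
- Expression per tissue: `expr_base`·max(0, 1 −
  `expr_meth_slope`·truth)·exp(N(0, `expr_noise_sd`)), defaults
  10·(1 − 0.8m)·lognoise(0.3).
- Ohnolog labels are drawn from duplicated ancestral genes
  (`ohnolog_frac` = 0.1 of them, both copies labelled): ohnologs are by
  definition duplicates, and only then does the "duplicates excluding
  ohnologs" stratum differ from the duplicate set.

Determinism: one `SeedSequence` keyed by `seed` is split into named
substreams (ancestry, duplication, per-species placement, structure,
truth, reads, sequences, expression, masks, ohnologs, in fixed spawn
order), and all iteration orders are fixed, so identical seeds give
byte-identical output files.

What the generator does **not** emulate: sequence evolution beyond CpG
density, realistic chromosome lengths and gene density, cross-mapping of
WGBS reads between near-identical young duplicates, tissue-specific
methylation programs (tissue noise is iid), dosage constraints, or
whole-genome duplication. Passing tests therefore demonstrate that the
pipeline recovers the planted structure under its own assumptions, not
that those assumptions hold in any real genome.

## Numerical choices and problem sizes

- Coordinates are 1-based inclusive throughout; BED converts at the
  boundary. CpG sites are keyed by the forward-strand C.
- All tie-breaks are lexicographic or sort-stable, making every output
  table byte-deterministic for a given input.
- Test problem sizes are chosen for single-CPU runs: the session fixture
  uses 300 ancestral genes; the power/size sweep uses 50 seeds per
  condition at 800 ancestral genes, one shared tissue and relocation-
  dominant duplication (`dup_rate` 0.45, `tandem_prob` 0.15), which
  yields ≥150 many-to-one groups per replicate; null-calibration uses
  200 replicates at 200 genes and 2000 resampling draws per statistical
  test.

## Known limitations

- The recomputed GOC score implements the published verbal definition;
  it is not guaranteed to clone any database's internal algorithm
  (treatment of strand, non-coding genes, assembly patches).
- Promoter CpGs overlapping a neighbouring gene's body are not excluded
  (real annotations are denser than the simulator's layout).
- Genome builds are opaque labels; no liftover is performed.
- MAF-based mask construction is upstream of this package.
- With few informative trios the sign test has little power; results
  report n alongside p so such cases are visible.
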