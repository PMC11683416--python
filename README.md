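# dupmeth

Comparative analysis of promoter DNA methylation of duplicated genes in
two species.

## The problem

After a gene duplicates, both copies are redundant and the doubled dosage
is often deleterious. One survival route is epigenetic: the copy that
relocates to a new genomic context (the **daughter**) is silenced by
promoter methylation, while the copy that stays put (the **parental**)
keeps the ancestral methylation level and the ancestral function. Testing
this requires, for thousands of genes in two species:

- singleton/duplicate classification and the four ortholog classes on the
  cross-species ortholog graph (one-to-one, one-to-many, many-to-one,
  many-to-many);
- promoter and gene-body methylation from WGBS per-CpG reports, with
  coverage and polymorphism-mask filters;
- a synteny score to tell parental from daughter copies: the **GOC (gene
  order conservation) score**, the fraction (0, 25, 50, 75 or 100%) of a
  gene's 4 closest neighbours (2 upstream, 2 downstream) whose orthologs
  lie among the 4 closest neighbours of the gene's ortholog;
- **trios** (parental, daughter, un-duplicated outgroup ortholog) built
  from many-to-one groups, compared by an exact one-tailed binomial sign
  test: with `k` of `n` non-tied trios favouring the alternative,
  `P = sum_{i>=k} C(n,i) / 2^n`;
- the promoter CpG observed/expected ratio
  `CpG_o/e = (n_CpG/(L-1)) / ((n_C/L)(n_G/L))`, depressed by historical
  methylation via C→T deamination, and mRNA abundance, both expected to
  drop in daughter copies.

`dupmeth` implements this pipeline end to end, plus a synthetic
two-species generator with known ground truth (duplication biased toward
methylated genes, a clamped daughter methylation increment, tandem vs
relocated placement, Poisson/Binomial WGBS read sampling, methylation-
dependent CpG depletion and expression), so every stage is testable
without any real dataset.

## Worked example

```python
from dupmeth import SimulationConfig, simulate_two_species
from dupmeth.pipeline import AnalysisInputs, run_full_analysis

config = SimulationConfig(seed=42, n_ancestral_genes=400, daughter_delta=0.2)
dataset = simulate_two_species(config)
results = run_full_analysis(AnalysisInputs.from_dataset(dataset))

st = results.sign_tests
row = st[(st.species == "speciesA") & (st.tissue == "colon")
         & (st.metric == "promoter_meth")
         & (st.comparison == "daughter_vs_parental")
         & (st.variant == "all")].iloc[0]
print(f"colon trios: daughter higher in {row.n_daughter_higher} of {row.n}, "
      f"one-tailed binomial P = {row.p_one_tailed:.2e}")
```

prints

```
colon trios: daughter higher in 65 of 74, one-tailed binomial P = 6.75e-12
```

i.e. with a true daughter increment of 0.2 the pipeline recovers the
asymmetry: most trios show the GOC-identified daughter copy
hypermethylated relative to the parental copy, and the sign test is
decisive. The same run gives, among duplicated many-to-one genes,

```
promoter methylation vs GOC: Spearman rho = -0.271 (P = 3.5e-04, n = 170)
expression vs GOC:           Spearman rho = 0.237 (P = 1.9e-03, n = 170)
```

methylation falls and expression rises with conserved synteny — daughter
copies (low GOC) are methylated and lowly expressed. `results.manifest`
records row counts at every filter step; `results.write(outdir)` emits
all tables as TSV.

The same analyses run from files via the CLI:

```
dupmeth simulate --seed 42 --out sim/
dupmeth run-all --config cfg.yaml --out results/
```

with subcommands `quantify`, `classify` and `goc` exposing the individual
stages (see `dupmeth --help`).

## Layout

```
src/dupmeth/
  model.py        domain types (GeneModel, OrthologGroup, DuplicationTrio, ...)
  io.py           GFF3 / cytosine-report / BED / FASTA / TSV readers-writers
  simulate.py     synthetic two-species generator with ground truth
  orthology.py    singleton/duplicate calls, ortholog classes, ohnologs
  methylation.py  CpG filters, promoter/body regions, region methylation
  synteny.py      gene order and GOC scores
  cpg.py          CpG observed/expected ratio
  trios.py        trio construction and sign tests
  stats.py        binomial / Mann-Whitney / Kruskal-Wallis + Dunn + Holm / Spearman
  pipeline.py     end-to-end orchestration and the run manifest
  cli.py          `dupmeth` console script
docs/methods.md   model, parameters, numerical conventions, limitations
```
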