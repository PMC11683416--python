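"""Synthetic two-species dataset generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every pipeline stage can be exercised and validated against
truth without any real dataset:

- ancestral genes laid out in a shared order on both species' chromosomes,
  each with a per-tissue promoter methylation level drawn from a Beta
  prior and shared across species (orthologs inherit the ancestral state);
- per-gene duplication in either species with probability
  ``dup_rate * (1 + dup_meth_bias * m0)`` (clamped), so highly methylated
  genes duplicate preferentially;
- the parental copy keeps its position and ancestral methylation; the
  daughter copy gains ``daughter_delta`` (clamped to [0,1]) and either
  stays in tandem next to the parent or relocates to a uniform random
  slot, which is what separates parental from daughter GOC scores;
- background local gene-order shuffling adds GOC noise;
- WGBS-like read sampling: per CpG site and tissue, total reads are
  Poisson and methylated reads Binomial at the site's true level (the
  regional truth is a single scalar per gene x tissue);
- promoter CpG density, and hence the emitted promoter sequence and its
  CpG_o/e, decreases with historical methylation (deamination footprint);
- expression decreases with promoter methylation, with log-normal noise;
- relocated daughters are occasionally emitted as single-exon retrogenes;
- a fraction of duplicated genes is labelled as ohnologs.

Identical seeds give byte-identical output files: one SeedSequence keyed
by ``seed`` is split into named substreams (one per independent output),
and all iteration orders are fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from dupmeth import io as dmio
from dupmeth.model import GeneModel, HomologyRecord, MaskRegions, Transcript

_BASES = np.array(list("ATCG"))
_BASE_PROBS = np.array([0.3, 0.3, 0.2, 0.2])  # A T C G

# Named RNG substreams, in spawn order. Adding a stream at the end keeps
# earlier streams' draws unchanged.
_STREAMS = (
    "ancestry", "duplication", "placement_a", "placement_b",
    "structure", "truth_a", "truth_b", "reads_a", "reads_b",
    "seq_a", "seq_b", "expr_a", "expr_b", "mask_a", "mask_b", "ohnolog",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-species duplication/methylation simulation.

    Defaults are the study conditions the rest of the package is tested
    under; see docs/methods.md for the rationale behind each value.
    """

    seed: int = 0
    n_ancestral_genes: int = 500
    n_chromosomes: int = 4
    tissues_a: tuple[str, ...] = ("colon", "liver", "placenta", "bcell")
    tissues_b: tuple[str, ...] = ("colon", "liver", "placenta", "cortex")
    meth_prior: tuple[float, float] = (2.0, 2.0)
    dup_rate: float = 0.2
    dup_meth_bias: float = 1.0
    daughter_delta: float = 0.2
    tandem_prob: float = 0.25
    shuffle_rate: float = 0.02
    coverage_mean_a: float = 20.0
    coverage_mean_b: float = 20.0
    promoter_len: int = 1500
    cpg_base_density: float = 0.04
    cpg_deamination_coef: float = 0.5
    body_cpg_density: float = 0.01
    expr_base: float = 10.0
    expr_meth_slope: float = 0.8
    expr_noise_sd: float = 0.3
    retro_prob: float = 0.15
    ohnolog_frac: float = 0.1
    tissue_noise_sd: float = 0.05
    mask_frac: float = 0.01
    species_a: str = "speciesA"
    species_b: str = "speciesB"

    def __post_init__(self) -> None:
        probs = {
            "dup_rate": self.dup_rate, "daughter_delta": self.daughter_delta,
            "tandem_prob": self.tandem_prob, "shuffle_rate": self.shuffle_rate,
            "retro_prob": self.retro_prob, "ohnolog_frac": self.ohnolog_frac,
            "mask_frac": self.mask_frac,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.coverage_mean_a <= 0 or self.coverage_mean_b <= 0:
            raise ValueError("coverage means must be > 0")
        if min(self.meth_prior) <= 0:
            raise ValueError("meth_prior shapes must be > 0")
        if self.n_ancestral_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need >= 1 gene and >= 1 chromosome")
        if self.promoter_len < 2:
            raise ValueError("promoter_len must be >= 2")
        if not self.tissues_a or not self.tissues_b:
            raise ValueError("tissue lists must be nonempty")
        if self.dup_meth_bias < 0:
            raise ValueError("dup_meth_bias must be >= 0")

    @property
    def shared_tissues(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.tissues_a) & set(self.tissues_b)))


@dataclass
class SimulatedDataset:
    """Everything one simulation emits, in memory; ``write`` dumps files."""

    config: SimulationConfig
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    homology: list[HomologyRecord]
    cpg_a: pd.DataFrame
    cpg_b: pd.DataFrame
    mask_a: MaskRegions
    mask_b: MaskRegions
    promoters_a: dict[str, str]
    promoters_b: dict[str, str]
    expression_a: pd.DataFrame
    expression_b: pd.DataFrame
    ohnologs_a: set[str] = field(default_factory=set)
    ohnologs_b: set[str] = field(default_factory=set)
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full bundle; returns logical name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for tag, genes in (("a", self.genes_a), ("b", self.genes_b)):
            paths[f"annotation_{tag}"] = outdir / f"genes_{tag}.gff3"
            dmio.write_gene_annotation(genes, paths[f"annotation_{tag}"])
        paths["homology"] = outdir / "homology.tsv"
        dmio.write_homology_table(self.homology, paths["homology"])

        for tag, cpg, tissues in (
            ("a", self.cpg_a, self.config.tissues_a),
            ("b", self.cpg_b, self.config.tissues_b),
        ):
            for tissue in tissues:
                single = pd.DataFrame(
                    {
                        "chrom": cpg["chrom"],
                        "pos": cpg["pos"],
                        "meth": cpg[f"meth:{tissue}"],
                        "total": cpg[f"total:{tissue}"],
                    }
                )
                key = f"cpg_{tag}_{tissue}"
                paths[key] = outdir / f"cpg_{tag}_{tissue}.tsv"
                dmio.write_cpg_report(single, paths[key])

        for tag, mask in (("a", self.mask_a), ("b", self.mask_b)):
            paths[f"mask_{tag}"] = outdir / f"mask_{tag}.bed"
            dmio.write_mask(mask, paths[f"mask_{tag}"])
        for tag, seqs in (("a", self.promoters_a), ("b", self.promoters_b)):
            paths[f"promoters_{tag}"] = outdir / f"promoters_{tag}.fasta"
            dmio.write_fasta(seqs, paths[f"promoters_{tag}"])
        for tag, expr in (("a", self.expression_a), ("b", self.expression_b)):
            paths[f"expression_{tag}"] = outdir / f"expression_{tag}.tsv"
            dmio.write_table(expr, paths[f"expression_{tag}"], sort_by=["gene_id", "tissue"])
        for tag, ohno in (("a", self.ohnologs_a), ("b", self.ohnologs_b)):
            paths[f"ohnologs_{tag}"] = outdir / f"ohnologs_{tag}.txt"
            dmio.write_gene_list(ohno, paths[f"ohnologs_{tag}"])
        paths["truth"] = outdir / "truth.tsv"
        dmio.write_table(self.truth, paths["truth"], sort_by=["species", "gene_id"])
        return paths

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in [*self.genes_a, *self.genes_b]}


@dataclass
class _Copy:
    """One gene copy during construction."""

    copy_id: str
    ancestral_index: int
    role: str  # singleton | parental | daughter
    relocated: bool = False
    retrogene: bool = False
    ohnolog: bool = False


def _gene_structures(config: SimulationConfig, rng: np.random.Generator):
    """Per-ancestral-gene exon/intron structure, shared by both species."""
    n = config.n_ancestral_genes
    n_exons = rng.integers(3, 9, size=n)
    structures = []
    for i in range(n):
        exon_lens = rng.integers(120, 301, size=n_exons[i])
        intron_lens = rng.integers(200, 801, size=max(0, n_exons[i] - 1))
        structures.append((exon_lens.tolist(), intron_lens.tolist()))
    return structures


def _layout_species(
    config: SimulationConfig,
    tag: str,
    dup_flags: np.ndarray,
    retro_flags: dict[int, bool],
    rng_place: np.random.Generator,
) -> tuple[list[list[_Copy]], dict[int, bool]]:
    """Chromosome-wise ordered copy lists for one species.

    Ancestral genes occupy contiguous blocks per chromosome in ancestral
    order; daughters are inserted in tandem or at uniform random slots,
    then adjacent-pair shuffling adds order noise.
    """
    n = config.n_ancestral_genes
    per_chrom = int(np.ceil(n / config.n_chromosomes))
    chroms: list[list[_Copy]] = []
    for c in range(config.n_chromosomes):
        block = range(c * per_chrom, min(n, (c + 1) * per_chrom))
        chroms.append(
            [
                _Copy(f"g{i:05d}{tag}", i, "parental" if dup_flags[i] else "singleton")
                for i in block
            ]
        )
    chroms = [c for c in chroms if c]

    relocated_flags: dict[int, bool] = {}
    # Tandem-vs-relocate decisions in ancestral order for determinism.
    for i in np.flatnonzero(dup_flags):
        i = int(i)
        daughter = _Copy(f"g{i:05d}{tag}.d", i, "daughter")
        if rng_place.random() < config.tandem_prob:
            relocated_flags[i] = False
            for chrom in chroms:
                for j, copy in enumerate(chrom):
                    if copy.ancestral_index == i and copy.role == "parental":
                        chrom.insert(j + 1, daughter)
                        break
                else:
                    continue
                break
        else:
            relocated_flags[i] = True
            daughter.relocated = True
            daughter.retrogene = retro_flags.get(i, False)
            target = int(rng_place.integers(0, len(chroms)))
            slot = int(rng_place.integers(0, len(chroms[target]) + 1))
            chroms[target].insert(slot, daughter)

    # Background local shuffling: swap adjacent pairs with prob shuffle_rate.
    for chrom in chroms:
        for j in range(len(chrom) - 1):
            if rng_place.random() < config.shuffle_rate:
                chrom[j], chrom[j + 1] = chrom[j + 1], chrom[j]
    return chroms, relocated_flags


def _build_gene_models(
    config: SimulationConfig,
    species: str,
    chrom_prefix: str,
    chroms: list[list[_Copy]],
    structures,
    rng_place: np.random.Generator,
) -> list[GeneModel]:
    """Assign coordinates along each chromosome and emit GeneModel objects.

    Genes are separated by at least promoter_len + 100 bp of intergenic
    space so promoters never overlap a neighbouring gene body and
    overlapping-gene removal keeps everything.
    """
    genes: list[GeneModel] = []
    for c, chrom_copies in enumerate(chroms, start=1):
        chrom = f"{chrom_prefix}{c}"
        cursor = config.promoter_len + 1600
        for copy in chrom_copies:
            exon_lens, intron_lens = structures[copy.ancestral_index]
            if copy.retrogene:
                exon_lens, intron_lens = [sum(exon_lens)], []
            strand = "+" if rng_place.random() < 0.5 else "-"
            start = cursor
            exons = []
            pos = start
            for k, elen in enumerate(exon_lens):
                exons.append((pos, pos + elen - 1))
                pos += elen
                if k < len(intron_lens):
                    pos += intron_lens[k]
            end = exons[-1][1]
            genes.append(
                GeneModel(
                    gene_id=copy.copy_id,
                    species=species,
                    chrom=chrom,
                    strand=strand,
                    gene_start=start,
                    gene_end=end,
                    biotype="protein_coding",
                    transcripts=(Transcript(f"{copy.copy_id}.t1", tuple(exons)),),
                )
            )
            # leave room for this gene's downstream promoter (minus strand)
            # and the next gene's upstream promoter, so promoter regions of
            # neighbouring genes never overlap and every CpG position is
            # owned by exactly one gene
            gap = int(rng_place.integers(500, 2001))
            cursor = end + 2 * config.promoter_len + 200 + gap
    return genes


def _simulate_species_data(
    config: SimulationConfig,
    genes: list[GeneModel],
    copies: dict[str, _Copy],
    tissues: Sequence[str],
    prom_truth_anc: np.ndarray,  # (n_ancestral, n_union_tissues)
    union_tissues: Sequence[str],
    coverage_mean: float,
    rng_truth: np.random.Generator,
    rng_reads: np.random.Generator,
    rng_seq: np.random.Generator,
    rng_expr: np.random.Generator,
    rng_mask: np.random.Generator,
):
    """Per-species CpG reads, promoter sequences, expression and truth rows."""
    tissue_idx = [union_tissues.index(t) for t in tissues]
    delta = config.daughter_delta

    order = sorted(copies)  # fixed iteration order
    n_copies = len(order)
    gene_by_id = {g.gene_id: g for g in genes}

    # True regional methylation per copy x tissue.
    prom_truth = np.empty((n_copies, len(tissues)))
    for row, cid in enumerate(order):
        anc = copies[cid].ancestral_index
        base = prom_truth_anc[anc, tissue_idx]
        prom_truth[row] = np.clip(base + delta, 0, 1) if copies[cid].role == "daughter" else base
    body_noise = rng_truth.beta(2.0, 2.0, size=(n_copies, len(tissues)))
    body_truth = np.clip(0.5 * prom_truth + 0.5 * body_noise, 0, 1)

    # CpG site layout: density shrinks with historical (mean) methylation.
    hist_prom = prom_truth.mean(axis=1)
    hist_body = body_truth.mean(axis=1)
    site_rows: list[tuple[str, int, int, bool]] = []  # (chrom, pos, copy row, in promoter)
    prom_offsets: dict[str, np.ndarray] = {}
    even_prom = np.arange(0, config.promoter_len - 1, 2)
    for row, cid in enumerate(order):
        gene = gene_by_id[cid]
        tr = gene.transcripts[0]
        lo, hi = tr.span
        if gene.strand == "+":
            prom_start = max(1, lo - config.promoter_len)
        else:
            prom_start = hi + 1
        n_prom = int(round(
            config.promoter_len * config.cpg_base_density
            * (1.0 - config.cpg_deamination_coef * hist_prom[row])
        ))
        n_prom = min(n_prom, len(even_prom))
        offs = np.sort(rng_truth.choice(even_prom, size=n_prom, replace=False))
        prom_offsets[cid] = offs
        for off in offs:
            site_rows.append((gene.chrom, int(prom_start + off), row, True))

        body_len = hi - lo + 1
        even_body = np.arange(0, body_len - 1, 2)
        n_body = int(round(
            body_len * config.body_cpg_density
            * (1.0 - config.cpg_deamination_coef * hist_body[row])
        ))
        n_body = min(n_body, len(even_body))
        boffs = np.sort(rng_truth.choice(even_body, size=n_body, replace=False))
        for off in boffs:
            site_rows.append((gene.chrom, int(lo + off), row, False))

    site_chrom = np.array([s[0] for s in site_rows])
    site_pos = np.array([s[1] for s in site_rows], dtype=np.int64)
    site_copy = np.array([s[2] for s in site_rows], dtype=np.int64)
    in_promoter = np.array([s[3] for s in site_rows], dtype=bool)

    cpg = pd.DataFrame({"chrom": site_chrom, "pos": site_pos})
    for j, tissue in enumerate(tissues):
        level = np.where(in_promoter, prom_truth[site_copy, j], body_truth[site_copy, j])
        total = rng_reads.poisson(coverage_mean, size=len(site_pos))
        meth = rng_reads.binomial(total, level)
        cpg[f"meth:{tissue}"] = meth
        cpg[f"total:{tissue}"] = total
    cpg = cpg.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    # Promoter sequences: random background with CG dinucleotides planted
    # at the simulated CpG site offsets.
    promoters: dict[str, str] = {}
    for cid in order:
        chars = _BASES[rng_seq.choice(4, size=config.promoter_len, p=_BASE_PROBS)]
        offs = prom_offsets[cid]
        chars[offs] = "C"
        chars[offs + 1] = "G"
        promoters[cid] = "".join(chars)

    # Expression: declines with promoter methylation, log-normal noise.
    expr_rows = []
    noise = rng_expr.normal(0.0, config.expr_noise_sd, size=(n_copies, len(tissues)))
    for row, cid in enumerate(order):
        for j, tissue in enumerate(tissues):
            value = (
                config.expr_base
                * max(0.0, 1.0 - config.expr_meth_slope * prom_truth[row, j])
                * float(np.exp(noise[row, j]))
            )
            expr_rows.append({"gene_id": cid, "tissue": tissue, "abundance": value})
    expression = pd.DataFrame(expr_rows, columns=["gene_id", "tissue", "abundance"])

    # Polymorphism mask: a random fraction of CpG positions.
    unique_sites = cpg[["chrom", "pos"]]
    n_masked = int(round(config.mask_frac * len(unique_sites)))
    mask_intervals: dict[str, list[tuple[int, int]]] = {}
    if n_masked > 0:
        picks = np.sort(rng_mask.choice(len(unique_sites), size=n_masked, replace=False))
        for i in picks:
            chrom = str(unique_sites["chrom"].iloc[i])
            pos = int(unique_sites["pos"].iloc[i])
            mask_intervals.setdefault(chrom, []).append((pos, pos))
    mask = MaskRegions(mask_intervals)

    truth_rows = []
    for row, cid in enumerate(order):
        copy = copies[cid]
        entry = {
            "gene_id": cid,
            "species": genes[0].species,
            "ancestral_id": f"g{copy.ancestral_index:05d}",
            "role": copy.role,
            "relocated": copy.relocated,
            "retrogene": copy.retrogene,
            "ohnolog": copy.ohnolog,
        }
        for j, tissue in enumerate(tissues):
            entry[f"true_prom:{tissue}"] = prom_truth[row, j]
            entry[f"true_body:{tissue}"] = body_truth[row, j]
        truth_rows.append(entry)
    return cpg, promoters, expression, mask, pd.DataFrame(truth_rows)


def simulate_two_species(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative model and return the dataset bundle."""
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(child) for name, child in zip(_STREAMS, ss.spawn(len(_STREAMS)))}

    n = config.n_ancestral_genes
    rng_anc = rngs["ancestry"]
    m0 = rng_anc.beta(*config.meth_prior, size=n)
    union_tissues = sorted(set(config.tissues_a) | set(config.tissues_b))
    prom_truth_anc = np.clip(
        m0[:, None] + rng_anc.normal(0.0, config.tissue_noise_sd, size=(n, len(union_tissues))),
        0.0, 1.0,
    )

    p_dup = np.clip(config.dup_rate * (1.0 + config.dup_meth_bias * m0), 0.0, 1.0)
    rng_dup = rngs["duplication"]
    dup_a = rng_dup.random(n) < p_dup
    dup_b = rng_dup.random(n) < p_dup

    structures = _gene_structures(config, rngs["structure"])

    retro_a = {int(i): bool(rngs["placement_a"].random() < config.retro_prob) for i in np.flatnonzero(dup_a)}
    retro_b = {int(i): bool(rngs["placement_b"].random() < config.retro_prob) for i in np.flatnonzero(dup_b)}
    chroms_a, _ = _layout_species(config, "a", dup_a, retro_a, rngs["placement_a"])
    chroms_b, _ = _layout_species(config, "b", dup_b, retro_b, rngs["placement_b"])

    genes_a = _build_gene_models(config, config.species_a, "chrA", chroms_a, structures, rngs["placement_a"])
    genes_b = _build_gene_models(config, config.species_b, "chrB", chroms_b, structures, rngs["placement_b"])

    copies_a = {c.copy_id: c for chrom in chroms_a for c in chrom}
    copies_b = {c.copy_id: c for chrom in chroms_b for c in chrom}

    # Ohnolog labels: a fraction of duplicated ancestral genes per species;
    # both copies inherit the label.
    rng_ohno = rngs["ohnolog"]
    ohnologs_a: set[str] = set()
    ohnologs_b: set[str] = set()
    for flags, copies, sink in ((dup_a, copies_a, ohnologs_a), (dup_b, copies_b, ohnologs_b)):
        for i in np.flatnonzero(flags):
            if rng_ohno.random() < config.ohnolog_frac:
                for cid, copy in copies.items():
                    if copy.ancestral_index == int(i):
                        copy.ohnolog = True
                        sink.add(cid)

    # Homology: ortholog edges between all A copies and all B copies of the
    # same ancestral gene; paralog edges within species between the two copies.
    by_anc_a: dict[int, list[str]] = {}
    by_anc_b: dict[int, list[str]] = {}
    for cid, copy in copies_a.items():
        by_anc_a.setdefault(copy.ancestral_index, []).append(cid)
    for cid, copy in copies_b.items():
        by_anc_b.setdefault(copy.ancestral_index, []).append(cid)
    homology: list[HomologyRecord] = []
    for i in range(n):
        for ga in sorted(by_anc_a.get(i, [])):
            for gb in sorted(by_anc_b.get(i, [])):
                homology.append(HomologyRecord(ga, gb, "ortholog"))
        for members in (sorted(by_anc_a.get(i, [])), sorted(by_anc_b.get(i, []))):
            if len(members) == 2:
                homology.append(HomologyRecord(members[0], members[1], "within_species_paralog"))

    cpg_a, prom_a, expr_a, mask_a, truth_a = _simulate_species_data(
        config, genes_a, copies_a, config.tissues_a, prom_truth_anc, union_tissues,
        config.coverage_mean_a, rngs["truth_a"], rngs["reads_a"], rngs["seq_a"],
        rngs["expr_a"], rngs["mask_a"],
    )
    cpg_b, prom_b, expr_b, mask_b, truth_b = _simulate_species_data(
        config, genes_b, copies_b, config.tissues_b, prom_truth_anc, union_tissues,
        config.coverage_mean_b, rngs["truth_b"], rngs["reads_b"], rngs["seq_b"],
        rngs["expr_b"], rngs["mask_b"],
    )
    truth = pd.concat([truth_a, truth_b], ignore_index=True)

    return SimulatedDataset(
        config=config,
        genes_a=genes_a,
        genes_b=genes_b,
        homology=homology,
        cpg_a=cpg_a,
        cpg_b=cpg_b,
        mask_a=mask_a,
        mask_b=mask_b,
        promoters_a=prom_a,
        promoters_b=prom_b,
        expression_a=expr_a,
        expression_b=expr_b,
        ohnologs_a=ohnologs_a,
        ohnologs_b=ohnologs_b,
        truth=truth,
    )
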