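"""End-to-end orchestration of the comparative methylation analysis.

``run_full_analysis`` chains the stages into the study's analyses:

1.  per-species overlapping-gene removal and CpG coverage/mask filtering;
2.  per-gene, per-tissue promoter and gene-body methylation;
3.  singleton/duplicate classification (with an ohnolog-excluded
    duplicate stratum) and ortholog-type assignment;
4.  GOC scores for the duplicated members of many-to-one groups
    (recomputed from gene order, or taken from the homology table);
5.  group comparisons: singleton vs duplicate, the four ortholog classes,
    and metric-vs-GOC strata (methylation, CpG_o/e, expression), via
    Mann-Whitney / Kruskal-Wallis + Dunn + Holm / Spearman;
6.  parental/daughter trio construction per tissue and every sign test
    (daughter vs parental, each copy vs the outgroup ortholog in shared
    tissues, retrogene-excluded variants, promoter and body metrics,
    CpG_o/e and expression);
7.  a run manifest recording row counts at every filter step.

Every stage is also callable on its own, and all outputs are plain
data frames with deterministic ordering, so a full run equals chaining
the stage functions on intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from dupmeth import io as dmio
from dupmeth import __version__
from dupmeth.cpg import cpg_oe_table
from dupmeth.methylation import (
    filter_cpg_sites,
    quantify_methylation,
    remove_overlapping_genes,
)
from dupmeth.model import GeneModel, HomologyRecord, MaskRegions, OrthologGroup
from dupmeth.orthology import (
    build_ortholog_groups,
    classify_duplication_status,
    flag_ohnologs,
)
from dupmeth.simulate import SimulatedDataset
from dupmeth.stats import kruskal_dunn_holm, mann_whitney_u
from dupmeth.synteny import build_gene_order, goc_from_homology, goc_score, ortholog_map
from dupmeth.trios import (
    build_trios,
    compare_metric_across_goc,
    sign_test_copy_vs_outgroup,
    sign_test_daughter_vs_parental,
    trios_to_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths and parameters for a file-driven run.

    ``cpg_reports_a``/``_b`` map tissue -> cytosine-report path; the
    species' tissue set is their key set. ``shared_tissues`` defaults to
    the intersection of the two tissue sets.
    """

    annotation_a: str
    annotation_b: str
    homology: str
    cpg_reports_a: dict[str, str]
    cpg_reports_b: dict[str, str]
    species_a: str = "speciesA"
    species_b: str = "speciesB"
    mask_a: str | None = None
    mask_b: str | None = None
    promoters_a: str | None = None
    promoters_b: str | None = None
    expression_a: str | None = None
    expression_b: str | None = None
    ohnologs_a: str | None = None
    ohnologs_b: str | None = None
    shared_tissues: tuple[str, ...] | None = None
    min_coverage_a: int = 5
    min_coverage_b: int = 3
    promoter_length: int = 1500
    goc_mode: str = "recompute"
    cpgoe_convention: str = "length_adjusted"
    outdir: str = "dupmeth_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.cpg_reports_a or not self.cpg_reports_b:
            raise ValueError("each species needs at least one cytosine report")
        if self.goc_mode not in ("recompute", "from_table"):
            raise ValueError(f"goc_mode must be recompute|from_table, got {self.goc_mode!r}")
        if self.shared_tissues is not None:
            both = set(self.cpg_reports_a) & set(self.cpg_reports_b)
            extra = set(self.shared_tissues) - both
            if extra:
                raise ValueError(f"shared tissues absent from a species: {sorted(extra)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "shared_tissues" in raw and raw["shared_tissues"] is not None:
            raw["shared_tissues"] = tuple(raw["shared_tissues"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisInputs:
    """In-memory inputs to the analysis, from files or from a simulation."""

    species_a: str
    species_b: str
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    homology: list[HomologyRecord]
    cpg_a: pd.DataFrame
    cpg_b: pd.DataFrame
    tissues_a: tuple[str, ...]
    tissues_b: tuple[str, ...]
    mask_a: MaskRegions | None = None
    mask_b: MaskRegions | None = None
    promoters_a: dict[str, str] = field(default_factory=dict)
    promoters_b: dict[str, str] = field(default_factory=dict)
    expression_a: pd.DataFrame | None = None
    expression_b: pd.DataFrame | None = None
    ohnologs_a: set[str] = field(default_factory=set)
    ohnologs_b: set[str] = field(default_factory=set)
    shared_tissues: tuple[str, ...] = ()
    min_coverage_a: int = 5
    min_coverage_b: int = 3
    promoter_length: int = 1500
    goc_mode: str = "recompute"
    cpgoe_convention: str = "length_adjusted"
    config_label: str = "in-memory"

    def __post_init__(self) -> None:
        if not self.shared_tissues:
            self.shared_tissues = tuple(sorted(set(self.tissues_a) & set(self.tissues_b)))

    @classmethod
    def from_dataset(
        cls,
        dataset: SimulatedDataset,
        min_coverage_a: int = 5,
        min_coverage_b: int = 3,
        goc_mode: str = "recompute",
    ) -> "AnalysisInputs":
        cfg = dataset.config
        return cls(
            species_a=cfg.species_a,
            species_b=cfg.species_b,
            genes_a=dataset.genes_a,
            genes_b=dataset.genes_b,
            homology=dataset.homology,
            cpg_a=dataset.cpg_a,
            cpg_b=dataset.cpg_b,
            tissues_a=tuple(cfg.tissues_a),
            tissues_b=tuple(cfg.tissues_b),
            mask_a=dataset.mask_a,
            mask_b=dataset.mask_b,
            promoters_a=dataset.promoters_a,
            promoters_b=dataset.promoters_b,
            expression_a=dataset.expression_a,
            expression_b=dataset.expression_b,
            ohnologs_a=dataset.ohnologs_a,
            ohnologs_b=dataset.ohnologs_b,
            min_coverage_a=min_coverage_a,
            min_coverage_b=min_coverage_b,
            goc_mode=goc_mode,
            promoter_length=cfg.promoter_len,
            config_label=f"simulated(seed={cfg.seed})",
        )

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "AnalysisInputs":
        genes_a = dmio.read_gene_annotation(config.annotation_a, config.species_a)
        genes_b = dmio.read_gene_annotation(config.annotation_b, config.species_b)
        homology = dmio.read_homology_table(config.homology)
        cpg_a = dmio.combine_cpg_reports(
            {t: dmio.read_cpg_report(p, t) for t, p in config.cpg_reports_a.items()}
        )
        cpg_b = dmio.combine_cpg_reports(
            {t: dmio.read_cpg_report(p, t) for t, p in config.cpg_reports_b.items()}
        )
        maybe = lambda reader, p: reader(p) if p else None  # noqa: E731
        return cls(
            species_a=config.species_a,
            species_b=config.species_b,
            genes_a=genes_a,
            genes_b=genes_b,
            homology=homology,
            cpg_a=cpg_a,
            cpg_b=cpg_b,
            tissues_a=tuple(sorted(config.cpg_reports_a)),
            tissues_b=tuple(sorted(config.cpg_reports_b)),
            mask_a=maybe(dmio.read_mask, config.mask_a),
            mask_b=maybe(dmio.read_mask, config.mask_b),
            promoters_a=dmio.read_fasta(config.promoters_a) if config.promoters_a else {},
            promoters_b=dmio.read_fasta(config.promoters_b) if config.promoters_b else {},
            expression_a=maybe(dmio.read_expression, config.expression_a),
            expression_b=maybe(dmio.read_expression, config.expression_b),
            ohnologs_a=set(dmio.read_gene_list(config.ohnologs_a)) if config.ohnologs_a else set(),
            ohnologs_b=set(dmio.read_gene_list(config.ohnologs_b)) if config.ohnologs_b else set(),
            shared_tissues=config.shared_tissues or (),
            min_coverage_a=config.min_coverage_a,
            min_coverage_b=config.min_coverage_b,
            promoter_length=config.promoter_length,
            goc_mode=config.goc_mode,
            cpgoe_convention=config.cpgoe_convention,
            config_label=config.config_hash(),
        )


@dataclass
class AnalysisResults:
    """All tables one run produces, plus the audit manifest."""

    methylation_a: pd.DataFrame
    methylation_b: pd.DataFrame
    classification: pd.DataFrame
    goc: pd.DataFrame
    trios: pd.DataFrame
    group_comparisons: pd.DataFrame
    pairwise: pd.DataFrame
    goc_correlations: pd.DataFrame
    sign_tests: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        tables = {
            "methylation_a": (self.methylation_a, ["gene_id", "tissue"]),
            "methylation_b": (self.methylation_b, ["gene_id", "tissue"]),
            "classification": (self.classification, ["species", "gene_id"]),
            "goc": (self.goc, ["species", "gene_id"]),
            "trios": (self.trios, ["duplicated_species", "tissue", "parental_gene"]),
            "group_comparisons": (self.group_comparisons, None),
            "pairwise": (self.pairwise, None),
            "goc_correlations": (self.goc_correlations, None),
            "sign_tests": (self.sign_tests, None),
        }
        for name, (frame, sort_by) in tables.items():
            paths[name] = outdir / f"{name}.tsv"
            dmio.write_table(frame, paths[name], sort_by=sort_by)
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return paths


def ortholog_class(group: OrthologGroup, side: str) -> str:
    """The four-way ortholog class from one species' perspective.

    ``side`` is 'a' or 'b'. one2many from A's perspective is many2one from
    B's, and vice versa.
    """
    na, nb = len(group.members_a), len(group.members_b)
    if side == "b":
        na, nb = nb, na
    if na == 1 and nb == 1:
        return "one2one"
    if na == 1:
        return "one2many"
    if nb == 1:
        return "many2one"
    return "many2many"


def compute_goc_scores(inputs: AnalysisInputs, groups: Sequence[OrthologGroup]) -> pd.DataFrame:
    """GOC per duplicated member of every many-to-one group.

    In 'recompute' mode the score is computed from gene order and the
    ortholog map; in 'from_table' mode externally supplied values from the
    homology table are used verbatim (genes lacking one are skipped).
    Columns: species, gene_id, ortholog_gene, goc.
    """
    rows = []
    if inputs.goc_mode == "from_table":
        supplied = goc_from_homology(inputs.homology)
        species_of = {g.gene_id: g.species for g in [*inputs.genes_a, *inputs.genes_b]}
        for group in groups:
            for members, outgroup_members in (
                (group.members_a, group.members_b),
                (group.members_b, group.members_a),
            ):
                if len(members) < 2 or len(outgroup_members) != 1:
                    continue
                outgroup = next(iter(outgroup_members))
                for gid in sorted(members):
                    if gid in supplied:
                        rows.append(
                            {
                                "species": species_of[gid],
                                "gene_id": gid,
                                "ortholog_gene": outgroup,
                                "goc": supplied[gid],
                            }
                        )
        return pd.DataFrame(rows, columns=["species", "gene_id", "ortholog_gene", "goc"])

    order_a = build_gene_order(inputs.genes_a)
    order_b = build_gene_order(inputs.genes_b)
    omap = ortholog_map(inputs.homology)
    orders = {inputs.species_a: order_a, inputs.species_b: order_b}
    species_of = {g.gene_id: g.species for g in [*inputs.genes_a, *inputs.genes_b]}
    for group in groups:
        for members, outgroup_members in (
            (group.members_a, group.members_b),
            (group.members_b, group.members_a),
        ):
            if len(members) < 2 or len(outgroup_members) != 1:
                continue
            outgroup = next(iter(outgroup_members))
            for gid in sorted(members):
                focal_order = orders[species_of[gid]]
                other_order = orders[species_of[outgroup]]
                if gid not in focal_order or outgroup not in other_order:
                    continue
                score = goc_score(gid, outgroup, focal_order, other_order, omap)
                rows.append(
                    {
                        "species": species_of[gid],
                        "gene_id": gid,
                        "ortholog_gene": outgroup,
                        "goc": score.score,
                    }
                )
    return pd.DataFrame(rows, columns=["species", "gene_id", "ortholog_gene", "goc"])


def _level_maps(meth: pd.DataFrame, column: str) -> dict[str, dict[str, float]]:
    """tissue -> {gene_id -> level}, dropping missing values."""
    out: dict[str, dict[str, float]] = {}
    present = meth.dropna(subset=[column])
    for tissue, sub in present.groupby("tissue", sort=True):
        out[str(tissue)] = dict(zip(sub["gene_id"], sub[column]))
    return out


def _expression_maps(expr: pd.DataFrame | None) -> dict[str, dict[str, float]]:
    if expr is None or expr.empty:
        return {}
    out: dict[str, dict[str, float]] = {}
    for tissue, sub in expr.groupby("tissue", sort=True):
        out[str(tissue)] = dict(zip(sub["gene_id"], sub["abundance"]))
    return out


def run_full_analysis(inputs: AnalysisInputs) -> AnalysisResults:
    """Execute every stage and collect result tables plus the manifest."""
    manifest: dict = {
        "dupmeth_version": __version__,
        "config": inputs.config_label,
        "species": [inputs.species_a, inputs.species_b],
        "tissues": {"a": list(inputs.tissues_a), "b": list(inputs.tissues_b)},
        "shared_tissues": list(inputs.shared_tissues),
        "filters": {},
    }

    # --- stage 1: gene filters and methylation quantification ------------
    meth: dict[str, pd.DataFrame] = {}
    kept_genes: dict[str, list[GeneModel]] = {}
    for tag, genes, cpg, tissues, min_cov, mask in (
        ("a", inputs.genes_a, inputs.cpg_a, inputs.tissues_a, inputs.min_coverage_a, inputs.mask_a),
        ("b", inputs.genes_b, inputs.cpg_b, inputs.tissues_b, inputs.min_coverage_b, inputs.mask_b),
    ):
        retained = remove_overlapping_genes(genes)
        manifest["filters"][f"genes_{tag}"] = {"before": len(genes), "after": len(retained)}
        filtered = filter_cpg_sites(cpg, tissues, min_cov, mask=mask)
        manifest["filters"][f"cpg_sites_{tag}"] = {"before": len(cpg), "after": len(filtered)}
        kept_genes[tag] = retained
        meth[tag] = quantify_methylation(retained, filtered, tissues, inputs.promoter_length)
        logger.info(
            "species %s: %d/%d genes retained, %d/%d CpG sites retained",
            tag, len(retained), len(genes), len(filtered), len(cpg),
        )

    # --- stage 2: classification ------------------------------------------
    species_of = {g.gene_id: g.species for g in [*inputs.genes_a, *inputs.genes_b]}
    all_by_species = {
        inputs.species_a: inputs.genes_a,
        inputs.species_b: inputs.genes_b,
    }
    status: dict[str, str] = {}
    ohnolog_flags: dict[str, bool] = {}
    for species, genes in all_by_species.items():
        edges = [
            h for h in inputs.homology
            if h.relation == "within_species_paralog"
            and species_of.get(h.gene_a) == species
        ]
        status.update(classify_duplication_status(genes, edges))
        listed = inputs.ohnologs_a if species == inputs.species_a else inputs.ohnologs_b
        flagged = flag_ohnologs(genes, listed)
        for g in genes:
            ohnolog_flags[g.gene_id] = g.gene_id in flagged

    groups = build_ortholog_groups(
        inputs.homology, species_of, inputs.species_a, inputs.species_b
    )
    manifest["filters"]["ortholog_groups"] = {"n": len(groups)}
    class_of: dict[str, str] = {}
    group_of: dict[str, OrthologGroup] = {}
    for group in groups:
        for gid in group.members_a:
            class_of[gid] = ortholog_class(group, "a")
            group_of[gid] = group
        for gid in group.members_b:
            class_of[gid] = ortholog_class(group, "b")
            group_of[gid] = group

    classification = pd.DataFrame(
        [
            {
                "species": species_of[gid],
                "gene_id": gid,
                "status": status[gid],
                "ohnolog": ohnolog_flags.get(gid, False),
                "ortholog_class": class_of.get(gid, ""),
            }
            for gid in sorted(species_of)
        ],
        columns=["species", "gene_id", "status", "ohnolog", "ortholog_class"],
    )

    # --- stage 3: GOC ------------------------------------------------------
    goc_frame = compute_goc_scores(inputs, groups)
    goc_scores = dict(zip(goc_frame["gene_id"], goc_frame["goc"]))

    # --- stage 4: metric maps ---------------------------------------------
    prom = {"a": _level_maps(meth["a"], "promoter_level"), "b": _level_maps(meth["b"], "promoter_level")}
    body = {"a": _level_maps(meth["a"], "body_level"), "b": _level_maps(meth["b"], "body_level")}
    expr = {
        "a": _expression_maps(inputs.expression_a),
        "b": _expression_maps(inputs.expression_b),
    }
    cpgoe: dict[str, dict[str, float]] = {}
    for tag, seqs in (("a", inputs.promoters_a), ("b", inputs.promoters_b)):
        table = cpg_oe_table(seqs, inputs.cpgoe_convention) if seqs else {}
        cpgoe[tag] = {g: v for g, v in table.items() if v is not None}

    species_tag = {inputs.species_a: "a", inputs.species_b: "b"}
    tissues_of = {"a": inputs.tissues_a, "b": inputs.tissues_b}

    # --- stage 5: group comparisons ---------------------------------------
    comparison_rows = []
    pairwise_rows = []

    def _record_pairwise(species: str, tissue: str, metric: str, analysis: str, result) -> None:
        if result is None or result.pairwise is None:
            return
        for (gi, gj), (z, p_raw, p_adj) in result.pairwise.items():
            pairwise_rows.append(
                {
                    "species": species, "tissue": tissue, "metric": metric,
                    "analysis": analysis, "group_i": gi, "group_j": gj,
                    "z": z, "p_raw": p_raw, "p_holm": p_adj,
                }
            )

    for species in (inputs.species_a, inputs.species_b):
        tag = species_tag[species]
        gene_ids = [g.gene_id for g in all_by_species[species]]
        for metric_name, per_tissue in (("promoter_meth", prom[tag]), ("body_meth", body[tag])):
            for tissue in tissues_of[tag]:
                values = per_tissue.get(tissue, {})
                singletons = [values[g] for g in gene_ids if g in values and status[g] == "singleton"]
                duplicates = [values[g] for g in gene_ids if g in values and status[g] == "duplicate"]
                dup_no_ohno = [
                    values[g]
                    for g in gene_ids
                    if g in values and status[g] == "duplicate" and not ohnolog_flags.get(g, False)
                ]
                if singletons and duplicates:
                    mw = mann_whitney_u(singletons, duplicates)
                    comparison_rows.append(
                        {
                            "species": species, "tissue": tissue, "metric": metric_name,
                            "analysis": "singleton_vs_duplicate",
                            "statistic": mw.statistic, "p_value": mw.p_value,
                            "n": f"{len(singletons)},{len(duplicates)}",
                        }
                    )
                    strata = {"singleton": singletons, "duplicate": duplicates}
                    if dup_no_ohno:
                        strata["duplicate_no_ohnolog"] = dup_no_ohno
                    if len(strata) >= 2:
                        kd = kruskal_dunn_holm(strata)
                        comparison_rows.append(
                            {
                                "species": species, "tissue": tissue, "metric": metric_name,
                                "analysis": "singleton_duplicate_strata",
                                "statistic": kd.statistic, "p_value": kd.p_value,
                                "n": ",".join(str(x) for x in kd.n),
                            }
                        )
                        _record_pairwise(species, tissue, metric_name, "singleton_duplicate_strata", kd)

                classes = {}
                for cls in ("one2one", "one2many", "many2one", "many2many"):
                    sample = [
                        values[g] for g in gene_ids if g in values and class_of.get(g) == cls
                    ]
                    if sample:
                        classes[cls] = sample
                if len(classes) >= 2:
                    kd = kruskal_dunn_holm(classes)
                    comparison_rows.append(
                        {
                            "species": species, "tissue": tissue, "metric": metric_name,
                            "analysis": "ortholog_classes",
                            "statistic": kd.statistic, "p_value": kd.p_value,
                            "n": ",".join(str(x) for x in kd.n),
                        }
                    )
                    _record_pairwise(species, tissue, metric_name, "ortholog_classes", kd)

    # --- stage 6: metric vs GOC among many-to-one duplicates ---------------
    correlation_rows = []
    for species in (inputs.species_a, inputs.species_b):
        tag = species_tag[species]
        species_goc = {
            g: s for g, s in goc_scores.items()
            if species_of.get(g) == species and class_of.get(g) == "many2one"
        }
        metric_sources: list[tuple[str, str | None, Mapping[str, float]]] = []
        for tissue in tissues_of[tag]:
            if tissue in prom[tag]:
                metric_sources.append(("promoter_meth", tissue, prom[tag][tissue]))
            if tissue in body[tag]:
                metric_sources.append(("body_meth", tissue, body[tag][tissue]))
            if tissue in expr[tag]:
                metric_sources.append(("expression", tissue, expr[tag][tissue]))
        if cpgoe[tag]:
            metric_sources.append(("cpg_oe", None, cpgoe[tag]))
        for metric_name, tissue, values in metric_sources:
            outcome = compare_metric_across_goc(species_goc, values)
            sp = outcome["spearman"]
            kd = outcome["kruskal_dunn"]
            correlation_rows.append(
                {
                    "species": species,
                    "tissue": tissue if tissue is not None else "",
                    "metric": metric_name,
                    "n": outcome["n"],
                    "spearman_rho": sp.statistic,
                    "spearman_p": sp.p_value if sp.p_value is not None else float("nan"),
                    "kruskal_h": kd.statistic if kd is not None else float("nan"),
                    "kruskal_p": kd.p_value if kd is not None else float("nan"),
                }
            )
            if kd is not None:
                _record_pairwise(species, tissue or "", metric_name, "goc_strata", kd)

    # --- stage 7: trios and sign tests -------------------------------------
    genes_by_id = {g.gene_id: g for g in [*inputs.genes_a, *inputs.genes_b]}
    all_trios = []
    sign_rows = []

    def _sign_row(species, tissue, metric, comparison, variant, result) -> None:
        sign_rows.append(
            {
                "species": species, "tissue": tissue, "metric": metric,
                "comparison": comparison, "variant": variant,
                "n_daughter_higher": result.n_daughter_higher,
                "n_parental_higher": result.n_parental_higher,
                "n_ties": result.n_ties, "n": result.n,
                "p_one_tailed": result.p_one_tailed
                if result.p_one_tailed is not None
                else float("nan"),
            }
        )

    for species in (inputs.species_a, inputs.species_b):
        tag = species_tag[species]
        other_tag = "b" if tag == "a" else "a"
        for tissue in tissues_of[tag]:
            selection = prom[tag].get(tissue, {})
            trios = build_trios(
                groups, selection, goc_scores, genes_by_id,
                inputs.species_a, inputs.species_b, tissue,
            )
            trios = [t for t in trios if t.duplicated_species == species]
            all_trios.extend(trios)
            variants = {"all": trios, "no_retrogenes": [t for t in trios if not t.has_retrogene]}
            for variant, subset in variants.items():
                if not subset:
                    continue
                metric_maps: list[tuple[str, Mapping[str, float]]] = [
                    ("promoter_meth", prom[tag].get(tissue, {})),
                    ("body_meth", body[tag].get(tissue, {})),
                    ("cpg_oe", cpgoe[tag]),
                ]
                if tissue in expr[tag]:
                    metric_maps.append(("expression", expr[tag][tissue]))
                for metric_name, values in metric_maps:
                    if not values:
                        continue
                    result = sign_test_daughter_vs_parental(subset, values, metric_name)
                    _sign_row(species, tissue, metric_name, "daughter_vs_parental", variant, result)
                if tissue in inputs.shared_tissues:
                    outgroup_prom = prom[other_tag].get(tissue, {})
                    if outgroup_prom:
                        for role in ("daughter", "parental"):
                            result = sign_test_copy_vs_outgroup(
                                subset, prom[tag].get(tissue, {}), outgroup_prom,
                                role, "promoter_meth",
                            )
                            _sign_row(
                                species, tissue, "promoter_meth",
                                f"{role}_vs_outgroup", variant, result,
                            )

    manifest["filters"]["trios"] = {"n": len(all_trios)}

    return AnalysisResults(
        methylation_a=meth["a"],
        methylation_b=meth["b"],
        classification=classification,
        goc=goc_frame,
        trios=trios_to_frame(all_trios),
        group_comparisons=pd.DataFrame(
            comparison_rows,
            columns=["species", "tissue", "metric", "analysis", "statistic", "p_value", "n"],
        ),
        pairwise=pd.DataFrame(
            pairwise_rows,
            columns=[
                "species", "tissue", "metric", "analysis",
                "group_i", "group_j", "z", "p_raw", "p_holm",
            ],
        ),
        goc_correlations=pd.DataFrame(
            correlation_rows,
            columns=[
                "species", "tissue", "metric", "n",
                "spearman_rho", "spearman_p", "kruskal_h", "kruskal_p",
            ],
        ),
        sign_tests=pd.DataFrame(
            sign_rows,
            columns=[
                "species", "tissue", "metric", "comparison", "variant",
                "n_daughter_higher", "n_parental_higher", "n_ties", "n", "p_one_tailed",
            ],
        ),
        manifest=manifest,
    )
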