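"""Parental/daughter trio construction and paired comparisons.

A *many-to-one* ortholog group holds genes that duplicated in one species
after the two species split, plus a single un-duplicated ortholog in the
other species that serves as a proxy for the pre-duplication (ancestral)
state. From each such group a *trio* is built:

1. if the group has more than 2 duplicated-species copies, keep the 2
   copies with the largest promoter-methylation difference in the tissue
   under study;
2. the copy with the strictly higher GOC score is the parental copy, the
   lower one the daughter; pairs with equal GOC are rejected;
3. the single other-species ortholog is the outgroup.

Sign tests then count, per metric, in how many trios the daughter copy
exceeds (or is below, for CpG_o/e and expression) the parental copy or
the outgroup, against a one-tailed binomial null of 1/2. Ties are
excluded from n. Retrogenes (single-exon copies whose paralog has >= 3
exons) can be excluded trio-wise: a trio drops when either selected copy
is a retrogene.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dupmeth.model import (
    DuplicationTrio,
    GeneModel,
    OrthologGroup,
    SignTestResult,
    TestResult,
)
from dupmeth.methylation import select_longest_transcript
from dupmeth.stats import binomial_one_tailed, kruskal_dunn_holm, spearman

# metric -> direction of the one-tailed alternative for the daughter copy,
# fixed a priori: hypermethylation raises promoter/body methylation and
# lowers CpG content and expression.
DAUGHTER_DIRECTION: dict[str, str] = {
    "promoter_meth": "higher",
    "body_meth": "higher",
    "cpg_oe": "lower",
    "expression": "lower",
}


def select_trio_pair(
    group: OrthologGroup,
    methylation: Mapping[str, float],
    duplicated_members: Sequence[str] | None = None,
) -> tuple[str, str] | None:
    """The 2 duplicated-species copies with the largest methylation difference.

    ``methylation`` maps gene id -> promoter level in the tissue under
    study (missing genes simply absent). Returns None (rejection) when
    fewer than 2 members have data. Ties in |difference| break to the
    lexicographically smallest sorted id pair, so selection is
    deterministic.
    """
    if duplicated_members is None:
        na, nb = len(group.members_a), len(group.members_b)
        if na >= 2 and nb == 1:
            duplicated_members = sorted(group.members_a)
        elif nb >= 2 and na == 1:
            duplicated_members = sorted(group.members_b)
        else:
            raise ValueError("group is not many-to-one")
    with_data = [g for g in sorted(duplicated_members) if g in methylation]
    if len(with_data) < 2:
        return None
    best: tuple[float, tuple[str, str]] | None = None
    for i, gi in enumerate(with_data):
        for gj in with_data[i + 1 :]:
            delta = abs(methylation[gi] - methylation[gj])
            candidate = (-delta, (gi, gj))
            if best is None or candidate < best:
                best = candidate
    return best[1]


def assign_parental_daughter(
    pair: tuple[str, str],
    goc_scores: Mapping[str, int],
    outgroup_gene: str,
    duplicated_species: str,
    tissue: str,
) -> DuplicationTrio | None:
    """Orient a selected pair into a trio by GOC; equal GOC -> rejection.

    Returns None when either GOC is missing or the two scores are equal
    (the group is uninformative about which copy relocated).
    """
    g1, g2 = pair
    if g1 not in goc_scores or g2 not in goc_scores:
        return None
    s1, s2 = goc_scores[g1], goc_scores[g2]
    if s1 == s2:
        return None
    parental, daughter = (g1, g2) if s1 > s2 else (g2, g1)
    return DuplicationTrio(
        duplicated_species=duplicated_species,
        parental_gene=parental,
        daughter_gene=daughter,
        outgroup_gene=outgroup_gene,
        parental_goc=goc_scores[parental],
        daughter_goc=goc_scores[daughter],
        tissue=tissue,
    )


def is_retrogene(gene: GeneModel, paralog: GeneModel) -> bool:
    """Single-exon gene whose paralog has 3 or more exons.

    Exon counts come from each gene's longest transcript. This is the
    operational signature of a retrotransposed (intron-less) duplicate.
    """
    return (
        select_longest_transcript(gene).n_exons == 1
        and select_longest_transcript(paralog).n_exons >= 3
    )


def build_trios(
    groups: Iterable[OrthologGroup],
    methylation: Mapping[str, float],
    goc_scores: Mapping[str, int],
    genes_by_id: Mapping[str, GeneModel],
    species_a: str,
    species_b: str,
    tissue: str,
) -> list[DuplicationTrio]:
    """Construct trios from every many-to-one group, for one tissue.

    Only groups of shape (>=2, 1) or (1, >=2) are considered; pair
    selection uses ``methylation`` (promoter levels in ``tissue``);
    orientation uses ``goc_scores``. Retrogene flags are attached when
    both selected copies are present in ``genes_by_id``.
    """
    trios: list[DuplicationTrio] = []
    for group in groups:
        na, nb = len(group.members_a), len(group.members_b)
        if na >= 2 and nb == 1:
            duplicated, outgroup = sorted(group.members_a), next(iter(group.members_b))
            species = species_a
        elif nb >= 2 and na == 1:
            duplicated, outgroup = sorted(group.members_b), next(iter(group.members_a))
            species = species_b
        else:
            continue
        pair = select_trio_pair(group, methylation, duplicated_members=duplicated)
        if pair is None:
            continue
        trio = assign_parental_daughter(pair, goc_scores, outgroup, species, tissue)
        if trio is None:
            continue
        pg = genes_by_id.get(trio.parental_gene)
        dg = genes_by_id.get(trio.daughter_gene)
        if pg is not None and dg is not None:
            trio = replace(
                trio,
                parental_is_retrogene=is_retrogene(pg, dg),
                daughter_is_retrogene=is_retrogene(dg, pg),
            )
        trios.append(trio)
    return trios


def _paired_sign_counts(
    trios: Sequence[DuplicationTrio],
    left_values: Mapping[str, float],
    right_values: Mapping[str, float],
    left_role: str,
    right_role: str,
    direction: str,
) -> SignTestResult:
    """Count trios where the left member beats the right one, and test.

    ``direction`` is the one-tailed alternative for the left member:
    'higher' tests P(X >= n_left_higher), 'lower' tests the mirror.
    """
    n_left = n_right = n_ties = 0
    for trio in trios:
        left_gene = getattr(trio, f"{left_role}_gene")
        right_gene = getattr(trio, f"{right_role}_gene")
        if left_gene not in left_values or right_gene not in right_values:
            continue
        lv, rv = left_values[left_gene], right_values[right_gene]
        if lv > rv:
            n_left += 1
        elif lv < rv:
            n_right += 1
        else:
            n_ties += 1
    n = n_left + n_right
    if n == 0:
        return SignTestResult(n_left, n_right, n_ties, None)
    k = n_left if direction == "higher" else n_right
    return SignTestResult(n_left, n_right, n_ties, binomial_one_tailed(k, n))


def sign_test_daughter_vs_parental(
    trios: Sequence[DuplicationTrio],
    metric_values: Mapping[str, float],
    metric: str = "promoter_meth",
) -> SignTestResult:
    """One-tailed sign test: daughter vs parental copy on one metric.

    ``metric_values`` maps gene id -> value (in the tissue under study);
    trios missing either value are skipped, exact ties excluded from n.
    The alternative direction per metric is fixed in DAUGHTER_DIRECTION.
    """
    direction = DAUGHTER_DIRECTION[metric]
    return _paired_sign_counts(
        trios, metric_values, metric_values, "daughter", "parental", direction
    )


def sign_test_copy_vs_outgroup(
    trios: Sequence[DuplicationTrio],
    copy_values: Mapping[str, float],
    outgroup_values: Mapping[str, float],
    copy_role: str,
    metric: str = "promoter_meth",
) -> SignTestResult:
    """One-tailed sign test: a chosen copy vs the outgroup ortholog.

    ``copy_role`` is 'daughter' or 'parental'. Values for the copy come
    from the duplicated species and for the outgroup from the other
    species, both in a tissue shared between the species.
    """
    if copy_role not in ("daughter", "parental"):
        raise ValueError(f"copy_role must be daughter or parental, got {copy_role!r}")
    direction = DAUGHTER_DIRECTION[metric]
    return _paired_sign_counts(
        trios, copy_values, outgroup_values, copy_role, "outgroup", direction
    )


def compare_metric_across_goc(
    goc_scores: Mapping[str, int],
    metric_values: Mapping[str, float],
) -> dict:
    """Distribution of a metric across GOC strata among many-to-one genes.

    Returns a dict with the per-GOC value lists, the Spearman correlation
    of (metric, GOC) over genes, and — when >= 2 strata are populated —
    the Kruskal-Wallis/Dunn/Holm comparison. With a single stratum the
    correlation is undefined and reported as such.
    """
    genes = sorted(set(goc_scores) & set(metric_values))
    strata: dict[int, list[float]] = {}
    for g in genes:
        strata.setdefault(goc_scores[g], []).append(metric_values[g])
    result: dict = {"groups": {k: strata[k] for k in sorted(strata)}, "n": len(genes)}
    if len(strata) < 2 or len(genes) < 3:
        result["spearman"] = TestResult("spearman", float("nan"), None, (len(genes),))
        result["kruskal_dunn"] = None
        return result
    x = np.array([goc_scores[g] for g in genes], dtype=float)
    y = np.array([metric_values[g] for g in genes], dtype=float)
    result["spearman"] = spearman(x, y)
    result["kruskal_dunn"] = kruskal_dunn_holm(
        {str(k): v for k, v in result["groups"].items()}
    )
    return result


def trios_to_frame(trios: Sequence[DuplicationTrio]) -> pd.DataFrame:
    """Flatten trios into a table (one row per trio)."""
    rows = [
        {
            "duplicated_species": t.duplicated_species,
            "tissue": t.tissue,
            "parental_gene": t.parental_gene,
            "daughter_gene": t.daughter_gene,
            "outgroup_gene": t.outgroup_gene,
            "parental_goc": t.parental_goc,
            "daughter_goc": t.daughter_goc,
            "parental_is_retrogene": t.parental_is_retrogene,
            "daughter_is_retrogene": t.daughter_is_retrogene,
        }
        for t in trios
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "duplicated_species", "tissue", "parental_gene", "daughter_gene",
            "outgroup_gene", "parental_goc", "daughter_goc",
            "parental_is_retrogene", "daughter_is_retrogene",
        ],
    )
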