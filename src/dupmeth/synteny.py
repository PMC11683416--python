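"""Gene order and gene-order-conservation (GOC) scores.

The GOC score of a gene against its ortholog counts how many of the
gene's 4 closest neighbours (2 immediately upstream, 2 immediately
downstream in gene order) have an ortholog among the 4 closest
neighbours of the ortholog gene, scaled to a percentage: 0, 25, 50, 75
or 100. The denominator is fixed at 4, so neighbours missing at a
chromosome end count as non-matching, preserving the five-value codomain.

The score is directional (the focal gene's neighbours are searched in the
ortholog's window) and matching is permissive: a neighbour with several
orthologs matches if any of them lies in the window. Parental copies of a
duplication retain their ancestral neighbourhood and score high; relocated
daughter copies typically score 0 — which is what makes GOC usable to
tell the two copies apart.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

from dupmeth.model import GeneModel, GOCScore, HomologyRecord

NEIGHBORS_PER_SIDE = 2


class GeneOrder:
    """Gene order per chromosome, sorted by (gene_start, gene_end, gene_id)."""

    def __init__(self, per_chrom: Mapping[str, Sequence[str]]):
        self.per_chrom: dict[str, list[str]] = {c: list(v) for c, v in per_chrom.items()}
        self._index: dict[str, tuple[str, int]] = {}
        for chrom, ids in self.per_chrom.items():
            for i, gid in enumerate(ids):
                if gid in self._index:
                    raise ValueError(f"gene {gid!r} appears twice in the order")
                self._index[gid] = (chrom, i)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def neighbors(self, gene_id: str, per_side: int = NEIGHBORS_PER_SIDE) -> list[str]:
        """Up to ``per_side`` genes on each side of ``gene_id`` in gene order."""
        if gene_id not in self._index:
            raise KeyError(f"gene {gene_id!r} not in the gene order")
        chrom, i = self._index[gene_id]
        ids = self.per_chrom[chrom]
        left = ids[max(0, i - per_side) : i]
        right = ids[i + 1 : i + 1 + per_side]
        return left + right


def build_gene_order(
    genes: Iterable[GeneModel],
    include_filter: Callable[[GeneModel], bool] | None = None,
) -> GeneOrder:
    """Deterministic per-chromosome gene order.

    ``include_filter`` defaults to keeping protein-coding genes only;
    excluded genes appear neither in the order nor in anyone's neighbour
    window.
    """
    if include_filter is None:
        include_filter = lambda g: g.biotype == "protein_coding"  # noqa: E731
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if include_filter(g):
            by_chrom.setdefault(g.chrom, []).append(g)
    if not by_chrom:
        raise ValueError("no genes pass the include filter")
    ordered = {}
    for chrom, members in by_chrom.items():
        members.sort(key=lambda g: (g.gene_start, g.gene_end, g.gene_id))
        ordered[chrom] = [g.gene_id for g in members]
    return GeneOrder(ordered)


def ortholog_map(homology: Sequence[HomologyRecord]) -> dict[str, set[str]]:
    """gene id -> set of its cross-species orthologs (both directions)."""
    out: dict[str, set[str]] = {}
    for rec in homology:
        if rec.relation != "ortholog":
            continue
        out.setdefault(rec.gene_a, set()).add(rec.gene_b)
        out.setdefault(rec.gene_b, set()).add(rec.gene_a)
    return out


def goc_score(
    focal_gene: str,
    ortholog_gene: str,
    order_focal: GeneOrder,
    order_ortholog: GeneOrder,
    orthology: Mapping[str, set[str]],
) -> GOCScore:
    """GOC score of ``focal_gene`` against ``ortholog_gene``.

    A focal neighbour matches iff any of its orthologs lies among the
    ortholog gene's (up to) 4 closest neighbours; score = 25 x matches.
    """
    if focal_gene not in order_focal:
        raise KeyError(f"focal gene {focal_gene!r} absent from its gene order")
    if ortholog_gene not in order_ortholog:
        raise KeyError(f"ortholog gene {ortholog_gene!r} absent from its gene order")
    window = set(order_ortholog.neighbors(ortholog_gene))
    matches = 0
    for neighbor in order_focal.neighbors(focal_gene):
        if orthology.get(neighbor, set()) & window:
            matches += 1
    return GOCScore(focal_gene, ortholog_gene, 25 * matches)


def goc_table(
    pairs: Iterable[tuple[str, str]],
    order_focal: GeneOrder,
    order_ortholog: GeneOrder,
    orthology: Mapping[str, set[str]],
) -> dict[str, int]:
    """GOC score per focal gene for (focal, ortholog) pairs."""
    return {
        focal: goc_score(focal, ortho, order_focal, order_ortholog, orthology).score
        for focal, ortho in pairs
    }


def goc_from_homology(homology: Sequence[HomologyRecord]) -> dict[str, int]:
    """Externally supplied GOC values keyed by each edge's first gene.

    Used in 'from_table' mode when the homology table carries a GOC column
    (as Ensembl exports do); recomputation is skipped for those genes.
    """
    out: dict[str, int] = {}
    for rec in homology:
        if rec.relation == "ortholog" and rec.goc is not None:
            out[rec.gene_a] = rec.goc
    return out
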