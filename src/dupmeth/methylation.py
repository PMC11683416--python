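"""CpG site filtering and per-gene region methylation.

The quantification follows the WGBS conventions of the comparative study
this pipeline supports:

- a CpG site is retained only if covered by at least ``min_coverage``
  reads in every tissue of the species' tissue set and not at a masked
  (polymorphic) position;
- the promoter is the 1,500 bp immediately upstream of the TSS of the
  longest transcript, excluding the TSS itself; the gene body is the rest
  of the transcript span (TSS through the 3' end);
- a region's methylation level is the unweighted arithmetic mean of the
  per-site fractional methylation values (methylated/total per site), not
  a pooled read-count ratio; the two differ under variable depth.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from dupmeth.model import GeneModel, MaskRegions, RegionMethylation, Transcript

PROMOTER_LENGTH = 1500


def filter_cpg_sites(
    sites: pd.DataFrame,
    tissues: Sequence[str],
    min_coverage: int,
    mask: MaskRegions | None = None,
    require_all_tissues: bool = True,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Apply the coverage and polymorphism-mask filters.

    ``sites`` is a multi-tissue CpG table (columns chrom, pos,
    meth:<tissue>, total:<tissue>). With ``require_all_tissues`` (the
    default) a site survives iff total reads >= min_coverage in *every*
    tissue listed, and a single filtered table is returned. With the flag
    off, filtering is per tissue and a dict tissue -> filtered table is
    returned instead.
    """
    if min_coverage < 1:
        raise ValueError(f"min_coverage must be >= 1, got {min_coverage}")
    if len(tissues) == 0:
        raise ValueError("tissue set must be nonempty")
    for tissue in tissues:
        if f"total:{tissue}" not in sites.columns:
            raise ValueError(f"sites table lacks tissue {tissue!r}")

    if mask is not None and len(sites):
        unmasked = np.ones(len(sites), dtype=bool)
        for chrom, idx in sites.groupby("chrom", sort=False).indices.items():
            unmasked[idx] = ~mask.contains(str(chrom), sites["pos"].to_numpy()[idx])
    else:
        unmasked = np.ones(len(sites), dtype=bool)

    if require_all_tissues:
        keep = unmasked.copy()
        for tissue in tissues:
            keep &= sites[f"total:{tissue}"].to_numpy() >= min_coverage
        return sites.loc[keep].reset_index(drop=True)

    out: dict[str, pd.DataFrame] = {}
    for tissue in tissues:
        keep = unmasked & (sites[f"total:{tissue}"].to_numpy() >= min_coverage)
        out[tissue] = sites.loc[keep].reset_index(drop=True)
    return out


def select_longest_transcript(gene: GeneModel) -> Transcript:
    """The transcript with the largest summed exon length.

    Ties break to the lexicographically smallest transcript id, so the
    choice is deterministic.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return max(gene.transcripts, key=lambda t: (t.exon_length, _NegStr(t.transcript_id)))


class _NegStr:
    """Orders strings descending inside a max() key, i.e. min id wins ties."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def remove_overlapping_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Drop every gene whose span intersects another gene's span.

    Overlap is tested on [gene_start, gene_end] on the same chromosome,
    regardless of strand, and removal is mutual: both partners go, and a
    chain A-B-C (A overlaps B, B overlaps C) removes all three.
    """
    genes = list(genes)
    overlapping: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.gene_start, g.gene_end, g.gene_id))
        max_end = -1
        max_end_gene = None
        for g in members:
            if max_end_gene is not None and g.gene_start <= max_end:
                overlapping.add(g.gene_id)
                overlapping.add(max_end_gene.gene_id)
            if g.gene_end > max_end:
                max_end, max_end_gene = g.gene_end, g
    return [g for g in genes if g.gene_id not in overlapping]


def transcript_tss(gene: GeneModel, transcript: Transcript) -> int:
    """The 5'-most transcribed base of the transcript in genomic coordinates."""
    lo, hi = transcript.span
    return lo if gene.strand == "+" else hi


def promoter_region(
    gene: GeneModel,
    promoter_length: int = PROMOTER_LENGTH,
    transcript: Transcript | None = None,
) -> tuple[int, int]:
    """Promoter interval: ``promoter_length`` bp upstream of the TSS.

    On + the promoter is [TSS - L, TSS - 1], clipped at position 1; on -
    it is [TSS + 1, TSS + L]. The TSS itself is excluded (it belongs to
    the gene body).
    """
    tr = transcript if transcript is not None else select_longest_transcript(gene)
    tss = transcript_tss(gene, tr)
    if gene.strand == "+":
        return max(1, tss - promoter_length), tss - 1
    return tss + 1, tss + promoter_length


def body_region(
    gene: GeneModel,
    transcript: Transcript | None = None,
) -> tuple[int, int]:
    """Gene-body interval: the transcript span from the TSS to the 3' end.

    In genomic coordinates this is simply the selected transcript's span,
    since the promoter lies wholly upstream of it.
    """
    tr = transcript if transcript is not None else select_longest_transcript(gene)
    return tr.span


def region_methylation(
    filtered_sites: pd.DataFrame,
    chrom: str,
    region: tuple[int, int],
    tissue: str,
) -> tuple[float | None, int]:
    """Mean per-site fractional methylation over sites inside a region.

    Returns (level, n_sites); level is None when no filtered site with
    positive coverage in the tissue falls inside the region.
    """
    sub = filtered_sites[filtered_sites["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    inside = (pos >= region[0]) & (pos <= region[1])
    total = sub[f"total:{tissue}"].to_numpy()[inside]
    meth = sub[f"meth:{tissue}"].to_numpy()[inside]
    covered = total > 0
    if not covered.any():
        return None, 0
    fractions = meth[covered] / total[covered]
    return float(fractions.mean()), int(covered.sum())


def quantify_methylation(
    genes: Iterable[GeneModel],
    filtered_sites: pd.DataFrame,
    tissues: Sequence[str],
    promoter_length: int = PROMOTER_LENGTH,
) -> pd.DataFrame:
    """Per-gene, per-tissue promoter and body methylation as a long table.

    Columns: gene_id, tissue, promoter_level, body_level, n_promoter_cpgs,
    n_body_cpgs. Levels are NaN when the region holds no filtered CpG.
    Genes should already have passed overlapping-gene removal.
    """
    # Pre-sort site positions per chromosome once; per-gene windows are
    # then O(log n) lookups instead of boolean scans.
    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom, sub in filtered_sites.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        entry = {"pos": sub["pos"].to_numpy()}
        for tissue in tissues:
            entry[f"m:{tissue}"] = sub[f"meth:{tissue}"].to_numpy()
            entry[f"t:{tissue}"] = sub[f"total:{tissue}"].to_numpy()
        by_chrom[str(chrom)] = entry

    rows = []
    for gene in genes:
        tr = select_longest_transcript(gene)
        prom = promoter_region(gene, promoter_length, transcript=tr)
        body = body_region(gene, transcript=tr)
        entry = by_chrom.get(gene.chrom)
        for tissue in tissues:
            values: dict[str, float | int | None] = {
                "gene_id": gene.gene_id,
                "tissue": tissue,
            }
            for name, region in (("promoter", prom), ("body", body)):
                if entry is None:
                    values[f"{name}_level"], values[f"n_{name}_cpgs"] = np.nan, 0
                    continue
                pos = entry["pos"]
                lo = np.searchsorted(pos, region[0], side="left")
                hi = np.searchsorted(pos, region[1], side="right")
                total = entry[f"t:{tissue}"][lo:hi]
                meth = entry[f"m:{tissue}"][lo:hi]
                covered = total > 0
                if covered.any():
                    values[f"{name}_level"] = float((meth[covered] / total[covered]).mean())
                    values[f"n_{name}_cpgs"] = int(covered.sum())
                else:
                    values[f"{name}_level"] = np.nan
                    values[f"n_{name}_cpgs"] = 0
            rows.append(values)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "tissue", "promoter_level", "body_level",
            "n_promoter_cpgs", "n_body_cpgs",
        ],
    )


def to_records(table: pd.DataFrame) -> list[RegionMethylation]:
    """Convert a quantification table to validated RegionMethylation records."""
    records = []
    for row in table.itertuples(index=False):
        records.append(
            RegionMethylation(
                gene_id=row.gene_id,
                tissue=row.tissue,
                promoter_level=None if pd.isna(row.promoter_level) else float(row.promoter_level),
                body_level=None if pd.isna(row.body_level) else float(row.body_level),
                n_promoter_cpgs=int(row.n_promoter_cpgs),
                n_body_cpgs=int(row.n_body_cpgs),
            )
        )
    return records
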