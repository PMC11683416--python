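"""Readers and writers for the formats the pipeline touches.

GFF3 for gene annotations, Bismark-cytosine-report-style TSV for per-CpG
methylation counts, BED for the polymorphism mask, FASTA for promoter
sequences, TSV for homology/expression tables and all outputs.

Conventions
-----------
- Internal coordinates are 1-based inclusive everywhere. BED (0-based
  half-open) is converted on read and write; nothing else is converted.
- A CpG site is keyed by the position of the forward-strand C. Reads
  reported on the reverse strand (the G at pos+1) are pooled onto the
  forward position by summing counts, so total read mass is conserved.
- ``write_table`` emits a fixed column order and a deterministic row sort,
  so identical inputs give byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dupmeth.model import (
    ExpressionRecord,
    GeneModel,
    HomologyRecord,
    MaskRegions,
    Transcript,
    VALID_RELATIONS,
)

# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def read_gene_annotation(path: str | Path, species: str) -> list[GeneModel]:
    """Parse a GFF3 file of gene/mRNA/exon features into GeneModel objects.

    Features are linked by ``Parent`` attributes: exon -> mRNA -> gene.
    Coordinates are kept 1-based inclusive as in the file. Raises
    ``ValueError`` naming the line number for malformed lines and the
    feature id for orphan exons/transcripts.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    exons: list[tuple[str, int, int]] = []  # (parent transcript, start, end)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc

            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "biotype": attrs.get("biotype", "protein_coding"),
                }
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValueError(f"{path}:{lineno}: transcript without ID/Parent")
                transcripts[tid] = {"gene": parent}
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    eid = attrs.get("ID", f"line {lineno}")
                    raise ValueError(f"exon {eid}: missing Parent attribute")
                exons.append((parent, start, end))
            # other feature types ignored

    tr_exons: dict[str, list[tuple[int, int]]] = {tid: [] for tid in transcripts}
    for parent, start, end in exons:
        if parent not in transcripts:
            raise ValueError(f"exon with unknown Parent transcript {parent!r}")
        tr_exons[parent].append((start, end))

    gene_trs: dict[str, list[Transcript]] = {gid: [] for gid in genes}
    for tid, info in transcripts.items():
        gid = info["gene"]
        if gid not in genes:
            raise ValueError(f"transcript {tid}: unknown Parent gene {gid!r}")
        if not tr_exons[tid]:
            raise ValueError(f"transcript {tid}: no exons")
        gene_trs[gid].append(Transcript(tid, tuple(sorted(tr_exons[tid]))))

    models = []
    for gid in sorted(genes):
        g = genes[gid]
        models.append(
            GeneModel(
                gene_id=gid,
                species=species,
                chrom=g["chrom"],
                strand=g["strand"],
                gene_start=g["start"],
                gene_end=g["end"],
                biotype=g["biotype"],
                transcripts=tuple(sorted(gene_trs[gid], key=lambda t: t.transcript_id)),
            )
        )
    return models


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModel objects as GFF3 (genes sorted by chrom, start, id)."""
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.chrom, g.gene_start, g.gene_id)):
        lines.append(
            "\t".join(
                [
                    g.chrom, "dupmeth", "gene", str(g.gene_start), str(g.gene_end),
                    ".", g.strand, ".", f"ID={g.gene_id};biotype={g.biotype}",
                ]
            )
        )
        for tr in g.transcripts:
            lo, hi = tr.span
            lines.append(
                "\t".join(
                    [
                        g.chrom, "dupmeth", "mRNA", str(lo), str(hi),
                        ".", g.strand, ".", f"ID={tr.transcript_id};Parent={g.gene_id}",
                    ]
                )
            )
            for i, (es, ee) in enumerate(tr.exons, start=1):
                lines.append(
                    "\t".join(
                        [
                            g.chrom, "dupmeth", "exon", str(es), str(ee),
                            ".", g.strand, ".",
                            f"ID={tr.transcript_id}.e{i};Parent={tr.transcript_id}",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cytosine reports

_CPG_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated"]


def read_cpg_report(path: str | Path, tissue: str) -> pd.DataFrame:
    """Read one tissue's per-CpG cytosine report.

    Expects a TSV with columns chrom, pos, strand, count_methylated,
    count_unmethylated (header required). Reverse-strand rows report the G
    of a CpG at position pos; their counts are summed onto the
    forward-strand C at pos-1, so each CpG appears once.

    Returns a DataFrame with columns ``chrom, pos, meth, total`` sorted by
    (chrom, pos); ``tissue`` is attached as ``df.attrs['tissue']``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _CPG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not pd.api.types.is_integer_dtype(df["pos"]):
        raise ValueError(f"{path}: pos column is not integer")
    for col in ("count_methylated", "count_unmethylated"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"{path}: {col} column is not integer")
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative values in {col}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(f"{path}: bad strand value {df.loc[bad_strand, 'strand'].iloc[0]!r}")

    fwd_pos = df["pos"].where(df["strand"] == "+", df["pos"] - 1)
    out = (
        pd.DataFrame(
            {
                "chrom": df["chrom"],
                "pos": fwd_pos,
                "meth": df["count_methylated"],
                "total": df["count_methylated"] + df["count_unmethylated"],
            }
        )
        .groupby(["chrom", "pos"], as_index=False)
        .sum()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["tissue"] = tissue
    return out


def write_cpg_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write a single-tissue CpG table back as a forward-strand-only report."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"],
            "strand": "+",
            "count_methylated": df["meth"],
            "count_unmethylated": df["total"] - df["meth"],
        }
    ).sort_values(["chrom", "pos"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False)


def combine_cpg_reports(per_tissue: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join single-tissue CpG tables into one multi-tissue table.

    Result columns: chrom, pos, then meth:<tissue>, total:<tissue> for each
    tissue (sorted tissue order). Sites absent from a tissue get 0 reads
    there, so the all-tissue coverage filter treats absence as no coverage.
    """
    merged: pd.DataFrame | None = None
    for tissue in sorted(per_tissue):
        df = per_tissue[tissue].rename(
            columns={"meth": f"meth:{tissue}", "total": f"total:{tissue}"}
        )
        merged = df if merged is None else merged.merge(df, on=["chrom", "pos"], how="outer")
    if merged is None:
        raise ValueError("no tissues supplied")
    count_cols = [c for c in merged.columns if c not in ("chrom", "pos")]
    merged[count_cols] = merged[count_cols].fillna(0).astype(np.int64)
    return merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Homology, mask, expression, gene lists


def read_homology_table(path: str | Path) -> list[HomologyRecord]:
    """Read a homology TSV: gene_a, gene_b, relation[, goc].

    ``relation`` must be 'ortholog' or 'within_species_paralog'; ``goc`` is
    optional and may be empty per row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    for col in ("gene_a", "gene_b", "relation"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    bad = ~df["relation"].isin(VALID_RELATIONS)
    if bad.any():
        raise ValueError(
            f"{path}: unknown relation {df.loc[bad, 'relation'].iloc[0]!r}; "
            f"allowed values: {', '.join(VALID_RELATIONS)}"
        )
    records = []
    has_goc = "goc" in df.columns
    for row in df.itertuples(index=False):
        goc = None
        if has_goc and not pd.isna(row.goc):
            goc = int(row.goc)
        records.append(HomologyRecord(row.gene_a, row.gene_b, row.relation, goc))
    return records


def write_homology_table(records: Iterable[HomologyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_a": r.gene_a,
                "gene_b": r.gene_b,
                "relation": r.relation,
                "goc": "" if r.goc is None else r.goc,
            }
            for r in records
        ],
        columns=["gene_a", "gene_b", "relation", "goc"],
    )
    df = df.sort_values(["relation", "gene_a", "gene_b"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_mask(path: str | Path) -> MaskRegions:
    """Read a BED file (0-based half-open) into 1-based inclusive MaskRegions."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line with <3 fields")
            chrom, start_s, end_s = fields[:3]
            start0, end0 = int(start_s), int(end_s)
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: empty BED interval")
            intervals.setdefault(chrom, []).append((start0 + 1, end0))
    return MaskRegions(intervals)


def write_mask(mask: MaskRegions, path: str | Path) -> None:
    lines = []
    for chrom, ivs in mask.to_intervals().items():
        for start1, end1 in ivs:
            lines.append(f"{chrom}\t{start1 - 1}\t{end1}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV: gene_id, tissue, abundance (TPM-like, >= 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str})
    for col in ("gene_id", "tissue", "abundance"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    if (df["abundance"] < 0).any():
        raise ValueError(f"{path}: negative abundance")
    return df.sort_values(["gene_id", "tissue"], kind="mergesort").reset_index(drop=True)


def expression_records(df: pd.DataFrame) -> list[ExpressionRecord]:
    return [
        ExpressionRecord(r.gene_id, r.tissue, float(r.abundance))
        for r in df.itertuples(index=False)
    ]


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line; blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> sequence dict; duplicate ids are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seqs[name]), id=name, description="") for name in sorted(seqs)]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# Generic table output


def write_table(df: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Write a TSV with deterministic column order and row sort.

    Rows are sorted by ``sort_by`` (default: all columns, left to right);
    floats are rendered with repr-level precision so identical frames give
    byte-identical files.
    """
    cols = list(df.columns)
    key = list(sort_by) if sort_by is not None else cols
    out = df.sort_values(key, kind="mergesort") if len(df) else df
    buf = _io.StringIO()
    out.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())
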