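"""Domain types shared across the pipeline.

All genomic coordinates are 1-based inclusive (GFF3 convention). BED input
is converted at the reading boundary; nothing downstream ever sees 0-based
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-")
VALID_RELATIONS = ("ortholog", "within_species_paralog")


@dataclass(frozen=True)
class Transcript:
    """One transcript: an id plus sorted, pairwise-disjoint exon intervals."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon {start}-{end} inverted"
                )
            if start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exon_length(self) -> int:
        """Summed exon length in bp; the basis of longest-transcript selection."""
        return sum(end - start + 1 for start, end in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class GeneModel:
    """One gene with its transcripts.

    ``gene_start``/``gene_end`` are 1-based inclusive and must contain every
    exon of every transcript.
    """

    gene_id: str
    species: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    biotype: str = "protein_coding"
    transcripts: tuple[Transcript, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.gene_start > self.gene_end or self.gene_start < 1:
            raise ValueError(
                f"gene {self.gene_id}: bad span {self.gene_start}-{self.gene_end}"
            )
        for tr in self.transcripts:
            lo, hi = tr.span
            if lo < self.gene_start or hi > self.gene_end:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {tr.transcript_id} "
                    f"exceeds gene span"
                )


@dataclass(frozen=True)
class CpGSiteRecord:
    """One CpG site keyed by the forward-strand C position.

    ``counts`` maps tissue -> (methylated_reads, total_reads). Evidence from
    the reverse-strand G is pooled onto this position by the reader.
    """

    chrom: str
    pos: int
    counts: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for tissue, (meth, total) in self.counts.items():
            if meth < 0 or total < 0:
                raise ValueError(
                    f"CpG {self.chrom}:{self.pos} tissue {tissue}: negative counts"
                )
            if meth > total:
                raise ValueError(
                    f"CpG {self.chrom}:{self.pos} tissue {tissue}: "
                    f"methylated {meth} > total {total}"
                )

    def fraction(self, tissue: str) -> float | None:
        meth, total = self.counts[tissue]
        return meth / total if total > 0 else None


@dataclass(frozen=True)
class HomologyRecord:
    """One homology edge: cross-species ortholog or within-species paralog."""

    gene_a: str
    gene_b: str
    relation: str
    goc: int | None = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-edge on {self.gene_a}")
        if self.relation not in VALID_RELATIONS:
            raise ValueError(
                f"unknown relation {self.relation!r}; allowed: {VALID_RELATIONS}"
            )
        if self.goc is not None and self.goc not in (0, 25, 50, 75, 100):
            raise ValueError(f"GOC {self.goc} not in {{0,25,50,75,100}}")


@dataclass(frozen=True)
class RegionMethylation:
    """Per-gene, per-tissue promoter and gene-body methylation.

    A level is None exactly when the corresponding CpG count is zero.
    """

    gene_id: str
    tissue: str
    promoter_level: float | None
    body_level: float | None
    n_promoter_cpgs: int
    n_body_cpgs: int

    def __post_init__(self) -> None:
        for level, n, what in (
            (self.promoter_level, self.n_promoter_cpgs, "promoter"),
            (self.body_level, self.n_body_cpgs, "body"),
        ):
            if (level is None) != (n == 0):
                raise ValueError(
                    f"{self.gene_id}/{self.tissue}: {what} level/CpG-count mismatch"
                )
            if level is not None and not 0.0 <= level <= 1.0:
                raise ValueError(f"{self.gene_id}/{self.tissue}: {what} level {level}")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError(f"{self.gene_id}/{self.tissue}: negative abundance")


class MaskRegions:
    """Masked genomic positions (e.g. C/T polymorphisms), 1-based inclusive.

    Built from BED (0-based half-open) by the reader. Supports fast
    membership tests for vectors of positions.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        intervals = intervals or {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            for start, end in ivs:
                if start > end:
                    raise ValueError(f"empty mask interval {chrom}:{start}-{end}")
            self._starts[chrom] = np.array([s for s, _ in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in ivs], dtype=np.int64)

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos = site
        return bool(self.contains(chrom, np.array([pos]))[0])

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean array: which positions fall in a masked interval."""
        if chrom not in self._starts or len(self._starts[chrom]) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] <= self._ends[chrom][idx[ok]]
        return out

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def to_intervals(self) -> dict[str, list[tuple[int, int]]]:
        return {
            chrom: list(zip(self._starts[chrom].tolist(), self._ends[chrom].tolist()))
            for chrom in sorted(self._starts)
            if len(self._starts[chrom])
        }


@dataclass(frozen=True)
class OrthologGroup:
    """A connected component of the cross-species ortholog graph."""

    members_a: frozenset[str]
    members_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members_a or not self.members_b:
            raise ValueError("ortholog group must have members in both species")

    @property
    def type(self) -> str:
        na, nb = len(self.members_a), len(self.members_b)
        if na == 1 and nb == 1:
            return "one2one"
        if na == 1:
            return "one2many_from_a"
        if nb == 1:
            return "many2one_from_a"
        return "many2many"


@dataclass(frozen=True)
class GOCScore:
    focal_gene: str
    ortholog_gene: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 25, 50, 75, 100):
            raise ValueError(f"GOC score {self.score} not in {{0,25,50,75,100}}")


@dataclass(frozen=True)
class DuplicationTrio:
    """(parental, daughter, outgroup ortholog) for one many-to-one group.

    The parental copy is the one with the strictly higher GOC score; the
    tissue records which tissue's promoter methylation drove pair selection.
    """

    duplicated_species: str
    parental_gene: str
    daughter_gene: str
    outgroup_gene: str
    parental_goc: int
    daughter_goc: int
    tissue: str
    parental_is_retrogene: bool = False
    daughter_is_retrogene: bool = False
    metrics: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parental_goc <= self.daughter_goc:
            raise ValueError(
                f"trio {self.parental_gene}/{self.daughter_gene}: parental GOC "
                f"{self.parental_goc} not > daughter GOC {self.daughter_goc}"
            )
        if len({self.parental_gene, self.daughter_gene, self.outgroup_gene}) != 3:
            raise ValueError("trio members must be pairwise distinct")

    @property
    def has_retrogene(self) -> bool:
        return self.parental_is_retrogene or self.daughter_is_retrogene


@dataclass(frozen=True)
class SignTestResult:
    """Outcome of a one-tailed binomial sign test over trios."""

    n_daughter_higher: int
    n_parental_higher: int
    n_ties: int
    p_one_tailed: float | None

    @property
    def n(self) -> int:
        return self.n_daughter_higher + self.n_parental_higher


@dataclass(frozen=True)
class TestResult:
    """Generic test outcome used by the stats module."""

    method: str
    statistic: float
    p_value: float | None
    n: tuple[int, ...]
    pairwise: Mapping[tuple[str, str], tuple[float, float, float]] | None = None
    # pairwise maps (label_i, label_j) -> (z, raw p, Holm-adjusted p)
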