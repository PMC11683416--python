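"""Singleton/duplicate classification and ortholog-type assignment.

A gene is a *duplicate* iff it has at least one within-species paralog
edge, a *singleton* otherwise. Ortholog groups are the connected
components of the bipartite cross-species ortholog graph; the component's
member counts (|A|, |B|) determine the type: one-to-one (1,1), one-to-many
(1, >=2), many-to-one (>=2, 1), many-to-many (>=2, >=2). Components are
used rather than per-pair annotation strings so the classifier works on
any edge list, including synthetic ones.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from dupmeth.model import GeneModel, HomologyRecord, OrthologGroup

logger = logging.getLogger(__name__)


def classify_duplication_status(
    genes: Iterable[GeneModel | str],
    homology: Sequence[HomologyRecord],
) -> dict[str, str]:
    """Map each gene id to 'duplicate' or 'singleton'.

    Raises ``ValueError`` if a paralog edge references an unknown gene.
    """
    gene_ids = {g.gene_id if isinstance(g, GeneModel) else g for g in genes}
    has_paralog: set[str] = set()
    for rec in homology:
        if rec.relation != "within_species_paralog":
            continue
        for gid in (rec.gene_a, rec.gene_b):
            if gid not in gene_ids:
                raise ValueError(f"paralog edge references unknown gene {gid!r}")
        has_paralog.add(rec.gene_a)
        has_paralog.add(rec.gene_b)
    return {gid: ("duplicate" if gid in has_paralog else "singleton") for gid in gene_ids}


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_ortholog_groups(
    homology: Sequence[HomologyRecord],
    species_of: Mapping[str, str],
    species_a: str,
    species_b: str,
) -> list[OrthologGroup]:
    """Connected components of the cross-species ortholog graph.

    ``species_of`` maps gene id -> species label. Ortholog edges must
    connect the two species; genes with no ortholog edge appear in no
    group. Groups are returned sorted by their smallest member id.
    """
    uf = _UnionFind()
    seen: set[str] = set()
    for rec in homology:
        if rec.relation != "ortholog":
            continue
        sa = species_of.get(rec.gene_a)
        sb = species_of.get(rec.gene_b)
        if sa is None or sb is None:
            missing = rec.gene_a if sa is None else rec.gene_b
            raise ValueError(f"ortholog edge references unknown gene {missing!r}")
        if {sa, sb} != {species_a, species_b}:
            raise ValueError(
                f"ortholog edge {rec.gene_a}-{rec.gene_b} does not connect "
                f"{species_a} and {species_b}"
            )
        uf.union(rec.gene_a, rec.gene_b)
        seen.update((rec.gene_a, rec.gene_b))

    components: dict[str, tuple[set[str], set[str]]] = {}
    for gid in seen:
        root = uf.find(gid)
        members_a, members_b = components.setdefault(root, (set(), set()))
        if species_of[gid] == species_a:
            members_a.add(gid)
        else:
            members_b.add(gid)

    groups = [
        OrthologGroup(frozenset(ma), frozenset(mb)) for ma, mb in components.values()
    ]
    groups.sort(key=lambda g: min(g.members_a | g.members_b))
    return groups


def flag_ohnologs(
    genes: Iterable[GeneModel | str],
    ohnolog_ids: Iterable[str],
) -> set[str]:
    """Intersect an ohnolog id list with the known gene set.

    Unknown ids are logged and skipped, never an error: ohnolog lists come
    from an external database whose gene universe need not match ours.
    """
    gene_ids = {g.gene_id if isinstance(g, GeneModel) else g for g in genes}
    requested = set(ohnolog_ids)
    unknown = requested - gene_ids
    if unknown:
        logger.info("ohnolog list: %d ids not in the gene set, skipped", len(unknown))
    return requested & gene_ids
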