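"""Barcode-aware taxonomic rank promotion.

When short metagenomic reads are classified (e.g. with Kraken2), many land at
high ranks — genus, family or above — because their sequence is compatible
with several related genomes. But all reads of one fragment come from the same
organism, so cloud-mates can vouch for each other: a read is *promoted* to a
lower rank held by reads of the same (enhanced) barcode, provided the mates'
lower taxa do not conflict. Two taxa conflict when neither is an
ancestor-or-self of the other; conflicts arise when fragments of closely
related species share a barcode, which deconvolution makes rarer — hence
deconvolved clouds promote more reads than raw barcodes.

Inputs are Kraken2-style two-column assignments (read id, taxon id) and an
NCBI-``nodes.dmp``-like taxonomy table (taxon, parent, rank).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Taxonomy",
    "TaxAssignment",
    "read_taxonomy",
    "read_assignments",
    "promote_cloud",
    "promotion_summary",
]

UNASSIGNED = 0  # Kraken2 convention: taxid 0 = unclassified


@dataclass
class TaxAssignment:
    pair_id: str
    taxon: int  # UNASSIGNED (0) when the classifier gave nothing


class Taxonomy:
    """Rooted taxonomy: taxon -> (parent, rank), with ancestry queries."""

    def __init__(self, nodes: Mapping[int, tuple[int, str]]):
        self.nodes = dict(nodes)
        roots = [t for t, (p, _) in self.nodes.items()
                 if p == t or p not in self.nodes]
        if len(roots) != 1:
            raise ValueError(
                f"taxonomy must have exactly one root, found {roots}"
            )
        self.root = roots[0]
        # normalise: the root is its own parent
        self.nodes[self.root] = (self.root, self.nodes[self.root][1])
        self._depth: dict[int, int] = {self.root: 0}
        for taxon in self.nodes:
            self.depth(taxon)

    def parent(self, taxon: int) -> int:
        return self.nodes[taxon][0]

    def rank(self, taxon: int) -> str:
        return self.nodes[taxon][1]

    def depth(self, taxon: int) -> int:
        """Edges from the root (root = 0); raises on unknown taxa or cycles."""
        trail = []
        t = taxon
        while t not in self._depth:
            if t not in self.nodes:
                raise KeyError(f"taxon {t} absent from taxonomy")
            trail.append(t)
            t = self.parent(t)
            if len(trail) > len(self.nodes):
                raise ValueError("taxonomy contains a cycle")
        d = self._depth[t]
        for u in reversed(trail):
            d += 1
            self._depth[u] = d
        return self._depth[taxon]

    def is_ancestor_or_self(self, anc: int, taxon: int) -> bool:
        t = taxon
        while True:
            if t == anc:
                return True
            p = self.parent(t)
            if p == t:
                return False
            t = p

    def lca(self, taxa: Sequence[int]) -> int:
        it = iter(taxa)
        cur = next(it)
        for t in it:
            a, b = cur, t
            while self.depth(a) > self.depth(b):
                a = self.parent(a)
            while self.depth(b) > self.depth(a):
                b = self.parent(b)
            while a != b:
                a, b = self.parent(a), self.parent(b)
            cur = a
        return cur


def read_taxonomy(path) -> Taxonomy:
    """Load a (taxon, parent, rank) TSV; the root has parent == itself or 0."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["taxon", "parent", "rank"],
                     dtype={"taxon": int, "parent": int, "rank": str})
    return Taxonomy({int(r.taxon): (int(r.parent), str(r.rank))
                     for r in df.itertuples()})


def read_assignments(path) -> list[TaxAssignment]:
    """Load Kraken2-style (read id, taxon id) TSV assignments."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["pair_id", "taxon"],
                     dtype={"pair_id": str, "taxon": int})
    return [TaxAssignment(str(r.pair_id), int(r.taxon))
            for r in df.itertuples()]


def _chain_tip(taxonomy: Taxonomy, taxa: set[int]) -> Optional[int]:
    """Deepest taxon if all taxa lie on one root-to-leaf chain, else None."""
    tip = max(taxa, key=lambda t: (taxonomy.depth(t), t))
    for t in taxa:
        if not taxonomy.is_ancestor_or_self(t, tip):
            return None  # divergent branches: conflict
    return tip


def promote_cloud(
    assignments: Sequence[TaxAssignment],
    taxonomy: Taxonomy,
    promote_unassigned: bool = True,
    target: str = "deepest",
) -> list[TaxAssignment]:
    """Promote each read of one (deconvolved) cloud using its cloud-mates.

    For read r, let D be the cloud-mates' taxa strictly below r's taxon. If D
    is non-empty and conflict-free (all on one root-to-leaf chain), r moves to
    the chain's deepest taxon (``target="deepest"``) or to the LCA of D
    (``target="lca"``). Conflicting mates leave r untouched. Unassigned reads
    are promoted against all mates' taxa when ``promote_unassigned``.
    Promotion is monotone: the new taxon is a descendant-or-self of the old.
    """
    if target not in ("deepest", "lca"):
        raise ValueError("target must be 'deepest' or 'lca'")
    for a in assignments:
        if a.taxon != UNASSIGNED and a.taxon not in taxonomy.nodes:
            raise KeyError(
                f"read {a.pair_id!r}: taxon {a.taxon} absent from taxonomy"
            )
    taxa = [a.taxon for a in assignments]
    out: list[TaxAssignment] = []
    for i, a in enumerate(assignments):
        mates = [t for j, t in enumerate(taxa)
                 if j != i and t != UNASSIGNED]
        if a.taxon == UNASSIGNED:
            below = set(mates) if promote_unassigned else set()
        else:
            below = {t for t in mates
                     if t != a.taxon
                     and taxonomy.is_ancestor_or_self(a.taxon, t)}
        new_taxon = a.taxon
        if below:
            tip = _chain_tip(taxonomy, below)
            if tip is not None:
                new_taxon = tip if target == "deepest" else taxonomy.lca(list(below))
        out.append(TaxAssignment(a.pair_id, new_taxon))
    return out


def promotion_summary(
    before: Sequence[TaxAssignment],
    after: Sequence[TaxAssignment],
    taxonomy: Taxonomy,
) -> pd.DataFrame:
    """Read counts per rank before and after promotion.

    Ranks are ordered root-down (by the depth of the shallowest taxon holding
    each rank); unassigned reads appear under rank ``"unassigned"``.
    """
    if {a.pair_id for a in before} != {a.pair_id for a in after}:
        raise ValueError("before/after read sets differ")

    def rank_counts(assignments: Sequence[TaxAssignment]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in assignments:
            rank = ("unassigned" if a.taxon == UNASSIGNED
                    else taxonomy.rank(a.taxon))
            counts[rank] = counts.get(rank, 0) + 1
        return counts

    b, a = rank_counts(before), rank_counts(after)
    rank_depth: dict[str, int] = {"unassigned": -1}
    for taxon, (_, rank) in taxonomy.nodes.items():
        d = taxonomy.depth(taxon)
        rank_depth[rank] = min(rank_depth.get(rank, d), d)
    ranks = sorted(set(b) | set(a), key=lambda r: rank_depth.get(r, 99))
    return pd.DataFrame(
        {"rank": ranks,
         "before": [b.get(r, 0) for r in ranks],
         "after": [a.get(r, 0) for r in ranks]}
    )
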