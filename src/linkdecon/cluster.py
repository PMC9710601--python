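"""Chinese-whispers clustering of read graphs into enhanced barcodes.

The read graph of a cloud must be cut into an unknown number of per-fragment
groups. Chinese whispers — a randomised label-propagation scheme from NLP —
fits: it is parameter-free and agnostic about the number of clusters. Every
node starts in its own cluster; nodes are visited in a fresh random order each
pass and adopt the label with the largest total incident edge weight among
their neighbours (ties broken uniformly at random); iteration stops when a
full pass changes nothing (or after ``max_iter`` passes — the process can
oscillate, but rarely does on these graphs).

Clusters are renumbered 1..G per cloud in order of first appearance, giving
each read an *enhanced barcode* ``(barcode, group)``. Reads with no edge at
all — too noisy to overlap anything, or entirely de-indexed in repeat regions
— get the special group 0, "not deconvolved".

Every cloud is seeded from a stable hash of (global seed, barcode), so results
do not depend on the order or interleaving in which clouds are processed: runs
with different worker counts are bit-identical.
"""

from __future__ import annotations

import hashlib
import random
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .io import ReadCloud, ReadPair
from .kmer_index import IndexParams, KmerIndex
from .read_graph import build_bipartite, collapse, similarity_sets

__all__ = [
    "Deconvolution",
    "chinese_whispers",
    "deconvolve_cloud",
    "deconvolve_all",
    "cloud_seed",
]


@dataclass
class Deconvolution:
    """Enhanced-barcode labels: pair_id -> (original barcode, group >= 0)."""

    labels: dict[str, tuple[str, int]] = field(default_factory=dict)

    def group_of(self, pair_id: str) -> int:
        return self.labels[pair_id][1]

    def deconvolved_fraction(
        self, pair_ids: Optional[Iterable[str]] = None
    ) -> float:
        """Fraction of pairs with group >= 1 (over ``pair_ids`` if given)."""
        pids = list(pair_ids) if pair_ids is not None else list(self.labels)
        if not pids:
            return float("nan")
        good = sum(1 for p in pids if self.labels[p][1] >= 1)
        return good / len(pids)

    def cloud_members(
        self, include_group0: bool = False
    ) -> dict[tuple[str, int], list[str]]:
        """Deconvolved clouds: (barcode, group) -> member pair_ids."""
        out: dict[tuple[str, int], list[str]] = {}
        for pid, key in self.labels.items():
            if key[1] == 0 and not include_group0:
                continue
            out.setdefault(key, []).append(pid)
        return out


def cloud_seed(seed: int, barcode: str) -> int:
    """Stable per-cloud seed derived from the global seed and the barcode."""
    digest = hashlib.blake2b(
        f"{seed}:{barcode}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


def chinese_whispers(
    graph: nx.Graph, seed: int = 0, max_iter: int = 100
) -> dict:
    """Weighted Chinese-whispers node labels (label = some node id).

    A node's own current label does not vote; only neighbour labels do.
    Isolated nodes keep their own label. Deterministic under ``seed``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = random.Random(seed)
    nodes = list(graph.nodes)
    labels = {node: node for node in nodes}
    for _ in range(max_iter):
        changed = False
        order = nodes[:]
        rng.shuffle(order)
        for node in order:
            votes: dict = {}
            for nbr, data in graph.adj[node].items():
                lbl = labels[nbr]
                votes[lbl] = votes.get(lbl, 0) + data.get("weight", 1)
            if not votes:
                continue
            best = max(votes.values())
            winners = [lbl for lbl, v in votes.items() if v == best]
            new = winners[0] if len(winners) == 1 else rng.choice(winners)
            if new != labels[node]:
                labels[node] = new
                changed = True
        if not changed:
            break
    return labels


def _renumber(
    cloud: ReadCloud, graph: nx.Graph, raw_labels: Mapping
) -> dict[str, tuple[str, int]]:
    """Groups numbered 1..G by first appearance in pair input order; edge-less
    pairs get group 0."""
    groups: dict = {}
    out: dict[str, tuple[str, int]] = {}
    for pair in cloud.pairs:
        pid = pair.pair_id
        if graph.degree(pid) == 0:
            out[pid] = (cloud.barcode, 0)
        else:
            lbl = raw_labels[pid]
            if lbl not in groups:
                groups[lbl] = len(groups) + 1
            out[pid] = (cloud.barcode, groups[lbl])
    return out


def deconvolve_cloud(
    cloud: ReadCloud,
    index: KmerIndex,
    barcode_of: Mapping[str, str],
    seed: int = 0,
    similar: Optional[Mapping[str, set[str]]] = None,
    max_iter: int = 100,
) -> dict[str, tuple[str, int]]:
    """Deconvolve one cloud: bipartite -> read graph -> Chinese whispers.

    Returns pair_id -> (barcode, group) for the cloud's pairs. The clustering
    seed is :func:`cloud_seed`-derived, so the result is independent of when
    and where this cloud is processed.
    """
    bipartite = build_bipartite(cloud, index, barcode_of, similar=similar)
    graph = collapse(bipartite)
    raw = chinese_whispers(graph, seed=cloud_seed(seed, cloud.barcode),
                           max_iter=max_iter)
    return _renumber(cloud, graph, raw)


def deconvolve_all(
    pairs: Sequence[ReadPair],
    clouds: Mapping[str, ReadCloud],
    index: KmerIndex,
    seed: int = 0,
    workers: int = 1,
) -> Deconvolution:
    """Deconvolve every cloud of the dataset.

    Similarity sets are computed once for the whole dataset, then clouds are
    processed independently (``workers`` threads; output is invariant to the
    worker count by construction). Unbarcoded pairs are passed through
    unlabeled.
    """
    result = Deconvolution()
    if not clouds:
        return result
    barcode_of = {p.pair_id: p.barcode for p in pairs if p.barcode is not None}
    similar = similarity_sets(index)

    def work(cloud: ReadCloud) -> dict[str, tuple[str, int]]:
        return deconvolve_cloud(cloud, index, barcode_of, seed=seed,
                                similar=similar)

    cloud_list = list(clouds.values())
    if workers > 1 and len(cloud_list) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            partials = list(pool.map(work, cloud_list))
    else:
        partials = [work(c) for c in cloud_list]
    for part in partials:  # cloud key sets are disjoint: merge order-free
        result.labels.update(part)
    return result
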