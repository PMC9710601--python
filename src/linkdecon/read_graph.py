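"""Per-barcode read graphs from shared-k-mer similarity.

Each barcode (*anchor*) is processed separately. For every read pair of the
anchor cloud, all similar pairs in the whole dataset are found — two pairs are
*similar* when they share at least ``min_shared`` distinct indexed canonical
k-mers; no alignment is ever performed. A bipartite structure then links each
anchor pair to the barcodes of its similar pairs, and collapsing it yields a
weighted graph over the anchor cloud: the weight of an edge is the number of
barcodes the two pairs both link to. Reads from the same fragment link to the
barcodes of the fragments overlapping it, so they share many linked barcodes,
while reads from different fragments of the same cloud share almost none —
the graph's clusters are the fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import numpy as np
from scipy import sparse

from .io import ReadCloud, ReadPair
from .kmer_index import KmerIndex

__all__ = [
    "BipartiteLinks",
    "find_similar",
    "similarity_sets",
    "shared_kmer_matrix",
    "build_bipartite",
    "collapse",
]


@dataclass
class BipartiteLinks:
    """Read-to-barcode links for one anchor cloud.

    ``links`` maps each anchor pair_id to the set of barcodes whose reads are
    similar to it; the anchor's own barcode is excluded by default (it carries
    no signal discriminating the cloud's fragments).
    """

    anchor_barcode: str
    links: dict[str, set[str]] = field(default_factory=dict)


def find_similar(
    pair: Union[ReadPair, str],
    index: KmerIndex,
    min_shared: Optional[int] = None,
) -> set[str]:
    """All other pairs sharing >= min_shared distinct indexed k-mers.

    Counts shared k-mer *types* (a k-mer contributes once however often it
    occurs); pruned k-mers contribute nothing. A pair with an empty indexed
    set simply has no similar reads.
    """
    pid = pair.pair_id if isinstance(pair, ReadPair) else pair
    if min_shared is None:
        min_shared = index.params.min_shared
    counts: dict[str, int] = {}
    for code in index.pair_kmers.get(pid, ()):
        for other in index.occurrences.get(code, ()):
            counts[other] = counts.get(other, 0) + 1
    counts.pop(pid, None)
    return {other for other, c in counts.items() if c >= min_shared}


def shared_kmer_matrix(index: KmerIndex) -> tuple[sparse.csr_matrix, list[str]]:
    """Pair-by-pair matrix of shared indexed k-mer counts (sparse, symmetric).

    Computed as M @ M.T with M the binary pair x k-mer incidence matrix;
    the diagonal is zeroed. Row/column order follows ``index.pair_ids``.
    """
    pair_ids = index.pair_ids
    pos = {pid: i for i, pid in enumerate(pair_ids)}
    kmer_col: dict[int, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    for pid, codes in index.pair_kmers.items():
        i = pos[pid]
        for code in codes:
            j = kmer_col.setdefault(code, len(kmer_col))
            rows.append(i)
            cols.append(j)
    m = sparse.csr_matrix(
        (np.ones(len(rows), np.int32), (rows, cols)),
        shape=(len(pair_ids), max(len(kmer_col), 1)),
    )
    s = (m @ m.T).tocsr()
    s.setdiag(0)
    s.eliminate_zeros()
    return s, pair_ids

def similarity_sets(
    index: KmerIndex, min_shared: Optional[int] = None
) -> dict[str, set[str]]:
    """Similar-pair sets for every pair at once (batch form of find_similar).

    Identical to calling :func:`find_similar` per pair, but computed through
    one sparse matrix product; used by the full pipeline.
    """
    if min_shared is None:
        min_shared = index.params.min_shared
    s, pair_ids = shared_kmer_matrix(index)
    s.data[s.data < min_shared] = 0
    s.eliminate_zeros()
    out: dict[str, set[str]] = {}
    indptr, indices = s.indptr, s.indices
    for i, pid in enumerate(pair_ids):
        out[pid] = {pair_ids[j] for j in indices[indptr[i]:indptr[i + 1]]}
    return out


def build_bipartite(
    cloud: ReadCloud,
    index: KmerIndex,
    barcode_of: Mapping[str, str],
    similar: Optional[Mapping[str, set[str]]] = None,
    include_self_barcode: bool = False,
) -> BipartiteLinks:
    """Link every anchor pair to the barcodes of its similar reads.

    ``similar`` may carry precomputed :func:`similarity_sets`; otherwise
    similarity is computed per pair. Pairs absent from the index get empty
    link sets. ``include_self_barcode`` keeps the anchor's own barcode in the
    link sets (off by default).
    """
    links: dict[str, set[str]] = {}
    for pair in cloud.pairs:
        pid = pair.pair_id
        sim = (similar[pid] if similar is not None
               else find_similar(pid, index))
        bcs = {barcode_of[q] for q in sim if q in barcode_of}
        if not include_self_barcode:
            bcs.discard(cloud.barcode)
        links[pid] = bcs
    return BipartiteLinks(anchor_barcode=cloud.barcode, links=links)


def collapse(bipartite: BipartiteLinks) -> nx.Graph:
    """Project the bipartite links onto the anchor reads.

    Returns a weighted undirected graph whose nodes are the anchor pair_ids
    (insertion order preserved); an edge of weight n joins two pairs linking
    to n >= 1 common barcodes.
    """
    graph = nx.Graph(anchor_barcode=bipartite.anchor_barcode)
    pids = list(bipartite.links)
    graph.add_nodes_from(pids)
    for i, p in enumerate(pids):
        lp = bipartite.links[p]
        if not lp:
            continue
        for q in pids[i + 1:]:
            weight = len(lp & bipartite.links[q])
            if weight:
                graph.add_edge(p, q, weight=weight)
    return graph
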