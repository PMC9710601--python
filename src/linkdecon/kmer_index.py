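"""Sparse k-mer indexing with lexicographic-fraction selection.

Overlap detection between reads is done purely through shared k-mers, never by
alignment. To keep the index small, only a fraction *d* of k-mer space is
indexed: a k-mer qualifies at level *m* when its lexicographic rank fraction
(position in the sorted list of all 4^k k-mers, divided by 4^k) is below m*d.
With d = 0.25, level 1 is exactly "k-mers starting with A".

Low-complexity or GC-biased regions may contain no level-1 k-mer at all, so the
indexed fraction escalates locally: for every window of w consecutive bases the
selection level is raised until the window holds at least one selected k-mer.
The escalation is evaluated per *sliding* window over canonical k-mers, which
makes the selected set position-independent: the minimum-rank canonical k-mer
of any w-window is always selected, so two reads sharing w bases of sequence
share at least one indexed k-mer regardless of their relative offsets (the
window guarantee).

Ranking and selection operate on the canonical form (lexicographic minimum of
a k-mer and its reverse complement), making indexing orientation-invariant.
K-mers containing N are never selected. Finally, k-mers occurring far more
often than typical — repeats, which would create hubs of false links — are
de-indexed (:func:`prune_repeats`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .io import ReadPair

__all__ = [
    "IndexParams",
    "KmerIndex",
    "revcomp",
    "canonical",
    "kmer_rank_fraction",
    "sparse_positions",
    "build_index",
    "prune_repeats",
    "decode_kmer",
    "encode_kmer",
]

# Base encoding: A=0, C=1, G=2, T=3 keeps integer order == lexicographic order.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Sentinel escalation level for k-mers containing N: never selected.
_NEVER = np.iinfo(np.int64).max


def revcomp(seq: str) -> str:
    """Reverse complement (N-safe)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode_kmer(kmer: str) -> int:
    """Base-4 integer code of a k-mer (A=0, C=1, G=2, T=3)."""
    code = 0
    for base in kmer:
        value = _CODE[ord(base)]
        if value < 0:
            raise ValueError(f"k-mer contains non-ACGT base: {kmer!r}")
        code = (code << 2) | int(value)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def kmer_rank_fraction(kmer: str) -> float:
    """Lexicographic rank of a k-mer divided by 4^k, in [0, 1).

    The base-4 value of the string over A<C<G<T equals its rank among all 4^k
    k-mers. A k-mer containing N returns ``inf`` ("never selected").
    """
    if any(_CODE[ord(b)] < 0 for b in kmer):
        return math.inf
    return encode_kmer(kmer) / 4 ** len(kmer)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class IndexParams:
    """Tuning knobs of the sparse index.

    k: k-mer length.
    d: base indexed fraction of k-mer space (level m indexes rank < m*d).
    w: window length in bases; every w-stretch of a read holds >= 1 indexed
       k-mer (after escalation).
    repeat_factor: de-index k-mers occurring >= repeat_factor * average.
    min_shared: shared indexed k-mers required to call two reads similar.
    repeat_mean: which average the repeat threshold uses — "occurrence"
       (mean multiplicity of a k-mer *instance*, i.e. coverage-scaled) or
       "kmer" (mean occurrence-list length over distinct indexed k-mers).
    """

    k: int = 20
    d: float = 1 / 8
    w: int = 50
    repeat_factor: float = 2.0
    min_shared: int = 3
    repeat_mean: str = "occurrence"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.d <= 1:
            raise ValueError("d must be in (0, 1]")
        if self.w < self.k:
            raise ValueError("window w must be >= k")
        if self.repeat_factor <= 1:
            raise ValueError("repeat_factor must be > 1")
        if self.min_shared < 1:
            raise ValueError("min_shared must be >= 1")
        if self.repeat_mean not in ("occurrence", "kmer"):
            raise ValueError("repeat_mean must be 'occurrence' or 'kmer'")

    @property
    def max_level(self) -> int:
        """Level at which the indexed fraction reaches 1."""
        return math.ceil(1 / self.d)


# ---------------------------------------------------------------------------
# Sparse selection (vectorised core)
# ---------------------------------------------------------------------------

def _canonical_codes(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for a batch of equal-length encoded sequences.

    ``mat`` is (n_seqs, L) int8 with -1 for non-ACGT. Returns ``(codes, valid)``
    of shape (n_seqs, L-k+1): base-4 canonical codes (int64) and a mask of
    N-free k-mers.
    """
    n, length = mat.shape
    ns = length - k + 1
    if ns <= 0:
        return (np.empty((n, 0), np.int64), np.empty((n, 0), bool))
    m64 = mat.astype(np.int64)
    fwd = np.zeros((n, ns), np.int64)
    rc = np.zeros((n, ns), np.int64)
    for j in range(k):
        col = m64[:, j:j + ns]
        fwd = (fwd << 2) | (col & 3)
        rc |= ((3 - col) & 3) << (2 * j)
    bad = (mat < 0).astype(np.int32)
    csum = np.zeros((n, length + 1), np.int32)
    np.cumsum(bad, axis=1, out=csum[:, 1:])
    valid = (csum[:, k:] - csum[:, :-k]) == 0
    return np.minimum(fwd, rc), valid


def _selection_levels(codes: np.ndarray, valid: np.ndarray,
                      params: IndexParams) -> np.ndarray:
    """Escalation level needed for each k-mer (``_NEVER`` where invalid)."""
    frac = codes / float(4 ** params.k)
    levels = np.floor(frac / params.d).astype(np.int64) + 1
    np.clip(levels, 1, params.max_level, out=levels)
    levels[~valid] = _NEVER
    return levels


def _select(levels: np.ndarray, params: IndexParams) -> np.ndarray:
    """Window-escalated selection mask for a batch of level matrices.

    For every sliding window of W = w-k+1 k-mer starts, the minimal level m
    making the window non-empty is found; a position is selected iff its own
    level is <= the largest such m over all windows covering it. Every window
    with at least one N-free k-mer therefore contains a selected position, and
    in particular its minimum-rank canonical k-mer is always selected.
    """
    n, ns = levels.shape
    if ns == 0:
        return np.zeros((n, 0), bool)
    W = max(1, params.w - params.k + 1)
    if ns <= W:
        wmin = levels.min(axis=1, keepdims=True)
        wmin[wmin == _NEVER] = 0
        thresh = np.broadcast_to(wmin, levels.shape)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(levels, W, axis=1)
        wmin = windows.min(axis=2)  # (n, ns - W + 1)
        wmin = np.where(wmin == _NEVER, 0, wmin)  # all-N windows demand nothing
        padded = np.zeros((n, wmin.shape[1] + 2 * (W - 1)), np.int64)
        padded[:, W - 1:W - 1 + wmin.shape[1]] = wmin
        thresh = np.lib.stride_tricks.sliding_window_view(
            padded, W, axis=1).max(axis=2)  # (n, ns)
    return levels <= thresh


def _encode_seqs(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) int8 matrix."""
    joined = "".join(seqs)
    arr = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    return _CODE[arr].reshape(len(seqs), -1)


def sparse_positions(
    seq: str, params: IndexParams
) -> list[tuple[int, str, int]]:
    """Selected positions of one sequence: ``(position, canonical k-mer, level)``.

    The level is the escalation level the k-mer's rank fraction demands
    (rank < level*d). Sequences shorter than k yield an empty list.
    """
    if len(seq) < params.k:
        return []
    mat = _encode_seqs([seq])
    codes, valid = _canonical_codes(mat, params.k)
    levels = _selection_levels(codes, valid, params)
    sel = _select(levels, params)[0]
    return [
        (int(i), decode_kmer(int(codes[0, i]), params.k), int(levels[0, i]))
        for i in np.flatnonzero(sel)
    ]


def _sparse_codes_batch(
    seqs: Sequence[str], params: IndexParams, chunk: int = 4096
) -> list[np.ndarray]:
    """Selected canonical codes per sequence, vectorised over length groups."""
    out: list[Optional[np.ndarray]] = [None] * len(seqs)
    empty = np.empty(0, np.int64)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        if len(s) < params.k:
            out[i] = empty
        else:
            by_len.setdefault(len(s), []).append(i)
    for _, idxs in by_len.items():
        for lo in range(0, len(idxs), chunk):
            batch = idxs[lo:lo + chunk]
            mat = _encode_seqs([seqs[i] for i in batch])
            codes, valid = _canonical_codes(mat, params.k)
            levels = _selection_levels(codes, valid, params)
            sel = _select(levels, params)
            for row, i in enumerate(batch):
                out[i] = codes[row, sel[row]]
    return out  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# The index
# ---------------------------------------------------------------------------

@dataclass
class KmerIndex:
    """Occurrence dictionary of sparse canonical k-mers across read pairs.

    Indexing is per *pair*: both mates' selected k-mers are pooled into one
    set, so one indexable mate suffices to anchor the pair. ``occurrences``
    maps each indexed canonical k-mer code to the pair_ids carrying it (input
    order); ``mean_occurrence`` is the mean list length over distinct indexed
    k-mers and ``occurrence_weighted_mean`` the mean multiplicity of a k-mer
    instance (sum occ^2 / sum occ). Both are frozen before pruning.
    """

    params: IndexParams
    pair_ids: list[str]
    pair_kmers: dict[str, set[int]]
    occurrences: dict[int, list[str]]
    mean_occurrence: float
    occurrence_weighted_mean: float
    pruned: set[int] = field(default_factory=set)

    def indexed_kmers(self, pair_id: str) -> set[str]:
        """Decoded indexed k-mer set of one pair (convenience accessor)."""
        k = self.params.k
        return {decode_kmer(c, k) for c in self.pair_kmers[pair_id]}


def build_index(
    pairs: Sequence[ReadPair], params: Optional[IndexParams] = None
) -> KmerIndex:
    """Build the sparse k-mer occurrence index over all read pairs.

    Deterministic and independent of pair processing order (occurrence lists
    follow the input order of ``pairs``).
    """
    params = params or IndexParams()
    if len(pairs) == 0:
        raise ValueError("cannot index an empty pair collection")
    seqs: list[str] = []
    owner: list[int] = []
    for i, pair in enumerate(pairs):
        for seq in pair.sequences:
            seqs.append(seq)
            owner.append(i)
    per_seq = _sparse_codes_batch(seqs, params)

    pair_ids = [p.pair_id for p in pairs]
    pair_kmers: dict[str, set[int]] = {pid: set() for pid in pair_ids}
    for codes, i in zip(per_seq, owner):
        pair_kmers[pair_ids[i]].update(int(c) for c in codes)

    occurrences: dict[int, list[str]] = {}
    for pid in pair_ids:
        for code in pair_kmers[pid]:
            occurrences.setdefault(code, []).append(pid)

    if occurrences:
        counts = np.array([len(v) for v in occurrences.values()], np.int64)
        mean_occ = float(counts.mean())
        weighted = float((counts * counts).sum() / counts.sum())
    else:
        mean_occ = weighted = 0.0
    return KmerIndex(
        params=params,
        pair_ids=pair_ids,
        pair_kmers=pair_kmers,
        occurrences=occurrences,
        mean_occurrence=mean_occ,
        occurrence_weighted_mean=weighted,
        pruned=set(),
    )


def prune_repeats(index: KmerIndex) -> KmerIndex:
    """De-index repeat k-mers occurring >= repeat_factor * average.

    Repeats link reads that are far apart on the genome, creating hubs of false
    edges; removing them costs a few unindexable reads in repeated regions but
    greatly cleans the graph. The average is frozen at its pre-pruning value.
    With ``repeat_mean="occurrence"`` (default) the reference average is the
    occurrence-weighted mean, which sits on the coverage scale so the threshold
    reads "more than twice the typical multiplicity"; ``"kmer"`` uses the plain
    mean list length over distinct k-mers. Modifies the index in place and
    returns it.
    """
    mean = (index.occurrence_weighted_mean
            if index.params.repeat_mean == "occurrence"
            else index.mean_occurrence)
    threshold = index.params.repeat_factor * mean
    doomed = [c for c, occ in index.occurrences.items()
              if len(occ) >= threshold]
    for code in doomed:
        for pid in index.occurrences.pop(code):
            index.pair_kmers[pid].discard(code)
        index.pruned.add(code)
    return index
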