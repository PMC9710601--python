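"""Sparse k-mer selection: ranking, window escalation, index, repeat pruning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import linkdecon as ld
from linkdecon.kmer_index import IndexParams, KmerIndex, decode_kmer, encode_kmer

DNA = st.text(alphabet="ACGT", min_size=25, max_size=200)


# ---------------------------------------------------------------------------
# Rank fraction
# ---------------------------------------------------------------------------

def test_rank_fraction_examples():
    assert ld.kmer_rank_fraction("A" * 20) == 0.0
    assert ld.kmer_rank_fraction("CG") == 0.375
    assert math.isinf(ld.kmer_rank_fraction("ACGTN"))


def test_rank_fraction_matches_enumeration():
    # oracle: position in the explicitly sorted list of all 4^3 3-mers
    all3 = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
    for i, kmer in enumerate(sorted(all3)):
        assert ld.kmer_rank_fraction(kmer) == i / 64


def test_kmers_starting_with_A_are_first_quarter():
    for kmer in ("AAAA", "ACGT", "ATTT", "AGCA"):
        assert ld.kmer_rank_fraction(kmer) < 0.25
    for kmer in ("CAAA", "GGGG", "TACG"):
        assert ld.kmer_rank_fraction(kmer) >= 0.25


def test_encode_decode_roundtrip():
    for kmer in ("ACGTACGTACGTACGTACGT", "TTTT", "A"):
        assert decode_kmer(encode_kmer(kmer), len(kmer)) == kmer


def test_canonical_is_min_of_strands():
    assert ld.canonical("TTTTT") == "AAAAA"
    assert ld.canonical("ACGTA") == min("ACGTA", ld.revcomp("ACGTA"))


# ---------------------------------------------------------------------------
# Sparse selection
# ---------------------------------------------------------------------------

def test_minimum_rank_sequence_fully_selected_at_level_1():
    out = ld.sparse_positions("A" * 150, IndexParams())
    assert len(out) == 131
    assert all(kmer == "A" * 20 and level == 1 for _, kmer, level in out)


def test_full_density_selects_every_nfree_kmer():
    seq = "ACGTTGCA" * 20
    out = ld.sparse_positions(seq, IndexParams(d=1.0))
    assert [pos for pos, _, _ in out] == list(range(len(seq) - 19))


def test_homopolymer_G_escalates_but_stays_covered():
    # canonical(G^20) = C^20, rank 0.25 -> needs level 3 at d = 1/8
    out = ld.sparse_positions("G" * 150, IndexParams())
    assert all(level == 3 for _, _, level in out)
    assert len(out) == 131  # whole-sequence single bucket: all selected


def test_short_sequence_yields_empty():
    assert ld.sparse_positions("ACGT", IndexParams()) == []


def _window_guarantee_holds(seq, params):
    """Brute-force check: every w-stretch holding a complete N-free k-mer
    contains a selected k-mer start, and each window's minimum-rank canonical
    k-mer is selected."""
    out = ld.sparse_positions(seq, params)
    selected = {pos for pos, _, _ in out}
    n_starts = len(seq) - params.k + 1
    W = max(1, params.w - params.k + 1)
    ranks = []
    for i in range(n_starts):
        kmer = seq[i:i + params.k]
        ranks.append(ld.kmer_rank_fraction(ld.canonical(kmer))
                     if "N" not in kmer else math.inf)
    for lo in range(max(1, n_starts - W + 1)):
        window = range(lo, min(lo + W, n_starts))
        finite = [i for i in window if math.isfinite(ranks[i])]
        if not finite:
            continue
        if not selected & set(window):
            return False
        best = min(finite, key=lambda i: ranks[i])
        if ranks[best] < min(ranks[i] for i in selected & set(window)):
            return False
    return True


@settings(max_examples=60, deadline=None, derandomize=True)
@given(DNA)
def test_window_guarantee_random_sequences(seq):
    assert _window_guarantee_holds(seq, IndexParams(k=11, w=20))


def test_window_guarantee_with_N_runs():
    seq = "G" * 40 + "N" * 30 + "T" * 60 + "N" + "ACGT" * 10
    params = IndexParams(k=11, w=20)
    assert _window_guarantee_holds(seq, params)
    # no selected k-mer may contain N
    for pos, kmer, _ in ld.sparse_positions(seq, params):
        assert "N" not in seq[pos:pos + params.k]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(DNA)
def test_orientation_invariance(seq):
    params = IndexParams(k=11, w=20)
    fwd = {kmer for _, kmer, _ in ld.sparse_positions(seq, params)}
    rev = {kmer for _, kmer, _ in ld.sparse_positions(ld.revcomp(seq), params)}
    assert fwd == rev


# ---------------------------------------------------------------------------
# Index construction
# ---------------------------------------------------------------------------

def _pair(pid, seq1, seq2=None):
    qual = "I" * len(seq1)
    mate1 = ld.LinkedRead(pid, 1, seq1, qual, "BC")
    mate2 = (ld.LinkedRead(pid, 2, seq2, "I" * len(seq2), "BC")
             if seq2 else None)
    return ld.ReadPair(pid, mate1, mate2, "BC")


def test_identical_pairs_share_all_kmers():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 150))
    index = ld.build_index([_pair("a", seq), _pair("b", seq)], IndexParams())
    assert index.pair_kmers["a"] == index.pair_kmers["b"]
    assert all(occ == ["a", "b"] for occ in index.occurrences.values())
    assert ld.build_index([_pair("solo", seq)]).mean_occurrence == 1.0


def test_full_density_index_covers_every_substring():
    rng = np.random.default_rng(1)
    region = "".join(rng.choice(list("ACGT"), 2000))
    pairs = [_pair(f"p{i}", region[i * 185:i * 185 + 150]) for i in range(10)]
    index = ld.build_index(pairs, IndexParams(d=1.0))
    for i in range(10):
        for j in range(131):
            kmer = region[i * 185 + j:i * 185 + j + 20]
            assert encode_kmer(ld.canonical(kmer)) in index.occurrences


def test_index_independent_of_pair_order():
    rng = np.random.default_rng(2)
    pairs = [_pair(f"p{i}", "".join(rng.choice(list("ACGT"), 150)))
             for i in range(20)]
    a = ld.build_index(pairs, IndexParams())
    b = ld.build_index(pairs[::-1], IndexParams())
    assert a.pair_kmers == b.pair_kmers
    assert {k: set(v) for k, v in a.occurrences.items()} == \
           {k: set(v) for k, v in b.occurrences.items()}
    assert a.mean_occurrence == b.mean_occurrence


def test_pair_pools_both_mates():
    rng = np.random.default_rng(3)
    s1 = "".join(rng.choice(list("ACGT"), 150))
    s2 = "".join(rng.choice(list("ACGT"), 150))
    paired = ld.build_index([_pair("p", s1, s2)], IndexParams(d=1.0))
    split = ld.build_index([_pair("a", s1), _pair("b", s2)], IndexParams(d=1.0))
    assert paired.pair_kmers["p"] == split.pair_kmers["a"] | split.pair_kmers["b"]


# ---------------------------------------------------------------------------
# Repeat pruning
# ---------------------------------------------------------------------------

def _toy_index(counts, repeat_mean):
    """Index with len(counts) k-mers, k-mer i occurring counts[i] times."""
    params = IndexParams(repeat_mean=repeat_mean)
    occurrences = {i: [f"p{i}_{j}" for j in range(c)]
                   for i, c in enumerate(counts)}
    pair_kmers = {}
    for code, occ in occurrences.items():
        for pid in occ:
            pair_kmers.setdefault(pid, set()).add(code)
    arr = np.array(counts, float)
    return KmerIndex(params=params, pair_ids=sorted(pair_kmers),
                     pair_kmers=pair_kmers, occurrences=occurrences,
                     mean_occurrence=float(arr.mean()),
                     occurrence_weighted_mean=float((arr ** 2).sum() / arr.sum()))


def test_prune_nothing_when_all_counts_equal():
    index = ld.prune_repeats(_toy_index([1] * 10, "kmer"))
    assert index.pruned == set()
    assert len(index.occurrences) == 10


def test_prune_hub_kmer_against_plain_mean():
    # nine singletons + one 11x k-mer: mean 2.0, threshold 4 -> hub pruned
    index = _toy_index([1] * 9 + [11], "kmer")
    assert index.mean_occurrence == 2.0
    ld.prune_repeats(index)
    assert index.pruned == {9}
    assert 9 not in index.occurrences and len(index.occurrences) == 9
    assert all(9 not in s for s in index.pair_kmers.values())
    assert index.mean_occurrence == 2.0  # frozen pre-pruning value


def test_occurrence_weighted_mean_ignores_error_singletons():
    # same counts, occurrence-weighted mean (9+121)/20 = 6.5, threshold 13:
    # the 11x k-mer survives — singleton noise no longer drags the average
    index = _toy_index([1] * 9 + [11], "occurrence")
    assert index.occurrence_weighted_mean == pytest.approx(6.5)
    ld.prune_repeats(index)
    assert index.pruned == set()


def test_huge_repeat_factor_prunes_nothing():
    index = _toy_index([1] * 5 + [100], "kmer")
    index.params.repeat_factor = 1e9
    ld.prune_repeats(index)
    assert index.pruned == set()


def test_param_validation():
    with pytest.raises(ValueError):
        IndexParams(d=0)
    with pytest.raises(ValueError):
        IndexParams(w=10, k=20)
    with pytest.raises(ValueError):
        IndexParams(repeat_mean="median")
    with pytest.raises(ValueError):
        ld.build_index([], IndexParams())
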