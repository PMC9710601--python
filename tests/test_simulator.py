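"""Simulator: pseudo-diploid construction, read placement, ground truth."""

import math

import numpy as np
import pytest
from scipy import stats

import linkdecon as ld


def test_random_genome_composition():
    g = ld.random_genome(1000, gc=0.5, seed=1)["chr1"]
    gc = sum(b in "GC" for b in g)
    assert abs(gc - 500) <= 47  # 3 sd of Binomial(1000, 0.5)
    assert set(ld.random_genome(500, gc=0.0, seed=2)["chr1"]) <= {"A", "T"}
    assert ld.random_genome(300, seed=3) == ld.random_genome(300, seed=3)


def test_pseudo_diploid_divergence():
    g = ld.random_genome(100_000, seed=4)
    same = ld.make_pseudo_diploid(g, 0.0, seed=5)
    assert same["chr1_hap2"] == g["chr1"]
    dip = ld.make_pseudo_diploid(g, 0.01, seed=6)
    diffs = sum(a != b for a, b in zip(dip["chr1"], dip["chr1_hap2"]))
    # 3 sd of Binomial(1e5, 0.01)
    assert abs(diffs - 1000) <= 3 * math.sqrt(100_000 * 0.01 * 0.99)
    with pytest.raises(ValueError):
        ld.make_pseudo_diploid({}, 0.01)


@pytest.fixture(scope="module")
def medium_sim():
    genome = ld.random_genome(1_000_000, seed=7)
    # fragments small relative to the genome so end-clipping losses stay small
    params = ld.SimParams(frag_len_min=20_000, frag_len_max=40_000, seed=8)
    return genome, params, ld.simulate_linked_reads(genome, params)


def test_fragment_and_barcode_counts(medium_sim):
    genome, params, (pairs, truth, frags) = medium_sim
    mean_frag = (params.frag_len_min + params.frag_len_max) / 2
    expected = math.ceil(params.read_coverage * 1_000_000
                         / (params.per_fragment_coverage * mean_frag))
    assert len(frags) == expected
    allocated = max(1, round(len(frags) / params.fragments_per_barcode))
    n_used = len({f.barcode for f in frags})
    # uniform assignment leaves a few barcodes unused (occupancy ~ 1 - e^-n)
    assert 0.95 * allocated <= n_used <= allocated


def test_realized_coverage_within_5pct(medium_sim):
    genome, params, (pairs, truth, frags) = medium_sim
    read_bases = len(pairs) * 2 * params.read_len
    realized = read_bases / 1_000_000
    assert abs(realized - params.read_coverage) / params.read_coverage < 0.05


def test_fragment_starts_uniform(medium_sim):
    _, _, (_, _, frags) = medium_sim
    starts = np.array([f.start for f in frags])
    assert len(starts) >= 1000
    counts, _ = np.histogram(starts, bins=10, range=(0, 1_000_000))
    assert stats.chisquare(counts).pvalue > 0.001


def test_truth_covers_every_pair_once(medium_sim):
    _, _, (pairs, truth, frags) = medium_sim
    assert truth["pair_id"].is_unique
    assert set(truth["pair_id"]) == {p.pair_id for p in pairs}
    from_frags = [pid for f in frags for pid in f.read_pair_ids]
    assert sorted(from_frags) == sorted(truth["pair_id"])


def test_pairs_per_fragment_matches_covered_fraction():
    genome = ld.random_genome(300_000, seed=9)
    params = ld.SimParams(frag_len_min=100_000, frag_len_max=100_000, seed=10)
    _, _, frags = ld.simulate_linked_reads(genome, params)
    full = [f for f in frags if not f.clipped]
    # 15% of 100 kb divided by 300 read bases per pair -> 50 pairs
    assert all(len(f.read_pair_ids) == 50 for f in full)


def test_error_free_reads_are_genome_substrings():
    genome = ld.random_genome(40_000, seed=11)
    params = ld.SimParams(frag_len_min=5000, frag_len_max=8000,
                          error_rate=0.0, read_coverage=2.0, seed=12)
    pairs, truth, frags = ld.simulate_linked_reads(genome, params)
    seq = genome["chr1"]
    by_id = {p.pair_id: p for p in pairs}
    for frag in frags[:20]:
        for pid, start in zip(frag.read_pair_ids, frag.read_starts):
            pair = by_id[pid]
            assert pair.mate1.sequence == seq[start:start + 150]
            assert ld.revcomp(pair.mate2.sequence) == seq[start + 150:start + 300]


def test_same_seed_reproduces_byte_identical_output(tmp_path):
    genome = ld.random_genome(30_000, seed=13)
    params = ld.SimParams(frag_len_min=4000, frag_len_max=6000,
                          read_coverage=5.0, seed=14)
    pairs_a, truth_a, _ = ld.simulate_linked_reads(genome, params)
    pairs_b, truth_b, _ = ld.simulate_linked_reads(genome, params)
    assert [(p.pair_id, p.mate1.sequence, p.mate2.sequence, p.barcode)
            for p in pairs_a] == \
           [(p.pair_id, p.mate1.sequence, p.mate2.sequence, p.barcode)
            for p in pairs_b]
    assert truth_a.equals(truth_b)
    path = tmp_path / "truth.tsv"
    ld.write_truth(truth_a, path)
    assert ld.read_truth(path).equals(truth_a)


def test_param_validation_errors():
    with pytest.raises(ValueError):
        ld.SimParams(per_fragment_coverage=0.0)
    with pytest.raises(ValueError):
        ld.SimParams(error_rate=1.0)
    with pytest.raises(ValueError):
        ld.SimParams(frag_len_min=100, frag_len_max=50)
    with pytest.raises(ValueError):
        ld.simulate_linked_reads({}, ld.SimParams())
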