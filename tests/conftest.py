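"""Shared fixtures: small simulated datasets and planted-partition instances.

All fixtures are generated programmatically at test time; nothing is read from
disk. Session scope keeps the expensive simulations shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import linkdecon as ld


@pytest.fixture(scope="session")
def small_errorfree_sim():
    """~200 error-free read pairs on a 30 kb genome, for brute-force oracles."""
    genome = ld.random_genome(30_000, seed=101)
    params = ld.SimParams(frag_len_min=4000, frag_len_max=6000,
                          error_rate=0.0, read_coverage=2.0, seed=102)
    pairs, truth, frags = ld.simulate_linked_reads(genome, params)
    assert len(pairs) <= 220
    return genome, params, pairs, truth, frags


@pytest.fixture(scope="session")
def small_noisy_sim():
    """A small noisy pseudo-diploid dataset (~4k pairs) for pipeline tests."""
    genome = ld.make_pseudo_diploid(ld.random_genome(12_000, seed=201),
                                    0.01, seed=202)
    params = ld.SimParams(frag_len_min=2000, frag_len_max=3000,
                          error_rate=0.01, seed=203)
    pairs, truth, frags = ld.simulate_linked_reads(genome, params)
    index = ld.prune_repeats(ld.build_index(pairs, ld.IndexParams()))
    clouds = ld.group_into_clouds(pairs)
    return pairs, truth, frags, index, clouds


def planted_instances(seed: int, genome_len: int = 120_000,
                      frag_min: int = 8000, frag_max: int = 12_000,
                      p: float = 0.75, n_clouds: int = 15):
    """Planted-partition clouds with 2-4 well-separated fragments each.

    The background emulates the realistic linked-read regime (N_tot >= 1e6,
    hence far-fragment barcode collisions ~ 0) by giving every background
    fragment its own barcode, while preserving the full protocol's ~25 read
    pairs per fragment (read coverage 50). Planted clouds merge F fragments
    whose intervals are pairwise separated by more than one fragment length,
    so no background fragment can bridge them.

    Returns ``(index, similar, instances)`` where each instance is
    ``(cloud, barcode_of, true_fragment_labels)``.
    """
    genome = ld.random_genome(genome_len, seed=seed)
    params = ld.SimParams(frag_len_min=frag_min, frag_len_max=frag_max,
                          error_rate=0.0, per_fragment_coverage=p,
                          fragments_per_barcode=1, seed=seed + 10_000)
    pairs, truth, frags = ld.simulate_linked_reads(genome, params)
    index = ld.prune_repeats(ld.build_index(pairs, ld.IndexParams()))
    similar = ld.similarity_sets(index)
    frag_of = dict(zip(truth["pair_id"], truth["fragment_id"]))
    background = {pid: f"BG{f}" for pid, f in frag_of.items()}
    by_id = {pair.pair_id: pair for pair in pairs}
    rng = np.random.default_rng(seed + 20_000)
    frag_list = [f for f in frags if not f.clipped and len(f.read_pair_ids) > 1]

    def separated(a, b):
        return a.end + frag_max <= b.start or b.end + frag_max <= a.start

    instances = []
    used: set[int] = set()
    for t in range(n_clouds):
        n_frag = 2 + t % 3
        chosen = []
        for i in rng.permutation(len(frag_list)):
            frag = frag_list[i]
            if frag.fragment_id in used:
                continue
            if all(separated(frag, c) for c in chosen):
                chosen.append(frag)
            if len(chosen) == n_frag:
                break
        if len(chosen) < n_frag:
            continue
        barcode = f"PLANT{t}"
        cloud = ld.ReadCloud(barcode=barcode)
        barcode_of = dict(background)
        true_labels = []
        for frag in chosen:
            used.add(frag.fragment_id)
            for pid in frag.read_pair_ids:
                barcode_of[pid] = barcode
                true_labels.append(frag.fragment_id)
                cloud.pairs.append(by_id[pid])
        instances.append((cloud, barcode_of, true_labels))
    return index, similar, instances
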