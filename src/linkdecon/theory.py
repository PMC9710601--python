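"""Expected shared-barcode model.

Why does the read graph separate fragments at all? Consider fragments of
length L drawn uniformly across the genome, a fraction p of each fragment
covered by reads, read coverage c (hence fragment coverage c/p), N_tot
distinct barcodes and on average n fragments per barcode.

Two reads from the *same* fragment, distant by l < L along the strand, overlap
on average

    p1 = ((L - l) / L) * (c/p - 1)

common fragments. Two reads with the same barcode but from two *far-away*
fragments overlap on average

    p2 = (c/p) * (c/p) * (n - 1) / (n * N_tot - c/p)

common fragments: the first read overlaps ~c/p fragments carrying ~c/p
distinct barcodes, each such barcode tags n-1 other fragments among the
n*N_tot - c/p far-away ones, and the second read samples ~c/p of those.

If P is the probability that a read of a common overlapping fragment overlaps
a given read, both expectations are multiplied by P^2 when counting shared
*overlapped barcodes*, so the ratio p1/p2 is P-free. In realistic linked-read
regimes (N_tot >= 1e6, c/p <= 1e3) p1 >> p2: reads of one fragment share far
more barcodes with each other than with the cloud's other fragments, which is
the signal the clustering exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TheoryParams",
    "expected_common_same_fragment",
    "expected_common_far_fragments",
    "empirical_shared_barcodes",
]


@dataclass
class TheoryParams:
    """Parameters of the expected-overlap model (see module docstring)."""

    L: float            # fragment length (bp)
    l: float = 0.0      # intra-fragment distance between the two reads (bp)
    c: float = 50.0     # read coverage (fold)
    p: float = 0.15     # fraction of each fragment covered by reads
    n: float = 4.0      # mean fragments per barcode
    N_tot: float = 1e6  # total number of distinct barcodes
    P: float = 1.0      # read-level overlap probability (ratios are P-free)

    def __post_init__(self) -> None:
        if not 0 <= self.l <= self.L:
            raise ValueError("need 0 <= l <= L")
        if self.c <= 0 or not 0 < self.p <= 1:
            raise ValueError("need c > 0 and 0 < p <= 1")
        if self.n < 1 or self.N_tot < 1:
            raise ValueError("need n >= 1 and N_tot >= 1")


def expected_common_same_fragment(params: TheoryParams) -> float:
    """Expected overlapping fragments p1 for two reads of one fragment.

    Multiply by P^2 to get expected shared overlapped barcodes. Decreases
    linearly in the intra-fragment distance l and vanishes at l = L.
    """
    return (params.L - params.l) / params.L * (params.c / params.p - 1)


def expected_common_far_fragments(params: TheoryParams) -> float:
    """Expected overlapping fragments p2 for same-barcode, far-away reads."""
    cp = params.c / params.p
    denom = params.n * params.N_tot - cp
    if denom <= 0:
        raise ValueError("need n * N_tot > c/p")
    return cp * cp * (params.n - 1) / denom


def empirical_shared_barcodes(
    links: Mapping[str, "object"],
    truth: pd.DataFrame,
    max_pairs_per_cloud: int = 50,
) -> tuple[float, float, int, int]:
    """Measure shared overlapped-barcode counts on simulated data.

    ``links`` maps barcode -> BipartiteLinks (read-to-barcode link sets per
    anchor cloud); ``truth`` is the simulator's ground-truth table. For every
    unordered pair of reads within a cloud the number of shared linked barcodes
    is recorded, split into *same-fragment* pairs and *far* pairs (different
    fragments whose intervals do not overlap, haplotype homology included:
    ``name`` and ``name_hap2`` share a coordinate system). Returns
    ``(mean_same, mean_far, n_same, n_far)`` — the empirical counterparts of
    p1*P^2 and p2*P^2.
    """
    frag_of = dict(zip(truth["pair_id"], truth["fragment_id"]))
    frag_rows = truth.drop_duplicates("fragment_id").set_index("fragment_id")

    def interval(fid):
        row = frag_rows.loc[fid]
        name = str(row["sequence"])
        base = name[:-5] if name.endswith("_hap2") else name
        return base, int(row["start"]), int(row["end"])

    same: list[int] = []
    far: list[int] = []
    for barcode, bip in links.items():
        pids = [p for p in bip.links if p in frag_of]
        pids = pids[:max_pairs_per_cloud]
        for i in range(len(pids)):
            fi = frag_of[pids[i]]
            ci, si, ei = interval(fi)
            for j in range(i + 1, len(pids)):
                fj = frag_of[pids[j]]
                shared = len(bip.links[pids[i]] & bip.links[pids[j]])
                if fi == fj:
                    same.append(shared)
                else:
                    cj, sj, ej = interval(fj)
                    if ci != cj or ei <= sj or ej <= si:
                        far.append(shared)
    mean_same = float(np.mean(same)) if same else float("nan")
    mean_far = float(np.mean(far)) if far else 0.0
    return mean_same, mean_far, len(same), len(far)
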