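"""Synthetic linked-read data with ground truth.

Emulates a 10x-style library preparation over a known genome: long fragments
(default 70–130 kb, uniform) are drawn uniformly across the genome, a fraction
*p* (default 15%) of each fragment is covered by 150 bp paired-end reads with
1% substitution error, and barcodes are assigned uniformly at random with (on
average) *n* = 4 fragments per barcode. Enough fragments are drawn to reach a
target read coverage (default 50x). A "pseudo-diploid" genome — the genome
plus a copy diverged by ~1% of positions — mimics a diploid sample whose
haplotypes deconvolution should keep apart.

The ground truth (which fragment every read pair came from) is emitted as a
table, which downstream evaluation treats as the reference solution.

Modelling choices kept deliberately simple: read-pair starts are uniform within
the fragment with no overlap enforcement; the insert is fixed at 2*read_len
(mate2 is the reverse complement of the read_len bases following mate1);
errors are substitutions only; quality strings are constant ``I`` (the
deconvolution algorithm never reads qualities). Fragments clipped at sequence
ends are kept and flagged rather than redrawn, preserving uniformity of starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .io import LinkedRead, ReadPair

__all__ = [
    "SimParams",
    "FragmentTruth",
    "random_genome",
    "make_pseudo_diploid",
    "simulate_linked_reads",
    "read_fasta",
    "write_fasta",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

TRUTH_COLUMNS = ["pair_id", "fragment_id", "sequence", "start", "end", "barcode"]


@dataclass
class SimParams:
    """Simulation protocol parameters (defaults: the E. coli-style protocol)."""

    genome_length: int = 1_000_000  # used only when generating a random genome
    divergence: float = 0.01        # haplotype divergence of the pseudo-diploid
    frag_len_min: int = 70_000
    frag_len_max: int = 130_000
    per_fragment_coverage: float = 0.15   # p: fraction of fragment under reads
    read_len: int = 150
    error_rate: float = 0.01
    read_coverage: float = 50.0           # c: genome-wide read coverage
    fragments_per_barcode: int = 4        # n: barcodes = fragments / n
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.per_fragment_coverage <= 1:
            raise ValueError("per_fragment_coverage must be in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.frag_len_min > self.frag_len_max:
            raise ValueError("frag_len_min must be <= frag_len_max")
        if self.frag_len_min <= 0 or self.read_len <= 0:
            raise ValueError("lengths must be positive")
        if self.read_coverage <= 0:
            raise ValueError("read_coverage must be positive")
        if self.fragments_per_barcode < 1:
            raise ValueError("fragments_per_barcode must be >= 1")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")


@dataclass
class FragmentTruth:
    """One simulated fragment and the read pairs it generated."""

    fragment_id: int
    sequence_name: str
    start: int  # 0-based, half-open
    end: int
    barcode: str
    read_pair_ids: list[str] = field(default_factory=list)
    clipped: bool = False  # True when truncated at a sequence end
    read_starts: list[int] = field(default_factory=list)  # pair start positions
    # (aligned with read_pair_ids; mate1 covers [s, s+read_len), mate2 is the
    # reverse complement of [s+read_len, s+2*read_len))


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def random_genome(length: int, gc: float = 0.5, seed: int = 0,
                  name: str = "chr1") -> dict[str, str]:
    """I.i.d. random sequence with P(G or C) = gc, deterministic under seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=length, p=probs)
    return {name: _BASES[codes].tobytes().decode("ascii")}


def make_pseudo_diploid(genome: dict[str, str], divergence: float = 0.01,
                        seed: int = 0) -> dict[str, str]:
    """Duplicate each sequence with i.i.d. substitutions at rate ``divergence``.

    Each base of the copy is replaced (by a uniformly chosen *different* base)
    independently with probability ``divergence``; copies are named
    ``<name>_hap2``. Mimics a diploid sample with heterozygosity = divergence.
    """
    if not genome:
        raise ValueError("empty genome")
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = dict(genome)
    for name, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        codes = _CODE[arr]
        hit = (rng.random(len(arr)) < divergence) & (codes >= 0)
        shift = rng.integers(1, 4, size=int(hit.sum()))
        new = (codes[hit] + shift) % 4
        arr[hit] = _BASES[new]
        out[f"{name}_hap2"] = arr.tobytes().decode("ascii")
    return out


def read_fasta(path) -> dict[str, str]:
    import gzip
    handle = gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)
    with handle:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    import gzip
    handle = (gzip.open(path, "wt") if str(path).endswith(".gz")
              else open(path, "w"))
    with handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _mutate(codes: np.ndarray, rate: float, rng) -> np.ndarray:
    """Substitute each base (to a different one) with probability ``rate``."""
    if rate <= 0:
        return codes
    hit = rng.random(codes.shape) < rate
    shift = rng.integers(1, 4, size=codes.shape)
    return np.where(hit, (codes + shift) % 4, codes)


def _random_barcodes(count: int, rng, length: int = 16) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < count:
        bc = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_linked_reads(
    genome: dict[str, str], params: Optional[SimParams] = None
) -> tuple[list[ReadPair], pd.DataFrame, list[FragmentTruth]]:
    """Simulate a linked-read dataset over ``genome`` with ground truth.

    Fragment count = ceil(read_coverage * genome_length / (p * mean fragment
    length)), so that realised read coverage matches ``read_coverage``; barcode
    count = fragment count / fragments_per_barcode, assigned uniformly.
    Returns ``(pairs, truth, fragments)`` where ``truth`` has one row per read
    pair (columns pair_id, fragment_id, sequence, start, end, barcode; fragment
    coordinates 0-based half-open).
    """
    params = params or SimParams()
    if not genome:
        raise ValueError("empty genome")
    rng = np.random.default_rng(params.seed)
    names = list(genome)
    arrays = {n: _CODE[np.frombuffer(genome[n].encode("ascii"), np.uint8)]
              for n in names}
    lengths = np.array([len(genome[n]) for n in names], dtype=np.int64)
    total_len = int(lengths.sum())
    mean_frag = (params.frag_len_min + params.frag_len_max) / 2
    if total_len < params.frag_len_max:
        import warnings
        warnings.warn(
            "genome shorter than frag_len_max; fragments will be clipped",
            stacklevel=2,
        )
    n_frag = math.ceil(
        params.read_coverage * total_len
        / (params.per_fragment_coverage * mean_frag)
    )
    n_bc = max(1, round(n_frag / params.fragments_per_barcode))
    barcodes = _random_barcodes(n_bc, rng)

    # Fragment placement: chromosome chosen by length, start uniform, length
    # uniform in [min, max], clipped (and flagged) at chromosome ends.
    seq_idx = rng.choice(len(names), size=n_frag, p=lengths / total_len)
    starts = rng.integers(0, lengths[seq_idx])
    frag_lens = rng.integers(params.frag_len_min, params.frag_len_max + 1,
                             size=n_frag)
    bc_idx = rng.integers(0, n_bc, size=n_frag)

    pair_span = 2 * params.read_len
    pairs: list[ReadPair] = []
    fragments: list[FragmentTruth] = []
    truth_rows: list[tuple] = []
    for fid in range(n_frag):
        name = names[int(seq_idx[fid])]
        start = int(starts[fid])
        end = min(start + int(frag_lens[fid]), int(lengths[seq_idx[fid]]))
        clipped = end - start < int(frag_lens[fid])
        barcode = barcodes[int(bc_idx[fid])]
        frag = FragmentTruth(fid, name, start, end, barcode, [], clipped)
        fragments.append(frag)
        flen = end - start
        n_pairs = int(round(params.per_fragment_coverage * flen / pair_span))
        if flen < pair_span:
            n_pairs = 0
        if n_pairs == 0:
            continue
        chrom = arrays[name]
        p_starts = rng.integers(start, end - pair_span + 1, size=n_pairs)
        gather = p_starts[:, None] + np.arange(pair_span)
        mat = _mutate(chrom[gather], params.error_rate, rng)
        m1 = mat[:, :params.read_len]
        m2 = (3 - mat[:, params.read_len:])[:, ::-1]  # reverse complement
        s1 = _BASES[m1].tobytes().decode("ascii")
        s2 = _BASES[m2].tobytes().decode("ascii")
        qual = "I" * params.read_len
        rl = params.read_len
        for j in range(n_pairs):
            pid = f"sim{fid}_{j}"
            seq1 = s1[j * rl:(j + 1) * rl]
            seq2 = s2[j * rl:(j + 1) * rl]
            comment = f"BX:Z:{barcode}"
            pair = ReadPair(
                pair_id=pid,
                mate1=LinkedRead(pid, 1, seq1, qual, barcode, comment),
                mate2=LinkedRead(pid, 2, seq2, qual, barcode, comment),
            )
            pairs.append(pair)
            frag.read_pair_ids.append(pid)
            frag.read_starts.append(int(p_starts[j]))
            truth_rows.append((pid, fid, name, start, end, barcode))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return pairs, truth, fragments


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pair_id": str, "barcode": str})
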