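"""Entropy-based evaluation of a deconvolution against a reference.

A *reference cloud* is the set of reads coming from one true fragment; a
*deconvolved cloud* is a set of reads the deconvolution proposes as one
fragment (one enhanced barcode). Good deconvolution balances two failure
modes, each scored with a Shannon entropy (natural log):

* over-deconvolution entropy of a reference cloud: -sum_i p_i ln p_i over the
  proportions p_i of its reads landing in deconvolved cloud i. Zero when the
  fragment's reads stay together; an even two-way split gives ln 2 ~ 0.693.
* under-deconvolution entropy of a deconvolved cloud: the same entropy over
  the proportions of its reads coming from each reference cloud. Zero when
  the proposed cloud is pure.

Raw (non-deconvolved) barcodes are evaluated by treating each original barcode
as a single deconvolved cloud — they are under- but not over-deconvolved.
Group-0 reads ("not deconvolved") are excluded by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .cluster import Deconvolution

__all__ = [
    "ReferenceSolution",
    "EntropyReport",
    "reference_from_truth",
    "over_entropy",
    "under_entropy",
    "entropy_report",
    "raw_labels",
]

HIST_BIN_WIDTH = 0.1


@dataclass
class ReferenceSolution:
    """Reference cloud (true fragment) of every evaluated pair."""

    reference_cloud_of: dict[str, object] = field(default_factory=dict)
    n_missing: int = 0  # pairs encountered without a truth entry


def reference_from_truth(truth: pd.DataFrame) -> ReferenceSolution:
    """Reference solution from a simulator truth table (cloud = fragment)."""
    return ReferenceSolution(
        reference_cloud_of=dict(zip(truth["pair_id"].astype(str),
                                    truth["fragment_id"]))
    )


def _entropy(counts: Iterable[int]) -> float:
    arr = np.asarray(list(counts), dtype=float)
    total = arr.sum()
    if total == 0:
        raise ValueError("entropy of an empty cloud is undefined")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum()) + 0.0  # avoid negative zero


def _labels_dict(labels) -> Mapping[str, tuple[str, int]]:
    return labels.labels if isinstance(labels, Deconvolution) else labels


def over_entropy(
    reference_cloud: Iterable[str],
    labels: Union[Deconvolution, Mapping[str, tuple[str, int]]],
) -> float:
    """Scattering of one reference cloud across deconvolved clouds."""
    lab = _labels_dict(labels)
    counts: dict = {}
    n = 0
    for pid in reference_cloud:
        n += 1
        key = lab[pid]
        counts[key] = counts.get(key, 0) + 1
    if n == 0:
        raise ValueError("empty reference cloud")
    return _entropy(counts.values())


def under_entropy(
    deconvolved_cloud: Iterable[str], reference: ReferenceSolution
) -> float:
    """Mixing of reference clouds within one deconvolved cloud."""
    counts: dict = {}
    n = 0
    for pid in deconvolved_cloud:
        n += 1
        ref = reference.reference_cloud_of[pid]
        counts[ref] = counts.get(ref, 0) + 1
    if n == 0:
        raise ValueError("empty deconvolved cloud")
    return _entropy(counts.values())


def raw_labels(barcode_of: Mapping[str, str]) -> Deconvolution:
    """Labels treating each original barcode as one deconvolved cloud."""
    return Deconvolution(
        labels={pid: (bc, 1) for pid, bc in barcode_of.items()}
    )


@dataclass
class EntropyReport:
    """Per-cloud entropies, summaries and fixed-width histogram counts."""

    over_entropies: list[tuple[object, float]]
    under_entropies: list[tuple[object, float]]
    summary: dict[str, float]
    over_hist: np.ndarray
    under_hist: np.ndarray
    bin_width: float = HIST_BIN_WIDTH

    def to_dataframe(self) -> pd.DataFrame:
        rows = [("over", str(cid), e) for cid, e in self.over_entropies]
        rows += [("under", str(cid), e) for cid, e in self.under_entropies]
        return pd.DataFrame(rows, columns=["direction", "cloud_id", "entropy"])


def _histogram(values: list[float]) -> np.ndarray:
    if not values:
        return np.zeros(1, dtype=int)
    nbins = max(1, math.floor(max(values) / HIST_BIN_WIDTH) + 1)
    hist, _ = np.histogram(
        values, bins=nbins, range=(0.0, nbins * HIST_BIN_WIDTH)
    )
    return hist


def entropy_report(
    labels: Union[Deconvolution, Mapping[str, tuple[str, int]]],
    reference: ReferenceSolution,
    include_group0: bool = False,
) -> EntropyReport:
    """Both entropy distributions over all clouds.

    Pairs lacking a reference entry are skipped (counted in the reference's
    ``n_missing``); group-0 pairs are excluded unless ``include_group0``.
    """
    lab = _labels_dict(labels)
    ref_of = reference.reference_cloud_of
    ref_clouds: dict = {}
    dec_clouds: dict = {}
    for pid, key in lab.items():
        if key[1] == 0 and not include_group0:
            continue
        if pid not in ref_of:
            reference.n_missing += 1
            continue
        ref_clouds.setdefault(ref_of[pid], []).append(pid)
        dec_clouds.setdefault(key, []).append(pid)
    over = [(cid, over_entropy(members, lab))
            for cid, members in ref_clouds.items()]
    under = [(cid, under_entropy(members, reference))
             for cid, members in dec_clouds.items()]
    over_vals = [e for _, e in over]
    under_vals = [e for _, e in under]
    summary = {
        "over_mean": float(np.mean(over_vals)) if over_vals else float("nan"),
        "over_median": float(np.median(over_vals)) if over_vals else float("nan"),
        "under_mean": float(np.mean(under_vals)) if under_vals else float("nan"),
        "under_median": (float(np.median(under_vals)) if under_vals
                         else float("nan")),
        "n_reference_clouds": float(len(over)),
        "n_deconvolved_clouds": float(len(under)),
    }
    return EntropyReport(
        over_entropies=over,
        under_entropies=under,
        summary=summary,
        over_hist=_histogram(over_vals),
        under_hist=_histogram(under_vals),
    )
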