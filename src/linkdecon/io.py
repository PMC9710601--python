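"""Barcoded paired-end FASTQ input/output.

Linked-read technologies (10x Chromium, TELL-Seq, BGI stLFR, ...) attach a short
barcode to every read identifying the long DNA fragment it was sequenced from.
The set of reads sharing one barcode is a *read cloud*; because barcodes are
reused across fragments, a cloud typically mixes several unrelated fragments.

This module parses barcoded FASTQ (10x-style ``BX:Z:`` comment tags, or a
barcode embedded after the last underscore of the read name), groups read pairs
into clouds, and writes the *enhanced barcode* output dialect in which every
barcode carries a group number: ``BX:Z:<barcode>-<group>``.  Group ``0`` marks
reads that could not be connected to anything else in their cloud.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "LinkedRead",
    "ReadPair",
    "ReadCloud",
    "extract_barcode",
    "read_linked_fastq",
    "write_enhanced_fastq",
    "group_into_clouds",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class LinkedRead:
    """One mate of a barcoded paired-end read."""

    read_id: str
    mate: int  # 1 or 2
    sequence: str
    quality: str
    barcode: Optional[str] = None
    comment: str = ""  # full FASTQ comment field, used for faithful round-trips
    barcode_suffix: Optional[int] = None  # pre-existing "-<n>" gem-group suffix

    def __post_init__(self) -> None:
        if self.mate not in (1, 2):
            raise ValueError(f"mate must be 1 or 2, got {self.mate}")
        if len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class ReadPair:
    """A read pair; the unit of deconvolution (mate2 absent for single-end)."""

    pair_id: str
    mate1: LinkedRead
    mate2: Optional[LinkedRead] = None
    barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mate2 is not None and self.mate1.barcode != self.mate2.barcode:
            raise ValueError(
                f"pair {self.pair_id!r}: mates carry different barcodes "
                f"({self.mate1.barcode!r} vs {self.mate2.barcode!r})"
            )
        if self.barcode is None:
            self.barcode = self.mate1.barcode

    @property
    def sequences(self) -> list[str]:
        if self.mate2 is None:
            return [self.mate1.sequence]
        return [self.mate1.sequence, self.mate2.sequence]


@dataclass
class ReadCloud:
    """All read pairs sharing one barcode."""

    barcode: str
    pairs: list[ReadPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> list[str]:
        return [p.pair_id for p in self.pairs]


# ---------------------------------------------------------------------------
# Barcode extraction
# ---------------------------------------------------------------------------

def extract_barcode(header_comment: str) -> tuple[Optional[str], Optional[int]]:
    """Pull the ``BX:Z:`` barcode out of a FASTQ comment field.

    Returns ``(barcode, suffix)`` where ``suffix`` is the integer of a trailing
    ``-<n>`` gem-group/enhanced-barcode suffix, recorded separately and stripped
    from the barcode. Both are ``None`` when no well-formed tag is present.
    """
    if not header_comment:
        return None, None
    for token in header_comment.split():
        if token.startswith("BX:Z:"):
            value = token[5:]
            if not value:
                return None, None
            barcode, sep, tail = value.rpartition("-")
            if sep and barcode and tail.isdigit():
                return barcode, int(tail)
            return value, None
    return None, None


def _barcode_from_name(read_id: str) -> tuple[Optional[str], Optional[int]]:
    """Alternative dialect: barcode after the last underscore of the read name."""
    stem, sep, tail = read_id.rpartition("_")
    if not sep or not tail:
        return None, None
    barcode, s2, group = tail.rpartition("-")
    if s2 and barcode and group.isdigit():
        return barcode, int(group)
    return tail, None


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality); fail loudly on truncated records."""
    n = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                yield title, seq, qual
        except ValueError as exc:
            raise ValueError(
                f"{path}: truncated or malformed FASTQ at record {n + 1}: {exc}"
            ) from exc


def _parse_read(title: str, seq: str, qual: str, mate: int,
                dialect: str) -> LinkedRead:
    name, _, comment = title.partition(" ")
    if dialect == "bx-tag":
        barcode, suffix = extract_barcode(comment)
    elif dialect == "name-suffix":
        barcode, suffix = _barcode_from_name(_strip_mate_suffix(name))
    else:
        raise ValueError(f"unknown barcode dialect {dialect!r}")
    return LinkedRead(
        read_id=name,
        mate=mate,
        sequence=seq.upper(),
        quality=qual,
        barcode=barcode,
        comment=comment,
        barcode_suffix=suffix,
    )


def read_linked_fastq(
    path_r1,
    path_r2=None,
    dialect: str = "bx-tag",
) -> tuple[list[ReadPair], dict[str, ReadCloud], list[ReadPair]]:
    """Read barcoded FASTQ into read pairs and clouds.

    R1/R2 records are paired positionally (record *i* of R1 with record *i* of
    R2). Returns ``(pairs, clouds, unbarcoded)``: *pairs* holds every pair in
    input order, *clouds* maps barcode to :class:`ReadCloud`, and pairs without
    a barcode land in the *unbarcoded* bucket, excluded from clouds.
    """
    pairs: list[ReadPair] = []
    it1 = _iter_fastq(path_r1)
    it2 = _iter_fastq(path_r2) if path_r2 is not None else None
    n1 = n2 = 0
    for title, seq, qual in it1:
        n1 += 1
        r1 = _parse_read(title, seq, qual, 1, dialect)
        r2 = None
        if it2 is not None:
            try:
                t2, s2, q2 = next(it2)
            except StopIteration:
                raise ValueError(
                    f"R1/R2 record counts differ: {path_r2} ended at record "
                    f"{n1 - 1} while {path_r1} has more"
                ) from None
            n2 += 1
            r2 = _parse_read(t2, s2, q2, 2, dialect)
        pid = _strip_mate_suffix(r1.read_id)
        pairs.append(ReadPair(pair_id=pid, mate1=r1, mate2=r2))
    if it2 is not None:
        try:
            next(it2)
        except StopIteration:
            pass
        else:
            raise ValueError(
                f"R1/R2 record counts differ: {path_r1} has {n1} records, "
                f"{path_r2} has more"
            )
    clouds = group_into_clouds(pairs)
    unbarcoded = [p for p in pairs if p.barcode is None]
    return pairs, clouds, unbarcoded


def group_into_clouds(pairs: Iterable[ReadPair]) -> dict[str, ReadCloud]:
    """Group barcoded pairs into read clouds keyed by barcode (input order)."""
    clouds: dict[str, ReadCloud] = {}
    for pair in pairs:
        if pair.barcode is None:
            continue
        cloud = clouds.get(pair.barcode)
        if cloud is None:
            cloud = clouds[pair.barcode] = ReadCloud(barcode=pair.barcode)
        cloud.pairs.append(pair)
    return clouds


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _rewrite_comment(comment: str, barcode: str, group: int) -> str:
    """Rewrite (or append) the BX tag as ``BX:Z:<barcode>-<group>``."""
    tag = f"BX:Z:{barcode}-{group}"
    tokens = comment.split() if comment else []
    replaced = False
    for i, token in enumerate(tokens):
        if token.startswith("BX:Z:"):
            tokens[i] = tag
            replaced = True
            break
    if not replaced:
        tokens.append(tag)
    return " ".join(tokens)


def _format_record(read: LinkedRead, comment: str) -> str:
    title = f"{read.read_id} {comment}" if comment else read.read_id
    return f"@{title}\n{read.sequence}\n+\n{read.quality}\n"


def write_enhanced_fastq(
    pairs: Iterable[ReadPair],
    labels: Mapping[str, tuple[str, int]],
    path_out_r1,
    path_out_r2=None,
) -> None:
    """Write pairs with enhanced barcodes ``BX:Z:<barcode>-<group>``.

    ``labels`` maps pair_id to ``(barcode, group)`` with group >= 0; group 0 is
    written literally (the "could not be deconvolved" tag). A barcoded pair
    missing from ``labels`` is a fatal error; unbarcoded pairs are written
    unchanged. Sequences, qualities and record order are preserved exactly.
    """
    out1 = _open_text(path_out_r1, "wt")
    out2 = _open_text(path_out_r2, "wt") if path_out_r2 is not None else None
    try:
        for pair in pairs:
            if pair.barcode is None:
                c1 = pair.mate1.comment
                c2 = pair.mate2.comment if pair.mate2 is not None else ""
            else:
                if pair.pair_id not in labels:
                    raise KeyError(
                        f"pair {pair.pair_id!r} has no deconvolution label"
                    )
                barcode, group = labels[pair.pair_id]
                if group < 0:
                    raise ValueError(
                        f"pair {pair.pair_id!r}: group must be >= 0, got {group}"
                    )
                c1 = _rewrite_comment(pair.mate1.comment, barcode, group)
                c2 = (_rewrite_comment(pair.mate2.comment, barcode, group)
                      if pair.mate2 is not None else "")
            out1.write(_format_record(pair.mate1, c1))
            if pair.mate2 is not None:
                if out2 is None:
                    raise ValueError(
                        "pairs have mate2 but no R2 output path was given"
                    )
                out2.write(_format_record(pair.mate2, c2))
    finally:
        out1.close()
        if out2 is not None:
            out2.close()
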