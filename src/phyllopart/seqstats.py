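"""Sequence-level statistics for assembled transcripts and read pairs.

GC content is the count of G and C bases divided by the full sequence
length, expressed as a percentage rounded half-even to two decimal places.
Ambiguity codes (N etc.) count toward the length but not the GC tally, so
a run of Ns dilutes the GC percentage rather than being ignored.

N50 is the standard assembly-contiguity statistic: the largest length L
such that sequences of length >= L together contain at least half of the
total assembled bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.FastaIO import FastaWriter

__all__ = [
    "TranscriptRecord",
    "gc_percent",
    "read_pair_gc",
    "n50",
    "revcomp",
    "stats_table",
    "read_fasta",
    "write_fasta",
]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (A<->T, C<->G, N->N)."""
    return sequence.translate(_RC)[::-1]


def gc_percent(sequence: str) -> float:
    """GC content of a sequence as a percentage with two decimals.

    The count of C and G (case-insensitive) is divided by the full
    sequence length, multiplied by 100 and rounded half-even to two
    decimal places. Rounding is done in decimal arithmetic so the result
    is platform-independent.

    Raises
    ------
    ValueError
        If the sequence is empty.
    """
    if not sequence:
        raise ValueError("gc_percent: sequence must be non-empty")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    q = (Decimal(gc) * 100 / Decimal(len(s))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN
    )
    return float(q)


def read_pair_gc(mate1: str, mate2: str) -> float:
    """GC percentage of a read pair, computed over both mates jointly.

    The two mates are concatenated and scored as one sequence, which
    weights each mate by its length.
    """
    if not mate1 or not mate2:
        raise ValueError("read_pair_gc: both mates must be non-empty")
    return gc_percent(mate1 + mate2)


def n50(lengths: Sequence[int]) -> int:
    """N50 of a collection of sequence lengths.

    Lengths are sorted in decreasing order and accumulated until the
    running sum reaches at least half of the total; the length at which
    that happens is returned. The result is always a member of the input.
    """
    if len(lengths) == 0:
        raise ValueError("n50: empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("n50: lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for l in ordered:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class TranscriptRecord:
    """One assembled transcript with its per-sequence statistics."""

    id: str
    sample: str
    sequence: str
    length: int
    gc: float

    @classmethod
    def from_sequence(cls, id: str, sequence: str, sample: str = "") -> "TranscriptRecord":
        return cls(id=id, sample=sample, sequence=sequence,
                   length=len(sequence), gc=gc_percent(sequence))


def stats_table(
    records: Iterable,
    samples: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-transcript statistics table (id, sample, length, gc).

    ``records`` is an iterable of Biopython ``SeqRecord`` objects or
    ``(id, sequence)`` pairs; ``samples`` optionally maps transcript id
    to sample id.
    """
    rows = []
    for rec in records:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        else:
            rid, seq = rec
        sample = samples.get(rid, "") if samples else ""
        rows.append((rid, sample, len(seq), gc_percent(seq)))
    return pd.DataFrame(rows, columns=["id", "sample", "length", "gc"])


def read_fasta(path) -> list:
    """Read a (possibly line-wrapped, mixed-case) FASTA file."""
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable, path, wrap: int = 80) -> None:
    """Write records to FASTA with lines wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(records)
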