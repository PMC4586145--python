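"""Fungal-enrichment filters.

Two filters make up the enrichment branch of the pipeline:

* a read-pair GC filter — paired reads are kept when their joint GC
  content is at or above a threshold (default 46%), enriching for the
  GC-richer symbiont fraction before reassembly;
* a cross-sample exact-identity filter — transcripts sharing a perfect
  >= k-nucleotide stretch (default 100 nt) with transcripts in at least
  ``min_samples`` per-sample assemblies (default 5) are removed, since
  broadly recurring exact sequence is the signature of the host, whose
  genes are expressed in many samples.

Two sequences share an exact stretch of >= k nucleotides if and only if
they share a k-mer, so the identity filter is implemented losslessly
with a canonical (strand-symmetric) k-mer index. Ns never match
anything, including other Ns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .seqstats import read_pair_gc, revcomp

__all__ = [
    "FilterReport",
    "filter_reads_by_gc",
    "cross_sample_identity_filter",
]

_ACGT = frozenset("ACGT")


@dataclass
class FilterReport:
    """Accounting for one filter pass: retained + removed = input."""

    n_input: int
    n_retained: int
    n_removed: int
    per_sample: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_retained + self.n_removed != self.n_input:
            raise ValueError("FilterReport: retained + removed != input")

    def to_json(self, path=None) -> str:
        s = json.dumps(self.__dict__, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def filter_reads_by_gc(
    in1, in2, out1, out2, threshold: float = 46.0,
) -> FilterReport:
    """Keep read pairs whose joint GC is at or above ``threshold`` percent.

    Mates are streamed in lockstep from two FASTQ files and written in
    the same pairing; a pair is kept when ``read_pair_gc`` (GC of the
    concatenated mates, two decimals) is >= threshold, so a pair at
    exactly the threshold is retained. Desynchronised mate files raise,
    naming the first mismatched id.
    """
    n_in = n_kept = 0
    with open(out1, "w") as o1, open(out2, "w") as o2:
        it1 = SeqIO.parse(str(in1), "fastq")
        it2 = SeqIO.parse(str(in2), "fastq")
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None or _pair_key(r1.id) != _pair_key(r2.id):
                bad = _pair_key(r1.id if r1 is not None else r2.id)
                raise ValueError(
                    f"filter_reads_by_gc: mate files desynchronised at "
                    f"read {bad!r}")
            n_in += 1
            if read_pair_gc(str(r1.seq), str(r2.seq)) >= threshold:
                n_kept += 1
                SeqIO.write(r1, o1, "fastq")
                SeqIO.write(r2, o2, "fastq")
    return FilterReport(
        n_input=n_in, n_retained=n_kept, n_removed=n_in - n_kept,
        params={"threshold": threshold})


def _canonical_kmers(seq: str, k: int) -> set[str]:
    s = seq.upper()
    out: set[str] = set()
    for i in range(len(s) - k + 1):
        kmer = s[i:i + k]
        if not _ACGT.issuperset(kmer):
            continue  # any ambiguity code disqualifies the k-mer
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def _normalise(records) -> list[tuple[str, str]]:
    out = []
    for rec in records:
        if hasattr(rec, "seq"):
            out.append((rec.id, str(rec.seq)))
        else:
            out.append((rec[0], rec[1]))
    return out


def cross_sample_identity_filter(
    per_sample: Mapping[str, Iterable],
    k: int = 100,
    min_samples: int = 5,
    include_self_sample: bool = True,
) -> tuple[list[str], list[str], FilterReport]:
    """Remove transcripts exactly shared across too many samples.

    A transcript is removed when the set of samples containing at least
    one transcript that shares a perfect k-nt stretch with it has size
    >= ``min_samples``. By default the transcript's own sample counts
    toward that set (every transcript trivially matches itself); with
    ``include_self_sample=False`` the own sample counts only when a
    *different* transcript from it shares a stretch.

    Matching is strand-symmetric (canonical k-mers). Transcripts shorter
    than k cannot match and are always retained. Returns (retained ids,
    removed ids, report); id lists preserve input order per sample.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    data = {s: _normalise(recs) for s, recs in per_sample.items()}
    # kmer -> {sample: set of transcript ids}
    index: dict[str, dict[str, set[str]]] = {}
    kmers_of: dict[str, set[str]] = {}
    n_short = 0
    for sample, recs in data.items():
        for tid, seq in recs:
            if tid in kmers_of:
                raise ValueError(f"duplicate transcript id {tid!r}")
            kms = _canonical_kmers(seq, k)
            if len(seq) < k:
                n_short += 1
            kmers_of[tid] = kms
            for km in kms:
                index.setdefault(km, {}).setdefault(sample, set()).add(tid)
    retained: list[str] = []
    removed: list[str] = []
    per_sample_report: dict[str, dict[str, int]] = {}
    for sample in sorted(data):
        kept_s = rem_s = 0
        for tid, _seq in data[sample]:
            if not kmers_of[tid]:  # shorter than k (or all-ambiguous)
                retained.append(tid)
                kept_s += 1
                continue
            hit_samples: set[str] = set()
            for km in kmers_of[tid]:
                for s2, tids in index[km].items():
                    if s2 == sample and not include_self_sample:
                        if tids - {tid}:
                            hit_samples.add(s2)
                    else:
                        hit_samples.add(s2)
            if include_self_sample:
                hit_samples.add(sample)  # a transcript matches itself
            if len(hit_samples) >= min_samples:
                removed.append(tid)
                rem_s += 1
            else:
                retained.append(tid)
                kept_s += 1
        per_sample_report[sample] = {"retained": kept_s, "removed": rem_s}
    if n_short:
        warnings.warn(
            f"cross_sample_identity_filter: {n_short} transcripts shorter "
            f"than k={k} were trivially retained")
    report = FilterReport(
        n_input=len(kmers_of), n_retained=len(retained),
        n_removed=len(removed), per_sample=per_sample_report,
        params={"k": k, "min_samples": min_samples,
                "include_self_sample": include_self_sample})
    return retained, removed, report
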