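"""Taxonomic assignment of transcripts from homology evidence.

Each transcript is assigned the kingdom-level label of its top-ranking
protein hit (ranked by ascending e-value below a cutoff, ties broken by
descending bitscore then subject id so that assignment is a total
order). Transcripts with no passing protein hit but a valid alignment
to the host genome are reclassified as host; the genome alignment never
overrides a protein-derived label.

A genome alignment is valid when its reliable fraction (support) is at
least 0.99, it covers more than 80% of the transcript, and exceeds 90%
identity. The three thresholds are independent parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ProteinHit",
    "GenomeAlignment",
    "TaxonAssignment",
    "DEFAULT_KINGDOM_MAP",
    "LABELS",
    "read_hits",
    "read_genome_alignments",
    "top_hit_taxon",
    "valid_genome_alignment",
    "reclassify_unassigned",
    "kingdom_summary",
]

LABELS = ("host", "fungi", "viridiplantae_other", "bacteria", "metazoa",
          "other", "none")

# Taxon label -> kingdom bucket. Extend or replace via the kingdom_map
# argument; no live taxonomy database is consulted.
DEFAULT_KINGDOM_MAP: dict[str, str] = {
    "Picea abies": "host",
    "Embryophyta": "host",
    "Viridiplantae": "viridiplantae_other",
    "Chlorophyta": "viridiplantae_other",
    "Fungi": "fungi",
    "Ascomycota": "fungi",
    "Basidiomycota": "fungi",
    "Dothideomycetes": "fungi",
    "Leotiomycetes": "fungi",
    "Eurotiomycetes": "fungi",
    "Sordariomycetes": "fungi",
    "Bacteria": "bacteria",
    "Metazoa": "metazoa",
}

_HIT_COLUMNS = ("transcript_id", "subject_id", "evalue", "bitscore",
                "taxon_label")


@dataclass(frozen=True)
class ProteinHit:
    transcript_id: str
    subject_id: str
    evalue: float
    bitscore: float
    taxon_label: str


@dataclass(frozen=True)
class GenomeAlignment:
    """Summary of one transcript-to-genome alignment.

    ``support`` is the fraction of the alignment considered reliable,
    ``coverage`` the fraction of the transcript length aligned, and
    ``identity`` the fraction of matching positions. All in [0, 1].
    """

    transcript_id: str
    support: float
    coverage: float
    identity: float


@dataclass(frozen=True)
class TaxonAssignment:
    transcript_id: str
    label: str
    provenance: str  # protein_hit | genome_alignment | unassigned


def read_hits(path) -> list[ProteinHit]:
    """Parse a protein-hit TSV (outfmt-6-like plus a taxon column).

    Requires columns transcript_id, subject_id, evalue, bitscore,
    taxon_label. Malformed rows (unparseable numbers, negative e-values)
    are rejected with a warning naming their line numbers; missing
    columns raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read_hits: missing columns {missing} in {path}")
    hits: list[ProteinHit] = []
    bad: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header
        try:
            ev = float(row.evalue)
            bs = float(row.bitscore)
        except ValueError:
            bad.append(line_no)
            continue
        if ev < 0 or not row.transcript_id:
            bad.append(line_no)
            continue
        hits.append(ProteinHit(row.transcript_id, row.subject_id, ev, bs,
                               row.taxon_label))
    if bad:
        warnings.warn(f"read_hits: rejected {len(bad)} malformed rows "
                      f"(lines {bad[:10]}{'...' if len(bad) > 10 else ''})")
    return hits


def read_genome_alignments(path) -> dict[str, GenomeAlignment]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, GenomeAlignment] = {}
    for row in df.itertuples(index=False):
        a = GenomeAlignment(str(row.transcript_id), float(row.support),
                            float(row.coverage), float(row.identity))
        for v in (a.support, a.coverage, a.identity):
            if not 0 <= v <= 1:
                raise ValueError(
                    f"genome alignment fractions must be in [0,1]: {a}")
        out[a.transcript_id] = a
    return out


def top_hit_taxon(
    hits: Iterable[ProteinHit],
    e_cutoff: float = 1e-3,
    kingdom_map: Mapping[str, str] | None = None,
    transcript_ids: Iterable[str] | None = None,
) -> list[TaxonAssignment]:
    """Assign each transcript the kingdom of its best protein hit.

    Hits with e-value < ``e_cutoff`` are ranked by ascending e-value,
    ties by descending bitscore then lexicographic subject id; the top
    hit's taxon label is mapped to a kingdom bucket (unknown labels map
    to 'other'). Transcripts with no passing hit — including any extra
    ids supplied via ``transcript_ids`` — are labelled 'none'.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be > 0")
    kmap = DEFAULT_KINGDOM_MAP if kingdom_map is None else dict(kingdom_map)
    best: dict[str, ProteinHit] = {}
    seen: set[str] = set()
    for h in hits:
        seen.add(h.transcript_id)
        if h.evalue >= e_cutoff:
            continue
        cur = best.get(h.transcript_id)
        key = (h.evalue, -h.bitscore, h.subject_id)
        if cur is None or key < (cur.evalue, -cur.bitscore, cur.subject_id):
            best[h.transcript_id] = h
    if transcript_ids is not None:
        seen.update(transcript_ids)
    out = []
    for tid in sorted(seen):
        h = best.get(tid)
        if h is None:
            out.append(TaxonAssignment(tid, "none", "unassigned"))
        else:
            out.append(TaxonAssignment(
                tid, kmap.get(h.taxon_label, "other"), "protein_hit"))
    return out


def valid_genome_alignment(
    a: GenomeAlignment,
    min_cov: float = 0.80,
    min_ident: float = 0.90,
    min_support: float = 0.99,
) -> bool:
    """Whether a genome alignment is good enough to claim host origin.

    support >= min_support, coverage strictly > min_cov and identity
    strictly > min_ident (the coverage/identity thresholds are
    exclusive).
    """
    return (a.support >= min_support
            and a.coverage > min_cov
            and a.identity > min_ident)


def reclassify_unassigned(
    assignments: Sequence[TaxonAssignment],
    alignments: Mapping[str, GenomeAlignment],
    min_cov: float = 0.80,
    min_ident: float = 0.90,
    min_support: float = 0.99,
) -> list[TaxonAssignment]:
    """Rescue unassigned transcripts that align well to the host genome.

    A transcript labelled 'none' whose genome alignment is valid becomes
    'host' with provenance 'genome_alignment'; every protein-derived
    label is left untouched.
    """
    out = []
    for a in assignments:
        aln = alignments.get(a.transcript_id)
        if (a.label == "none" and aln is not None
                and valid_genome_alignment(aln, min_cov, min_ident,
                                           min_support)):
            out.append(TaxonAssignment(a.transcript_id, "host",
                                       "genome_alignment"))
        else:
            out.append(a)
    return out


def kingdom_summary(assignments: Sequence[TaxonAssignment]) -> pd.DataFrame:
    """Counts and percentages per kingdom label."""
    if not assignments:
        raise ValueError("kingdom_summary: no assignments")
    counts = pd.Series([a.label for a in assignments]).value_counts()
    counts = counts.reindex([l for l in LABELS if l in counts.index])
    df = pd.DataFrame({
        "label": counts.index,
        "count": counts.to_numpy(),
    })
    df["percent"] = df["count"] / df["count"].sum() * 100.0
    return df.reset_index(drop=True)
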