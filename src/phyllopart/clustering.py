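"""Homolog clustering by pairwise overlap identity.

Candidate homolog pairs are found by local alignment (match +1,
mismatch -1, gap open -5, gap extend -2) on both relative strands; a
pair is emitted when the better strand's alignment spans at least
``min_overlap`` columns with identity (matches over aligned columns,
gaps included) strictly above ``min_identity``. Clusters are then the
single-linkage groups at distance 1 - identity cut at the emission
threshold — i.e. exactly the connected components of the match graph —
so no separate cut height is needed. Unmatched sequences form
singletons.

Each cluster is represented by its longest member (ties broken by
lexicographically smallest id) and can carry a pooled per-sample
expression profile, the column-wise sum over its members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .seqstats import revcomp
from .taxonomy import TaxonAssignment

__all__ = [
    "PairwiseMatch",
    "HomologCluster",
    "make_aligner",
    "pairwise_overlap_identity",
    "all_vs_all",
    "cluster",
    "filter_min_size",
    "drop_plant_clusters",
    "pooled_expression",
]

PLANT_LABELS = frozenset({"host", "viridiplantae_other"})


@dataclass(frozen=True)
class PairwiseMatch:
    """An accepted overlap between two transcripts (unordered pair)."""

    id_a: str
    id_b: str
    overlap_length: int
    identity: float
    strand: str = "+"


@dataclass
class HomologCluster:
    cluster_id: str
    members: list[str]
    representative: str
    pooled_expression: pd.Series | None = None
    label: str | None = None


def make_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _column_scores(sa: str, sb: str, aligner) -> list[float]:
    scores: list[float] = []
    in_gap = False
    for ca, cb in zip(sa, sb):
        if ca == "-" or cb == "-":
            scores.append(aligner.extend_gap_score if in_gap
                          else aligner.open_gap_score)
            in_gap = True
        else:
            in_gap = False
            scores.append(aligner.match_score if ca == cb
                          else aligner.mismatch_score)
    return scores


def _shortest_optimal_window(scores: list[float], total: float) -> tuple[int, int]:
    """Shortest window of ``scores`` summing to the optimal ``total``.

    Co-optimal local alignments can be padded with zero-sum ends (e.g. a
    trailing match+mismatch pair), inflating the apparent overlap; the
    Smith-Waterman convention is the shortest maximal-scoring window.
    """
    best: tuple[int, int] | None = None
    last: dict[float, int] = {}
    prefix = 0.0
    last[0.0] = 0
    for j, s in enumerate(scores, start=1):
        prefix += s
        i = last.get(prefix - total)
        if i is not None and (best is None or j - i < best[1] - best[0]):
            best = (i, j)
        last[prefix] = j
    if best is None:  # numerical mismatch; fall back to the full span
        best = (0, len(scores))
    return best


def _score_alignment(aligner, a: str, b: str):
    """Best local alignment of a vs b; returns (score, columns, matches).

    The alignment is trimmed to the shortest window attaining the
    optimal score before columns and matches are counted.
    """
    alns = aligner.align(a, b)
    if len(alns) == 0:
        return None
    best = alns[0]
    if best.score <= 0:
        return None
    sa, sb = str(best[0]), str(best[1])
    scores = _column_scores(sa, sb, aligner)
    i, j = _shortest_optimal_window(scores, best.score)
    matches = sum(1 for ca, cb in zip(sa[i:j], sb[i:j])
                  if ca == cb and ca != "-")
    return best.score, j - i, matches


def pairwise_overlap_identity(
    a: str,
    b: str,
    min_overlap: int = 200,
    min_identity: float = 0.52,
    id_a: str = "a",
    id_b: str = "b",
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseMatch | None:
    """Overlap-identity of two sequences, or None below threshold.

    Both relative strands are aligned and the better-scoring one used.
    Identity is matches divided by aligned columns (including gap
    columns), measured over the local alignment only — not the full
    sequence lengths.
    """
    if not a or not b:
        raise ValueError("pairwise_overlap_identity: empty sequence")
    aligner = aligner or make_aligner()
    a, b = a.upper(), b.upper()
    best = None
    for strand, bs in (("+", b), ("-", revcomp(b))):
        res = _score_alignment(aligner, a, bs)
        if res is None:
            continue
        score, columns, matches = res
        if best is None or score > best[0]:
            best = (score, columns, matches, strand)
    if best is None:
        return None
    _score, columns, matches, strand = best
    if columns == 0:
        return None
    identity = matches / columns
    if columns >= min_overlap and identity > min_identity:
        return PairwiseMatch(id_a, id_b, int(columns), float(identity),
                             strand)
    return None


def all_vs_all(
    records: Iterable,
    min_overlap: int = 200,
    min_identity: float = 0.52,
) -> list[PairwiseMatch]:
    """Exhaustive pairwise comparison of a sequence set.

    Every unordered pair is evaluated exactly once; output is sorted by
    id pair so results are independent of input order.
    """
    seqs: dict[str, str] = {}
    for rec in records:
        if hasattr(rec, "seq"):
            tid, seq = rec.id, str(rec.seq)
        else:
            tid, seq = rec
        if tid in seqs:
            raise ValueError(f"duplicate sequence id {tid!r}")
        seqs[tid] = seq
    aligner = make_aligner()
    matches: list[PairwiseMatch] = []
    for id_a, id_b in combinations(sorted(seqs), 2):
        m = pairwise_overlap_identity(
            seqs[id_a], seqs[id_b], min_overlap, min_identity,
            id_a=id_a, id_b=id_b, aligner=aligner)
        if m is not None:
            matches.append(m)
    return matches


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster(
    matches: Sequence[PairwiseMatch],
    all_ids: Iterable[str],
    lengths: Mapping[str, int] | None = None,
) -> list[HomologCluster]:
    """Single-linkage clusters of the match graph.

    Equivalent to agglomerative clustering with distance 1 - identity
    between matched pairs and distance 1 otherwise, cut at the match
    threshold: the clusters are the connected components. Unmatched ids
    become singletons. Cluster ids are assigned in order of each
    cluster's lexicographically smallest member, so output is
    independent of input order. Representatives are the longest members
    (ties: smallest id); without ``lengths`` the smallest id is used.
    """
    ids = sorted(set(all_ids))
    known = set(ids)
    for m in matches:
        if m.id_a not in known or m.id_b not in known:
            raise ValueError(
                f"cluster: match references unknown id "
                f"{(m.id_a, m.id_b)}")
    uf = _UnionFind(ids)
    for m in matches:
        uf.union(m.id_a, m.id_b)
    groups: dict[str, list[str]] = {}
    for tid in ids:
        groups.setdefault(uf.find(tid), []).append(tid)
    clusters = []
    for i, members in enumerate(sorted(groups.values(), key=lambda g: g[0])):
        members = sorted(members)
        if lengths is not None:
            rep = max(members, key=lambda t: (lengths[t], _NegStr(t)))
        else:
            rep = members[0]
        clusters.append(HomologCluster(
            cluster_id=f"C{i:05d}", members=members, representative=rep))
    return clusters


class _NegStr(str):
    """Inverts string comparison so max() prefers the smallest id on ties."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def filter_min_size(
    clusters: Sequence[HomologCluster], min_size: int = 4,
) -> list[HomologCluster]:
    """Keep clusters with at least ``min_size`` members."""
    return [c for c in clusters if len(c.members) >= min_size]


def drop_plant_clusters(
    clusters: Sequence[HomologCluster],
    assignments: Iterable[TaxonAssignment],
    plant_labels: frozenset = PLANT_LABELS,
) -> list[HomologCluster]:
    """Remove clusters whose representative is taxonomically plant.

    A representative with no assignment, or labelled 'none', carries no
    evidence of plant origin, so its cluster is retained. Retained
    clusters get their representative's label attached.
    """
    label_of = {a.transcript_id: a.label for a in assignments}
    out = []
    for c in clusters:
        label = label_of.get(c.representative, "none")
        if label in plant_labels:
            continue
        c.label = label
        out.append(c)
    return out


def pooled_expression(
    clusters: Sequence[HomologCluster],
    matrix,
) -> pd.DataFrame:
    """Per-cluster expression: column-wise sum over member transcripts.

    ``matrix`` is an ExpressionMatrix; members absent from it contribute
    zero and are reported with a warning. The result (clusters x
    samples) is also attached to each cluster as ``pooled_expression``.
    """
    data = matrix.data
    missing = [m for c in clusters for m in c.members if m not in data.index]
    if missing:
        warnings.warn(
            f"pooled_expression: {len(missing)} members absent from the "
            f"matrix contribute zero (first: {missing[0]})")
    if not clusters:
        out = pd.DataFrame(columns=list(data.columns))
        out.index.name = "cluster_id"
        return out
    rows = {}
    for c in clusters:
        present = [m for m in c.members if m in data.index]
        if present:
            pooled = data.loc[present].sum(axis=0)
        else:
            pooled = pd.Series(0.0, index=data.columns)
        c.pooled_expression = pooled
        rows[c.cluster_id] = pooled
    out = pd.DataFrame(rows).T
    out.index.name = "cluster_id"
    out.columns = list(data.columns)
    return out


def matches_to_frame(matches: Sequence[PairwiseMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.id_a, m.id_b, m.overlap_length, m.identity, m.strand)
         for m in matches],
        columns=["id_a", "id_b", "overlap", "identity", "strand"])


def clusters_to_frame(clusters: Sequence[HomologCluster]) -> pd.DataFrame:
    rows = [(c.cluster_id, m, c.representative, len(c.members))
            for c in clusters for m in c.members]
    return pd.DataFrame(
        rows, columns=["cluster_id", "member_id", "representative", "size"])
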