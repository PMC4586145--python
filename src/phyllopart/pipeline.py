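"""Pipeline orchestration for the two analysis branches.

``run_joint`` characterises a joint assembly: per-transcript GC and
length statistics, the FPKM -> floored log2 -> tau expression chain,
taxonomic assignment with genome-alignment rescue, per-kingdom
composition and a Welch comparison of host vs fungal tau scores.

``run_enrichment`` runs the fungal-enrichment branch: the read-pair GC
filter (when reads are supplied), the cross-sample exact-identity
filter, all-vs-all overlap alignment, single-linkage clustering,
minimum-size filtering, removal of plant-representative clusters and
pooled per-cluster expression.

Every stage writes its artifact to the run directory so stages can be
re-run and audited independently; the machine-readable report is
written with sorted keys and no timestamps, so identical inputs and
parameters produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (all_vs_all, cluster, clusters_to_frame,
                         drop_plant_clusters, filter_min_size,
                         matches_to_frame, pooled_expression)
from .enrichment import cross_sample_identity_filter, filter_reads_by_gc
from .seqstats import n50, read_fasta, stats_table, write_fasta
from .specificity import (ExpressionMatrix, drop_all_zero, floor_log2, fpkm,
                          tau_scores, welch_t)
from .taxonomy import (kingdom_summary, read_genome_alignments, read_hits,
                       reclassify_unassigned, top_hit_taxon)

__all__ = ["RunConfig", "run_joint", "run_enrichment", "write_report"]

log = logging.getLogger("phyllopart")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run.

    Thresholds default to the analysis' standard values: e-value cutoff
    1e-3, read-pair GC 46%, exact-identity stretch 100 nt over >= 5
    samples, overlap >= 200 nt at identity > 0.52, clusters of >= 4
    members.
    """

    outdir: str | Path = "run"
    transcripts: str | Path | None = None
    counts: str | Path | None = None
    hits: str | Path | None = None
    genome_alignments: str | Path | None = None
    sample_fasta_dir: str | Path | None = None
    reads1: str | Path | None = None
    reads2: str | Path | None = None
    e_cutoff: float = 1e-3
    gc_threshold: float = 46.0
    k: int = 100
    min_samples: int = 5
    min_overlap: int = 200
    min_identity: float = 0.52
    min_cluster_size: int = 4
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def validate(self, require: Sequence[str]) -> None:
        if not 0 < self.min_identity < 1:
            raise ValueError("min_identity must be in (0, 1)")
        for name in ("k", "min_samples", "min_overlap", "min_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in require:
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"missing required input: {name}")
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {name}={p}")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise StageError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_joint(config: RunConfig, truth: pd.DataFrame | None = None) -> dict:
    """Joint-assembly characterisation branch.

    Needs transcripts (FASTA), counts (TSV), hits (TSV) and genome
    alignments (TSV). Writes seqstats, tau scores, assignments and a
    report under ``config.outdir``; returns the report dict. When a
    truth table is supplied, per-population summaries against ground
    truth are added.
    """
    config.validate(require=[
        n for n in ("transcripts", "counts", "hits", "genome_alignments")
        if getattr(config, n) is not None or n in ("transcripts", "counts")])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = _stage("seqstats")(read_fasta)(config.transcripts)
    stats = stats_table(records)
    stats.to_csv(outdir / "seqstats.tsv", sep="\t", index=False,
                 float_format="%.6g")
    log.info("seqstats: %d transcripts", len(stats))

    def _expression():
        counts = ExpressionMatrix.from_tsv(config.counts, state="counts")
        lengths = dict(zip(stats["id"], stats["length"]))
        floored = floor_log2(fpkm(counts, lengths))
        kept = drop_all_zero(floored)
        return counts, kept, tau_scores(kept)

    counts, floored, taus = _stage("specificity")(_expression)()
    taus.to_frame().to_csv(outdir / "tau.tsv", sep="\t",
                           float_format="%.6g")
    log.info("specificity: %d of %d transcripts retained after flooring",
             floored.shape[0], counts.shape[0])

    def _taxonomy():
        hits = read_hits(config.hits) if config.hits else []
        assigns = top_hit_taxon(hits, e_cutoff=config.e_cutoff,
                                transcript_ids=list(stats["id"]))
        if config.genome_alignments:
            alns = read_genome_alignments(config.genome_alignments)
            assigns = reclassify_unassigned(assigns, alns)
        return assigns

    assigns = _stage("taxonomy")(_taxonomy)()
    pd.DataFrame(
        [(a.transcript_id, a.label, a.provenance) for a in assigns],
        columns=["transcript_id", "label", "provenance"],
    ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    composition = kingdom_summary(assigns)
    composition.to_csv(outdir / "composition.tsv", sep="\t", index=False,
                       float_format="%.6g")

    label_of = {a.transcript_id: a.label for a in assigns}
    stats = stats.assign(label=stats["id"].map(label_of))
    per_class = {}
    for label, grp in stats.groupby("label"):
        cls_taus = taus.loc[taus.index.intersection(grp["id"])]
        per_class[label] = {
            "n": int(len(grp)),
            "n50": int(n50(list(grp["length"]))),
            "mean_gc": round(float(grp["gc"].mean()), 4),
            "mean_tau": (round(float(cls_taus.mean()), 6)
                         if len(cls_taus) else None),
        }
    welch = None
    host_tau = taus.loc[taus.index.intersection(
        stats.loc[stats["label"] == "host", "id"])]
    fungi_tau = taus.loc[taus.index.intersection(
        stats.loc[stats["label"] == "fungi", "id"])]
    if len(host_tau) >= 2 and len(fungi_tau) >= 2:
        w = welch_t(fungi_tau, host_tau)
        welch = {"t": w.t, "df": w.df, "p": w.p}

    report = {
        "branch": "joint",
        "version": __version__,
        "seed": config.seed,
        "parameters": {"e_cutoff": config.e_cutoff},
        "n_transcripts": int(len(records)),
        "n_tau_scored": int(floored.shape[0]),
        "per_class": per_class,
        "composition": {
            str(lbl): {"count": int(cnt), "percent": round(float(pct), 4)}
            for lbl, cnt, pct in zip(composition["label"],
                                     composition["count"],
                                     composition["percent"])},
        "welch_fungi_vs_host_tau": welch,
    }
    if truth is not None:
        pop_of = dict(zip(truth["transcript_id"], truth["population"]))
        correct = sum(
            1 for a in assigns
            if (a.label == "host") == (pop_of.get(a.transcript_id) == "host")
            and a.label != "none")
        report["truth_agreement"] = round(correct / len(assigns), 6)
    write_report(report, outdir / "report.json")
    return report


def run_enrichment(
    config: RunConfig,
    assignments=None,
) -> dict:
    """Fungal-enrichment branch.

    Needs a directory of per-sample FASTA files (named ``<sample>.fasta``);
    optionally paired FASTQ reads (GC-filtered first) and a counts TSV
    for pooled cluster expression. ``assignments`` (TaxonAssignment
    list) drives plant-cluster removal when given.
    """
    config.validate(require=["sample_fasta_dir"])
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "branch": "enrichment",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "gc_threshold": config.gc_threshold, "k": config.k,
            "min_samples": config.min_samples,
            "min_overlap": config.min_overlap,
            "min_identity": config.min_identity,
            "min_cluster_size": config.min_cluster_size},
    }

    if config.reads1 and config.reads2:
        gc_report = _stage("read_gc_filter")(filter_reads_by_gc)(
            config.reads1, config.reads2,
            outdir / "reads_gc_1.fastq", outdir / "reads_gc_2.fastq",
            threshold=config.gc_threshold)
        report["read_gc_filter"] = {
            "input": gc_report.n_input, "retained": gc_report.n_retained,
            "removed": gc_report.n_removed}
    else:
        report["read_gc_filter"] = "skipped (no reads supplied)"

    fasta_dir = Path(config.sample_fasta_dir)
    per_sample = {
        p.stem: read_fasta(p)
        for p in sorted(fasta_dir.glob("*.fasta"))}
    if not per_sample:
        raise StageError(
            f"stage 'identity_filter' failed: no *.fasta files in {fasta_dir}")
    retained, removed, id_report = _stage("identity_filter")(
        cross_sample_identity_filter)(
            per_sample, k=config.k, min_samples=config.min_samples)
    (outdir / "retained_ids.txt").write_text("\n".join(retained) + "\n")
    (outdir / "removed_ids.txt").write_text(
        ("\n".join(removed) + "\n") if removed else "")
    report["identity_filter"] = {
        "input": id_report.n_input, "retained": id_report.n_retained,
        "removed": id_report.n_removed}
    log.info("identity filter: %d retained, %d removed",
             len(retained), len(removed))

    keep = set(retained)
    seqs = [rec for recs in per_sample.values() for rec in recs
            if rec.id in keep]
    matches = _stage("all_vs_all")(all_vs_all)(
        seqs, min_overlap=config.min_overlap,
        min_identity=config.min_identity)
    matches_to_frame(matches).to_csv(
        outdir / "matches.tsv", sep="\t", index=False, float_format="%.6g")

    lengths = {rec.id: len(rec.seq) for rec in seqs}
    clusters = _stage("cluster")(cluster)(
        matches, [rec.id for rec in seqs], lengths)
    n_before = len(clusters)
    clusters = filter_min_size(clusters, config.min_cluster_size)
    if assignments is not None:
        clusters = drop_plant_clusters(clusters, assignments)
    clusters_to_frame(clusters).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False)
    reps = {c.representative for c in clusters}
    write_fasta([rec for rec in seqs if rec.id in reps],
                outdir / "representatives.fasta")
    report["clusters"] = {
        "n_components": n_before,
        "n_clusters": len(clusters),
        "size_distribution": dict(sorted(pd.Series(
            [len(c.members) for c in clusters]
        ).value_counts().astype(int).items())) if clusters else {},
    }

    if config.counts:
        counts = ExpressionMatrix.from_tsv(config.counts, state="counts")
        all_lengths = {rec.id: len(rec.seq)
                       for recs in per_sample.values() for rec in recs}
        mat = fpkm(counts, {t: all_lengths.get(t, 1)
                            for t in counts.transcript_ids})
        pooled = _stage("pooled_expression")(pooled_expression)(clusters, mat)
        pooled.to_csv(outdir / "pooled_expression.tsv", sep="\t",
                      float_format="%.6g")
        report["pooled_expression"] = {"n_clusters": int(pooled.shape[0])}
    else:
        report["pooled_expression"] = "skipped (no counts supplied)"

    write_report(report, outdir / "report.json")
    return report
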