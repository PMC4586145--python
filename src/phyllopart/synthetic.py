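"""Synthetic dual-population transcriptome generator with ground truth.

Emulates the statistical structure that the partitioning analysis relies
on: a plant-host transcript population (lower GC, longer transcripts,
broad expression across samples) and a fungal-symbiont population (higher
GC, shorter transcripts, expression confined to one or two samples),
plus homologous gene families at a controlled nucleotide identity and
exact sequence segments shared across per-sample assemblies.

Defaults target the empirical contrasts of a conifer phyllosphere
meta-transcriptome: mean GC 44.5% (host) vs 53.1% (symbiont), host N50
several-fold larger than symbiont N50, host transcripts expressed in
~90% of 22 samples while symbiont transcripts are detected in 1-2.

All randomness flows from one root seed. Each generator draws from its
own named stream, derived as ``SeedSequence(entropy=seed, spawn_key=(i,))``
where ``i`` is the stream's fixed index — so e.g. regenerating expression
never perturbs the sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqstats import revcomp

__all__ = [
    "ConfigError",
    "GeneratorConfig",
    "generate_transcripts",
    "generate_expression",
    "generate_read_pairs",
    "generate_families",
    "spike_shared_segments",
    "generate_protein_hits",
    "generate_genome_alignments",
    "sample_ids",
    "write_truth",
    "read_truth",
]


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# Fixed stream order; appending new streams keeps old ones stable.
_STREAMS = ("transcripts", "expression", "reads", "families", "spike",
            "hits", "genome")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(idx,)))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dual-population transcriptome.

    GC means/sds are percentages; length parameters are on the natural-log
    scale of nucleotides; breadths are the fraction of samples in which a
    transcript is expressed (stochastically rounded to a whole number of
    samples, never below one).
    """

    n_host: int = 2000
    n_symbiont: int = 2000
    n_samples: int = 22
    host_gc_mean: float = 44.5
    host_gc_sd: float = 3.0
    symbiont_gc_mean: float = 53.1
    symbiont_gc_sd: float = 3.0
    host_len_log_mean: float = 7.5    # e^7.5 ~ 1800 nt
    host_len_log_sd: float = 0.45
    symbiont_len_log_mean: float = 6.1  # e^6.1 ~ 450 nt
    symbiont_len_log_sd: float = 0.45
    host_breadth: float = 0.9
    symbiont_breadth: float = 0.05
    n_families: int = 10
    family_size: int = 6
    family_identity: float = 0.9
    family_len_log_mean: float = 6.4  # e^6.4 ~ 600 nt
    family_len_log_sd: float = 0.3
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_host", "n_symbiont", "n_samples", "n_families",
                     "family_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("host_gc_mean", "symbiont_gc_mean"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ConfigError(f"{name} must be in (0, 100]")
        for name in ("host_breadth", "symbiont_breadth"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if not 0 < self.family_identity <= 1:
            raise ConfigError("family_identity must be in (0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def sample_ids(n_samples: int) -> list[str]:
    return [f"S{i:02d}" for i in range(1, n_samples + 1)]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """I.i.d. bases with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    g = gc / 2.0
    a = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[a, g, g, a])
    return _BASES[idx].tobytes().decode("ascii")


def _breadth_count(rng: np.random.Generator, breadth: float, n_samples: int) -> int:
    """Stochastically round breadth*n_samples to an integer >= 1.

    E.g. breadth 0.05 over 22 samples gives 1.1, realised as 1 sample
    (90%) or 2 samples (10%), so the expected breadth is exact.
    """
    target = breadth * n_samples
    base = int(np.floor(target))
    frac = target - base
    k = base + (1 if rng.random() < frac else 0)
    return int(min(max(k, 1), n_samples))


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=[
        "transcript_id", "population", "family_id", "sample",
        "expressed_samples"])


def generate_transcripts(config: GeneratorConfig) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate host and symbiont transcript sequences plus ground truth.

    Returns Biopython records and a truth table with one row per
    transcript (population label, sample of origin, expressed-sample
    set as a semicolon-joined string). Deterministic under a fixed seed.
    """
    config.validate()
    rng = _rng(config.seed, "transcripts")
    samples = sample_ids(config.n_samples)
    specs = [
        ("host", "H", config.n_host, config.host_gc_mean, config.host_gc_sd,
         config.host_len_log_mean, config.host_len_log_sd, config.host_breadth),
        ("symbiont", "F", config.n_symbiont, config.symbiont_gc_mean,
         config.symbiont_gc_sd, config.symbiont_len_log_mean,
         config.symbiont_len_log_sd, config.symbiont_breadth),
    ]
    records: list[SeqRecord] = []
    truth_rows: list[dict] = []
    for pop, prefix, n, gc_mean, gc_sd, llm, lls, breadth in specs:
        gcs = np.clip(rng.normal(gc_mean, gc_sd, size=n), 0.0, 100.0) / 100.0
        lengths = np.maximum(
            np.rint(rng.lognormal(llm, lls, size=n)).astype(int), 100)
        for i in range(n):
            tid = f"{prefix}T{i:06d}"
            seq = _random_sequence(rng, int(lengths[i]), float(gcs[i]))
            k = _breadth_count(rng, breadth, config.n_samples)
            expressed = sorted(
                rng.choice(config.n_samples, size=k, replace=False))
            expressed_ids = [samples[j] for j in expressed]
            origin = expressed_ids[int(rng.integers(len(expressed_ids)))]
            records.append(SeqRecord(Seq(seq), id=tid, description=""))
            truth_rows.append(dict(
                transcript_id=tid, population=pop, family_id="",
                sample=origin,
                expressed_samples=";".join(expressed_ids)))
    return records, _truth_frame(truth_rows)


def generate_expression(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    base_mean: float | np.ndarray | None = None,
):
    """Negative-binomial fragment counts for each transcript and sample.

    A transcript receives counts only in its truth-defined expressed
    samples; counts are drawn NB with a per-transcript base mean
    (log-normal unless ``base_mean`` overrides it) and dispersion
    ``config.dispersion`` (variance mu + dispersion*mu^2).

    Returns an :class:`~phyllopart.specificity.ExpressionMatrix` in the
    ``counts`` state.
    """
    from .specificity import ExpressionMatrix

    if len(truth) == 0:
        raise ConfigError("generate_expression: empty truth table")
    config.validate()
    rng = _rng(config.seed, "expression")
    samples = sample_ids(config.n_samples)
    col = {s: j for j, s in enumerate(samples)}
    n = len(truth)
    if base_mean is None:
        mus = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)
    else:
        mus = np.broadcast_to(np.asarray(base_mean, dtype=float), (n,))
    counts = np.zeros((n, config.n_samples), dtype=np.int64)
    disp = config.dispersion
    for i, (mu, expr) in enumerate(zip(mus, truth["expressed_samples"])):
        idx = [col[s] for s in str(expr).split(";") if s]
        if not idx or mu <= 0:
            continue
        if disp > 0:
            r = 1.0 / disp
            p = r / (r + mu)
            draws = rng.negative_binomial(r, p, size=len(idx))
        else:
            draws = rng.poisson(mu, size=len(idx))
        counts[i, idx] = draws
    data = pd.DataFrame(counts, index=list(truth["transcript_id"]),
                        columns=samples)
    return ExpressionMatrix(data, state="counts")


def generate_read_pairs(
    records: Iterable[SeqRecord],
    n_pairs: int,
    read_len: int,
    seed: int,
    fragment_len: int | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Sample uniform paired-end reads from transcript sequences.

    Fragments of length ``fragment_len`` (default 2*read_len, truncated
    to the transcript where necessary) are drawn uniformly over all
    possible start positions across all eligible transcripts; mate 1 is
    the fragment 5' end, mate 2 the reverse complement of the fragment
    3' end. Transcripts shorter than ``read_len`` are skipped with a
    warning. Qualities are constant Phred 40 ('I').
    """
    if read_len <= 0:
        raise ConfigError("read_len must be > 0")
    if n_pairs < 0:
        raise ConfigError("n_pairs must be >= 0")
    frag = fragment_len if fragment_len is not None else 2 * read_len
    if frag < read_len:
        raise ConfigError("fragment_len must be >= read_len")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(_STREAMS.index("reads"),)))
    seqs: list[str] = []
    for rec in records:
        s = str(rec.seq)
        if len(s) < read_len:
            warnings.warn(
                f"generate_read_pairs: skipping {rec.id} "
                f"(length {len(s)} < read_len {read_len})")
            continue
        seqs.append(s)
    mate1: list[SeqRecord] = []
    mate2: list[SeqRecord] = []
    if n_pairs == 0 or not seqs:
        return mate1, mate2
    starts = np.array([len(s) - min(frag, len(s)) + 1 for s in seqs],
                      dtype=float)
    weights = starts / starts.sum()
    picks = rng.choice(len(seqs), size=n_pairs, p=weights)
    quals = None
    for i, t in enumerate(picks):
        s = seqs[t]
        f = min(frag, len(s))
        pos = int(rng.integers(len(s) - f + 1))
        fragment = s[pos:pos + f]
        m1 = fragment[:read_len]
        m2 = revcomp(fragment[-read_len:])
        rid = f"RP{i:07d}"
        for mates, seq_s, suffix in ((mate1, m1, "/1"), (mate2, m2, "/2")):
            rec = SeqRecord(Seq(seq_s), id=rid + suffix, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq_s)
            mates.append(rec)
    return mate1, mate2


def _mutate(rng: np.random.Generator, ancestor: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A substituted site becomes one of the three other bases uniformly.
    """
    out = ancestor.copy()
    hit = np.nonzero(rng.random(len(ancestor)) < rate)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit)).astype(np.uint8)
        # map base byte -> index 0..3, rotate, map back
        lut = np.zeros(256, dtype=np.uint8)
        lut[_BASES] = np.arange(4, dtype=np.uint8)
        out[hit] = _BASES[(lut[out[hit]] + shift) % 4]
    return out


def generate_families(
    config: GeneratorConfig,
) -> tuple[dict[str, list[SeqRecord]], pd.DataFrame]:
    """Homologous gene families spread across per-sample assemblies.

    Each family derives ``family_size`` members from one random ancestor
    (star phylogeny) by i.i.d. per-site substitution at rate
    ``1 - family_identity``; members are assigned round-robin to
    pseudo-samples. The expected pairwise identity between members is
    ``family_identity^2 + (1-family_identity)^2/3`` (two independent
    branches plus coincident substitutions).

    Returns a mapping sample id -> records plus a truth table with
    family ids.
    """
    config.validate()
    rng = _rng(config.seed, "families")
    samples = sample_ids(config.n_samples)
    rate = 1.0 - config.family_identity
    fastas: dict[str, list[SeqRecord]] = {s: [] for s in samples}
    truth_rows: list[dict] = []
    for f in range(config.n_families):
        length = max(int(np.rint(rng.lognormal(
            config.family_len_log_mean, config.family_len_log_sd))), 250)
        gc = np.clip(rng.normal(config.symbiont_gc_mean,
                                config.symbiont_gc_sd), 0, 100) / 100.0
        ancestor = np.frombuffer(
            _random_sequence(rng, length, float(gc)).encode(), dtype=np.uint8)
        fam_id = f"F{f:03d}"
        for m in range(config.family_size):
            member = _mutate(rng, ancestor, rate)
            tid = f"{fam_id}M{m:02d}"
            sample = samples[(f + m) % config.n_samples]
            fastas[sample].append(
                SeqRecord(Seq(member.tobytes().decode()), id=tid,
                          description=""))
            truth_rows.append(dict(
                transcript_id=tid, population="symbiont", family_id=fam_id,
                sample=sample, expressed_samples=sample))
    return fastas, _truth_frame(truth_rows)


def spike_shared_segments(
    per_sample_fastas: Mapping[str, Sequence[SeqRecord]],
    segment_len: int,
    n_samples_shared: int,
    seed: int,
) -> tuple[dict[str, list[SeqRecord]], list[str]]:
    """Copy one exact segment into one transcript in each of n samples.

    Used to plant ground truth for the cross-sample exact-identity
    filter: the recipients (and only they) share a ``segment_len``-nt
    identical stretch across ``n_samples_shared`` samples. Input records
    are not modified; a new mapping is returned along with the recipient
    transcript ids.
    """
    samples = sorted(per_sample_fastas)
    if n_samples_shared > len(samples):
        raise ConfigError("n_samples_shared exceeds number of samples")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(_STREAMS.index("spike"),)))
    eligible = {
        s: [i for i, r in enumerate(per_sample_fastas[s])
            if len(r.seq) >= segment_len]
        for s in samples
    }
    candidates = [s for s in samples if eligible[s]]
    if len(candidates) < n_samples_shared:
        raise ConfigError(
            f"segment_len {segment_len} exceeds every transcript in some "
            f"samples: only {len(candidates)} samples have an eligible target")
    chosen = sorted(rng.choice(len(candidates), size=n_samples_shared,
                               replace=False))
    segment = _random_sequence(rng, segment_len, 0.5)
    out: dict[str, list[SeqRecord]] = {
        s: list(per_sample_fastas[s]) for s in samples}
    spiked: list[str] = []
    for ci in chosen:
        s = candidates[ci]
        ti = eligible[s][int(rng.integers(len(eligible[s])))]
        rec = out[s][ti]
        seq = str(rec.seq)
        pos = int(rng.integers(len(seq) - segment_len + 1))
        new_seq = seq[:pos] + segment + seq[pos + segment_len:]
        out[s][ti] = SeqRecord(Seq(new_seq), id=rec.id, description="")
        spiked.append(rec.id)
    return out, spiked


def generate_protein_hits(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    hit_rate: float = 0.99,
) -> pd.DataFrame:
    """Protein-homology hit table consistent with the truth labels.

    Each transcript receives, with probability ``hit_rate``, one strong
    hit whose taxon label matches its population (host -> 'Picea abies',
    symbiont -> 'Fungi'); the rest get no hit and must be rescued by the
    genome-alignment rule or remain unassigned.
    """
    config.validate()
    rng = _rng(config.seed, "hits")
    rows = []
    taxon = {"host": "Picea abies", "symbiont": "Fungi"}
    for i, row in enumerate(truth.itertuples(index=False)):
        if rng.random() >= hit_rate:
            continue
        rows.append(dict(
            transcript_id=row.transcript_id,
            subject_id=f"UPI{i:06d}",
            evalue=float(10.0 ** -rng.uniform(4, 40)),
            bitscore=float(np.round(rng.uniform(80, 800), 1)),
            taxon_label=taxon[row.population]))
    return pd.DataFrame(rows, columns=[
        "transcript_id", "subject_id", "evalue", "bitscore", "taxon_label"])


def generate_genome_alignments(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    spurious_rate: float = 0.1,
) -> pd.DataFrame:
    """Host-genome alignment summaries consistent with the truth labels.

    Host transcripts receive valid alignments (support >= 0.99, coverage
    > 0.80, identity > 0.90); symbiont transcripts occasionally receive
    a spurious sub-threshold alignment and otherwise none.
    """
    config.validate()
    rng = _rng(config.seed, "genome")
    rows = []
    for row in truth.itertuples(index=False):
        if row.population == "host":
            rows.append(dict(
                transcript_id=row.transcript_id,
                support=float(rng.uniform(0.99, 1.0)),
                coverage=float(rng.uniform(0.81, 0.999)),
                identity=float(rng.uniform(0.905, 0.999))))
        elif rng.random() < spurious_rate:
            rows.append(dict(
                transcript_id=row.transcript_id,
                support=float(rng.uniform(0.5, 0.98)),
                coverage=float(rng.uniform(0.05, 0.6)),
                identity=float(rng.uniform(0.5, 0.85))))
    return pd.DataFrame(rows, columns=[
        "transcript_id", "support", "coverage", "identity"])


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"family_id": str})
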