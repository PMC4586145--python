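"""Synthetic generator: determinism, parameter recovery, truth integrity."""

import os
import tempfile

import numpy as np
import pytest
from Bio import SeqIO

from phyllopart.seqstats import gc_percent, revcomp, write_fasta
from phyllopart.specificity import drop_all_zero, floor_log2, fpkm, tau_scores
from phyllopart.synthetic import (ConfigError, GeneratorConfig,
                                  generate_expression, generate_families,
                                  generate_read_pairs, generate_transcripts,
                                  spike_shared_segments)


def fasta_bytes(records):
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        name = fh.name
    write_fasta(records, name)
    with open(name, "rb") as fh:
        data = fh.read()
    os.unlink(name)
    return data


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_host": 0},
        {"host_gc_mean": 0.0},
        {"host_gc_mean": 101.0},
        {"host_breadth": 0.0},
        {"symbiont_breadth": 1.5},
        {"family_identity": 0.0},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kwargs).validate()


class TestTranscripts:
    def test_degenerate_gc_all_gc_bases(self):
        cfg = GeneratorConfig(n_host=10, n_symbiont=1, host_gc_mean=100,
                              host_gc_sd=0.0, seed=1)
        records, truth = generate_transcripts(cfg)
        for rec in records[:10]:
            assert set(str(rec.seq)) <= {"G", "C"}

    def test_mean_gc_recovered(self):
        cfg = GeneratorConfig(n_host=2000, n_symbiont=1, host_gc_mean=44.5,
                              seed=1)
        records, truth = generate_transcripts(cfg)
        host_ids = set(truth.loc[truth.population == "host", "transcript_id"])
        gcs = [gc_percent(str(r.seq)) for r in records if r.id in host_ids]
        assert 44.0 <= np.mean(gcs) <= 45.0

    def test_gc_recovery_within_three_se(self):
        n = 1000
        cfg = GeneratorConfig(n_host=n, n_symbiont=n, seed=7)
        records, truth = generate_transcripts(cfg)
        pop = dict(zip(truth.transcript_id, truth.population))
        for label, target, sd in (("host", cfg.host_gc_mean, cfg.host_gc_sd),
                                  ("symbiont", cfg.symbiont_gc_mean,
                                   cfg.symbiont_gc_sd)):
            gcs = [gc_percent(str(r.seq)) for r in records
                   if pop[r.id] == label]
            assert abs(np.mean(gcs) - target) < 3 * sd / np.sqrt(n)

    def test_seeded_determinism_byte_identical(self, small_config):
        a, ta = generate_transcripts(small_config)
        b, tb = generate_transcripts(small_config)
        assert fasta_bytes(a) == fasta_bytes(b)
        assert ta.equals(tb)

    def test_truth_ids_unique_and_complete(self, small_config):
        records, truth = generate_transcripts(small_config)
        assert truth.transcript_id.is_unique
        assert {r.id for r in records} == set(truth.transcript_id)
        assert (truth.expressed_samples.str.len() > 0).all()

    def test_symbiont_breadth_confined(self):
        cfg = GeneratorConfig(n_host=1, n_symbiont=400, seed=3)
        _records, truth = generate_transcripts(cfg)
        sym = truth[truth.population == "symbiont"]
        n_expr = sym.expressed_samples.str.split(";").str.len()
        assert (n_expr >= 1).all()
        # <5% of symbiont transcripts span 3+ samples under defaults
        assert (n_expr >= 3).mean() < 0.05

    def test_host_longer_than_symbiont(self, small_config):
        records, truth = generate_transcripts(small_config)
        pop = dict(zip(truth.transcript_id, truth.population))
        host = [len(r.seq) for r in records if pop[r.id] == "host"]
        sym = [len(r.seq) for r in records if pop[r.id] == "symbiont"]
        assert np.median(host) > 2 * np.median(sym)


class TestExpression:
    def test_symbiont_rows_confined_to_expressed_samples(self, small_config):
        _records, truth = generate_transcripts(small_config)
        m = generate_expression(truth, small_config)
        samples = np.array(m.samples)
        for tid, expr in zip(truth.transcript_id, truth.expressed_samples):
            row = m.data.loc[tid]
            allowed = set(expr.split(";"))
            nz = set(samples[row.to_numpy() > 0])
            assert nz <= allowed

    def test_forced_single_sample_symbiont(self):
        cfg = GeneratorConfig(n_host=1, n_symbiont=30, n_samples=10,
                              symbiont_breadth=0.05, seed=5)
        _records, truth = generate_transcripts(cfg)
        sym = truth[truth.population == "symbiont"]
        # 0.05 * 10 = 0.5 rounds stochastically within {1} (min one sample)
        assert (sym.expressed_samples.str.split(";").str.len() == 1).all()

    def test_zero_base_mean_all_zero(self, small_config):
        _records, truth = generate_transcripts(small_config)
        m = generate_expression(truth, small_config, base_mean=0.0)
        assert (m.data.to_numpy() == 0).all()

    def test_symbiont_tau_exceeds_host_tau(self):
        cfg = GeneratorConfig(n_host=300, n_symbiont=300, seed=11)
        records, truth = generate_transcripts(cfg)
        m = generate_expression(truth, cfg)
        lengths = {r.id: len(r.seq) for r in records}
        kept = drop_all_zero(floor_log2(fpkm(m, lengths)))
        taus = tau_scores(kept)
        pop = dict(zip(truth.transcript_id, truth.population))
        by_pop = taus.groupby(taus.index.map(pop)).mean()
        assert by_pop["symbiont"] > by_pop["host"]

    def test_deterministic(self, small_config):
        _r, truth = generate_transcripts(small_config)
        a = generate_expression(truth, small_config)
        b = generate_expression(truth, small_config)
        assert a.data.equals(b.data)


class TestReadPairs:
    def test_pure_gc_source_gives_pure_gc_pairs(self):
        from phyllopart.seqstats import read_pair_gc
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        src = [SeqRecord(Seq("GC" * 200), id="t1")]
        m1, m2 = generate_read_pairs(src, n_pairs=5, read_len=50, seed=1)
        for r1, r2 in zip(m1, m2):
            assert read_pair_gc(str(r1.seq), str(r2.seq)) == 100.00

    def test_mate2_is_revcomp_of_fragment_end(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        seq = "ACGTA" * 60
        src = [SeqRecord(Seq(seq), id="t1")]
        m1, m2 = generate_read_pairs(src, n_pairs=10, read_len=40, seed=2)
        for r1, r2 in zip(m1, m2):
            start = seq.index(str(r1.seq))
            frag = seq[start:start + 80]
            assert str(r2.seq) == revcomp(frag[-40:])

    def test_zero_pairs_empty_output(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        m1, m2 = generate_read_pairs(
            [SeqRecord(Seq("A" * 300), id="t")], n_pairs=0, read_len=100,
            seed=3)
        assert m1 == [] and m2 == []

    def test_short_transcripts_skipped_with_warning(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        src = [SeqRecord(Seq("ACGT" * 10), id="short"),
               SeqRecord(Seq("ACGT" * 100), id="long")]
        with pytest.warns(UserWarning, match="short"):
            m1, _m2 = generate_read_pairs(src, n_pairs=20, read_len=100,
                                          seed=4)
        assert len(m1) == 20  # all drawn from the long transcript

    def test_determinism(self):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        src = [SeqRecord(Seq("ACGTTGCA" * 50), id="t")]
        a = generate_read_pairs(src, 8, 60, seed=9)
        b = generate_read_pairs(src, 8, 60, seed=9)
        assert [str(r.seq) for r in a[0]] == [str(r.seq) for r in b[0]]
        assert [str(r.seq) for r in a[1]] == [str(r.seq) for r in b[1]]


class TestFamilies:
    def brute_force_identity(self, a, b):
        assert len(a) == len(b)
        return sum(1 for x, y in zip(a, b) if x == y) / len(a)

    def test_identity_one_members_identical(self):
        cfg = GeneratorConfig(n_families=3, family_size=4,
                              family_identity=1.0, seed=1)
        fastas, truth = generate_families(cfg)
        seqs = {r.id: str(r.seq) for recs in fastas.values() for r in recs}
        for fam, grp in truth.groupby("family_id"):
            members = [seqs[t] for t in grp.transcript_id]
            assert len(set(members)) == 1

    def test_pairwise_identity_band(self):
        # two independent branches at rate 0.1: expected identity
        # 0.9^2 + 0.1^2/3 = 0.8133; check the empirical mean by direct
        # position-wise comparison
        cfg = GeneratorConfig(n_families=30, family_size=2,
                              family_identity=0.9,
                              family_len_log_mean=6.9,  # ~1000 nt
                              family_len_log_sd=0.01, seed=6)
        fastas, truth = generate_families(cfg)
        seqs = {r.id: str(r.seq) for recs in fastas.values() for r in recs}
        idents = []
        for fam, grp in truth.groupby("family_id"):
            a, b = [seqs[t] for t in grp.transcript_id]
            idents.append(self.brute_force_identity(a, b))
        assert 0.79 <= np.mean(idents) <= 0.84

    def test_singleton_families(self):
        cfg = GeneratorConfig(n_families=5, family_size=1, seed=2)
        _fastas, truth = generate_families(cfg)
        assert truth.groupby("family_id").size().eq(1).all()

    def test_every_member_in_truth_once(self, small_config):
        fastas, truth = generate_families(small_config)
        ids = [r.id for recs in fastas.values() for r in recs]
        assert sorted(ids) == sorted(truth.transcript_id)
        assert truth.transcript_id.is_unique


class TestSpike:
    def test_segment_too_large_raises(self, small_config):
        fastas, _truth = generate_families(small_config)
        with pytest.raises(ConfigError):
            spike_shared_segments(fastas, segment_len=10_000,
                                  n_samples_shared=3, seed=1)

    def test_recipients_share_exact_segment(self, small_config):
        fastas, _truth = generate_families(small_config)
        spiked, ids = spike_shared_segments(fastas, segment_len=100,
                                            n_samples_shared=3, seed=1)
        assert len(ids) == 3
        seqs = {r.id: str(r.seq) for recs in spiked.values() for r in recs}
        # the recipients share a common 100-mer
        first = seqs[ids[0]]
        shared = None
        for i in range(len(first) - 99):
            seg = first[i:i + 100]
            if all(seg in seqs[t] for t in ids[1:]):
                shared = seg
                break
        assert shared is not None

    def test_originals_untouched(self, small_config):
        fastas, _truth = generate_families(small_config)
        before = {r.id: str(r.seq) for recs in fastas.values() for r in recs}
        spike_shared_segments(fastas, 100, 3, seed=1)
        after = {r.id: str(r.seq) for recs in fastas.values() for r in recs}
        assert before == after
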