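"""Chimera pipeline tests: dedup, filtering, pairing, selection, support."""

import itertools

import numpy as np
import pandas as pd
import pytest

from isomirnet.chimera import (
    AlignmentHit, ChimeraCall, ChimericRead, PipelineConfig, call_chimeras,
    call_variant, dedup_reads, filter_hits, filter_support, hits_from_table,
    run_pipeline, select_best_pairs, support_counts,
)
from isomirnet.errors import DataError
from isomirnet.io import OUTFMT6_COLUMNS


def make_hit(read_id="r0", subject="m0", db="mirna", q=(0, 22), s=(0, 22),
             strand="+", mism=0, gaps=0, evalue=1e-6, bits=44.0):
    return AlignmentHit(
        read_id=read_id, subject_id=subject, subject_db=db,
        query_start=q[0], query_end=q[1], subject_start=s[0], subject_end=s[1],
        strand=strand, mismatches=mism, gap_openings=gaps,
        evalue=evalue, bitscore=bits,
    )


def make_call(read_id="r0", mirna="m0", tx="t0", portion="A" * 22,
              evalue=1e-6, bits=80.0, mq=(0, 22), tq=(24, 60)):
    mh = make_hit(read_id, mirna, "mirna", q=mq, evalue=evalue, bits=bits / 2)
    th = make_hit(read_id, tx, "transcript", q=tq, evalue=evalue, bits=bits / 2)
    return ChimeraCall(
        read_id=read_id, mirna_hit=mh, mrna_hit=th,
        gap_nt=tq[0] - mq[1], mirna_portion_seq=portion,
        mrna_portion_seq="C" * (tq[1] - tq[0]),
        combined_evalue=evalue, combined_bitscore=bits,
    )


class TestDedup:
    def test_duplicates_collapsed_first_kept(self):
        reads = [("a", "AAA", [40] * 3), ("b", "AAA", [40] * 3), ("c", "AAC", [40] * 3)]
        uniques, mult = dedup_reads(reads)
        assert [r.read_id for r in uniques] == ["a", "c"]
        assert mult == {"AAA": 2, "AAC": 1}

    def test_empty_stream(self):
        uniques, mult = dedup_reads([])
        assert uniques == [] and mult == {}

    def test_random_reads_match_set_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(1000)]
        reads = [(f"r{i}", s, [40] * 40) for i, s in enumerate(seqs)]
        uniques, mult = dedup_reads(reads)
        assert len(uniques) == len(set(seqs))
        assert sum(mult.values()) == 1000


class TestFilterHits:
    CFG = PipelineConfig()

    def test_evalue_boundary_inclusive(self):
        kept = filter_hits([make_hit(evalue=0.1), make_hit(evalue=0.11)], self.CFG)
        assert [h.evalue for h in kept] == [0.1]

    def test_antisense_dropped(self):
        assert filter_hits([make_hit(strand="-")], self.CFG) == []

    def test_gapped_alignment_dropped(self):
        assert filter_hits([make_hit(gaps=1)], self.CFG) == []

    def test_minus_strand_detected_from_coordinates(self):
        df = pd.DataFrame([["r0", "m0", 100.0, 22, 0, 0, 1, 22, 22, 1, 1e-6, 44.0]],
                          columns=OUTFMT6_COLUMNS)
        hit = hits_from_table(df, "mirna")[0]
        assert hit.strand == "-"
        assert (hit.subject_start, hit.subject_end) == (0, 22)


class TestCallChimeras:
    CFG = PipelineConfig()
    READ = ChimericRead("r0", "A" * 22 + "GG" + "C" * 36, tuple([40] * 60))

    def test_two_nt_gap_one_call(self):
        calls = call_chimeras(
            self.READ, [make_hit(q=(0, 22))],
            [make_hit(subject="t0", db="transcript", q=(24, 60))], self.CFG)
        assert len(calls) == 1 and calls[0].gap_nt == 2
        assert calls[0].mirna_portion_seq == "A" * 22

    def test_gap_five_rejected(self):
        calls = call_chimeras(
            self.READ, [make_hit(q=(0, 22))],
            [make_hit(subject="t0", db="transcript", q=(27, 60))], self.CFG)
        assert calls == []

    def test_overlapping_portions_rejected(self):
        calls = call_chimeras(
            self.READ, [make_hit(q=(0, 22))],
            [make_hit(subject="t0", db="transcript", q=(20, 60))], self.CFG)
        assert calls == []

    def test_mrna_first_rejected_when_mirna_first_required(self):
        calls = call_chimeras(
            self.READ, [make_hit(q=(30, 52))],
            [make_hit(subject="t0", db="transcript", q=(0, 26))], self.CFG)
        assert calls == []
        relaxed = PipelineConfig(require_mirna_first=False)
        assert len(call_chimeras(
            self.READ, [make_hit(q=(30, 52))],
            [make_hit(subject="t0", db="transcript", q=(0, 26))], relaxed)) == 1

    def test_combined_stats_max_and_sum(self):
        calls = call_chimeras(
            self.READ, [make_hit(q=(0, 22), evalue=1e-3, bits=30.0)],
            [make_hit(subject="t0", db="transcript", q=(24, 60), evalue=1e-5, bits=60.0)],
            self.CFG)
        assert calls[0].combined_evalue == 1e-3
        assert calls[0].combined_bitscore == 90.0


class TestSelectBestPairs:
    CFG = PipelineConfig()

    def test_smaller_evalue_wins(self):
        a = make_call(evalue=0.01, bits=40)
        b = make_call(tx="t1", evalue=0.02, bits=90)
        assert select_best_pairs([b, a], self.CFG)[0] is a

    def test_bitscore_breaks_evalue_tie(self):
        a = make_call(evalue=0.01, bits=40)
        b = make_call(tx="t1", evalue=0.01, bits=90)
        assert select_best_pairs([a, b], self.CFG)[0] is b

    def test_lexicographic_final_tiebreak(self):
        a = make_call(mirna="mirA", evalue=0.01, bits=40)
        b = make_call(mirna="mirB", evalue=0.01, bits=40)
        assert select_best_pairs([b, a], self.CFG)[0] is a

    def test_order_independent_total_order(self):
        calls = [
            make_call(mirna=m, tx=t, evalue=e, bits=b)
            for m, t, e, b in [
                ("m0", "t0", 0.01, 40), ("m1", "t0", 0.01, 40),
                ("m0", "t1", 0.005, 20), ("m0", "t2", 0.01, 90),
            ]
        ]
        cfg = PipelineConfig(top_k_pairs=4)
        expected = select_best_pairs(calls, cfg)
        for perm in itertools.permutations(calls):
            got = select_best_pairs(list(perm), cfg)
            assert [id(c) for c in got] == [id(c) for c in expected]

    def test_top_k_limits_output(self):
        calls = [make_call(tx=f"t{i}", evalue=0.01 * (i + 1)) for i in range(6)]
        assert len(select_best_pairs(calls, PipelineConfig(top_k_pairs=5))) == 5


class TestFilterSupport:
    def test_threshold_boundary(self):
        cfg = PipelineConfig(count_multiplicity=False)
        ten = [make_call(read_id=f"r{i}", portion="A" * 22) for i in range(10)]
        nine = [make_call(read_id=f"s{i}", portion="C" * 22) for i in range(9)]
        kept = filter_support(ten + nine, cfg)
        assert {c.mirna_portion_seq for c in kept} == {"A" * 22}

    def test_min_support_one_is_identity(self):
        cfg = PipelineConfig(min_support_reads=1)
        calls = [make_call(read_id="r0")]
        assert filter_support(calls, cfg) == calls

    def test_mixed_pool_counts_match_brute_force(self, rng):
        cfg = PipelineConfig(count_multiplicity=False)
        pool = [make_call(read_id=f"a{i}", portion="A" * 22) for i in range(12)]
        pool += [make_call(read_id=f"b{i}", portion="G" * 22) for i in range(3)]
        counts = support_counts(pool, cfg)
        brute = {}
        for c in pool:
            brute.setdefault(c.mirna_portion_seq, set()).add(c.read_id)
        assert {k: len(v) for k, v in brute.items()} == dict(counts)
        kept = filter_support(pool, cfg)
        assert {c.mirna_portion_seq for c in kept} == {"A" * 22}

    def test_multiplicity_counts_collapsed_duplicates(self):
        cfg = PipelineConfig(count_multiplicity=True)
        call = make_call(read_id="r0", portion="A" * 22)
        mult = {"READSEQ": 12}
        seqs = {"r0": "READSEQ"}
        assert filter_support([call], cfg, mult, seqs) == [call]
        mult = {"READSEQ": 9}
        assert filter_support([call], cfg, mult, seqs) == []


class TestCallVariant:
    REF = "ACGTTGCAACGGTTACGTACGC"
    CFG = PipelineConfig()

    def _call_with_portion(self, portion):
        c = make_call(portion=portion, mq=(0, len(portion)))
        return c

    def test_exact_match(self):
        c = self._call_with_portion(self.REF)
        assert call_variant(c, self.REF, [40] * 60, self.CFG) == "exact_mirna"

    def test_variant_quality_31_accepted(self):
        iso = self.REF[:10] + ("A" if self.REF[10] != "A" else "C") + self.REF[11:]
        quals = [40] * 60
        quals[10] = 31
        c = self._call_with_portion(iso)
        assert call_variant(c, self.REF, quals, self.CFG) == "isomir"

    def test_variant_quality_30_rejected_strict(self):
        iso = self.REF[:10] + ("A" if self.REF[10] != "A" else "C") + self.REF[11:]
        quals = [40] * 60
        quals[10] = 30
        c = self._call_with_portion(iso)
        assert call_variant(c, self.REF, quals, self.CFG) == "rejected"

    def test_short_quality_string_raises(self):
        c = self._call_with_portion(self.REF)
        with pytest.raises(DataError):
            call_variant(c, self.REF, [40] * 10, self.CFG)


class TestPipelineEndToEnd:
    def test_full_recovery_error_free(self, small_sim):
        mh, th = small_sim.alignment_hits()
        res = run_pipeline(small_sim.reads, small_sim.mirnas, mh, th)
        inter = res.interactions
        for p in small_sim.pairs:
            hit = (
                (inter.mirna_id == p.mirna_id)
                & (inter.transcript_id == p.transcript_id)
                & (inter.site_start < p.site_end)
                & (inter.site_end > p.site_start)
            )
            assert hit.any(), f"planted pair {p.pair_id} not recovered"

    def test_no_surviving_call_violates_constraints(self, small_sim):
        cfg = PipelineConfig()
        mh, th = small_sim.alignment_hits()
        res = run_pipeline(small_sim.reads, small_sim.mirnas, mh, th, cfg)
        inter = res.interactions
        assert (inter.read_support >= cfg.min_support_reads).all()
        assert (inter.gap_nt >= 0).all() and (inter.gap_nt <= cfg.max_gap).all()
        assert (inter.evalue <= cfg.max_evalue).all()

    def test_low_quality_variants_rejected_end_to_end(self):
        from isomirnet.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_mirnas=4, n_transcripts=3, reads_per_pair=12,
            base_error_rate=0.5, quality_model=(40, 20), seed=21,
            isomir_fraction=0.0,
        )
        sim = simulate_dataset(cfg)
        mh, th = sim.alignment_hits()
        res = run_pipeline(sim.reads, sim.mirnas, mh, th)
        # every surviving isomiR row must stem from high-quality positions,
        # but with error bases at quality 20 (< 30) no erroneous miRNA
        # portion may be called an isomiR
        for rec in res.interactions.itertuples(index=False):
            if rec.isomir_seq != "=":
                assert rec.isomir_seq in {
                    p.isomir_seq for p in sim.pairs
                } or rec.read_support >= 10
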