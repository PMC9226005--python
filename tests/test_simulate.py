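"""Generator tests: determinism, isomiR construction, sites, reads, hits."""

import numpy as np
import pandas as pd
import pytest

from isomirnet.errors import ParameterError, PlacementError
from isomirnet.seq import revcomp, seed_region
from isomirnet.simulate import (
    ISOMIR_TYPES, SimulationConfig, gen_alignment_hits, gen_chimeric_reads,
    gen_isomir, gen_references, gen_separable_pairs, plant_target_site,
    simulate_dataset, PlannedPair,
)


class TestReferences:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_mirnas=2, mirna_len_range=(22, 22), seed=1)
        a = gen_references(cfg)
        b = gen_references(cfg)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2].equals(b[2])
        assert len(set(a[0].values())) == 2
        assert all(len(s) == 22 for s in a[0].values())

    def test_different_seeds_differ(self):
        a = gen_references(SimulationConfig(seed=1))
        b = gen_references(SimulationConfig(seed=2))
        assert a[0] != b[0]

    def test_zero_mirnas_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(n_mirnas=0)

    def test_inverted_length_range_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(mirna_len_range=(24, 20))

    def test_utr_occupies_final_fraction(self):
        cfg = SimulationConfig(seed=4, utr_fraction=0.4)
        _, transcripts, utr = gen_references(cfg)
        for rec in utr.itertuples(index=False):
            length = len(transcripts[rec.transcript_id])
            assert rec.utr_end == length
            assert rec.utr_start == round(length * 0.6)


class TestGenIsomir:
    REF = "ACGTACGTACGTACGTACGTAC"

    def test_3p_addition_appends(self):
        iso, types = gen_isomir(self.REF, "3p_add", size=2, rng=0)
        assert iso[:-2] == self.REF and len(iso) == len(self.REF) + 2
        assert types == {"3p_add"}

    def test_5p_deletion_is_suffix(self):
        iso, types = gen_isomir(self.REF, "5p_del", size=2, rng=0)
        assert iso == self.REF[2:]
        assert types == {"5p_del"}

    def test_snp_single_internal_mismatch_same_length(self):
        iso, types = gen_isomir(self.REF, "snp", rng=5)
        assert len(iso) == len(self.REF)
        diffs = [i for i, (a, b) in enumerate(zip(iso, self.REF)) if a != b]
        assert len(diffs) == 1 and 0 < diffs[0] < len(self.REF) - 1
        assert types == {"snp"}

    def test_deletion_longer_than_sequence_rejected(self):
        with pytest.raises(ParameterError):
            gen_isomir(self.REF, "3p_del", size=len(self.REF), rng=0)

    def test_short_reference_rejected(self):
        with pytest.raises(ParameterError):
            gen_isomir("ACGTACGTACGT", "3p_add", rng=0)

    @pytest.mark.parametrize("kind", ISOMIR_TYPES)
    def test_every_type_differs_from_reference(self, kind):
        size = 2 if kind == "mnp" else 1
        iso, types = gen_isomir(self.REF, kind, size=size, rng=9)
        assert iso != self.REF
        assert types == {kind}


class TestPlantTargetSite:
    MIRNA = "ACGTTGCAACGGTTACGTACGC"

    def test_seed_complement_planted_exactly_once(self, rng):
        tx = "A" * 200
        new_tx, site = plant_target_site(tx, self.MIRNA, position=50, rng=rng)
        core = revcomp(seed_region(self.MIRNA))
        region = new_tx[site.interval[0]:site.interval[1]]
        assert region.count(core) == 1
        assert region.index(core) == site.seed_offset
        assert len(new_tx) == len(tx)

    def test_supplementary_model_adds_3prime_complement(self, rng):
        tx = "A" * 200
        new_tx, site = plant_target_site(
            tx, self.MIRNA, "seed_plus_3prime", position=10, rng=rng
        )
        region = new_tx[site.interval[0]:site.interval[1]]
        assert revcomp(self.MIRNA[9:16]) in region

    def test_position_beyond_end_rejected(self, rng):
        with pytest.raises(PlacementError):
            plant_target_site("A" * 40, self.MIRNA, position=20, rng=rng)

    def test_overlap_with_existing_rejected(self, rng):
        with pytest.raises(PlacementError):
            plant_target_site(
                "A" * 200, self.MIRNA, position=50, rng=rng,
                existing=[(60, 80)],
            )


class TestChimericReads:
    def _pair(self, iso="ACGTACGTACGTACGTACGTAC", site="TTGGCCAATTGGCCAATTGGCCAATTGGCC"):
        return PlannedPair(
            pair_id="p0", mirna_id="m0", isomir_seq=iso,
            isomir_types=frozenset(), transcript_id="t0",
            site_start=0, site_end=len(site), site_seq=site,
        )

    def test_error_free_reads_contain_isomir(self):
        cfg = SimulationConfig(reads_per_pair=12, base_error_rate=0.0, seed=2)
        reads, manifest = gen_chimeric_reads([self._pair()], cfg)
        assert len(reads) == 12
        for _rid, seq, quals in reads:
            assert seq.startswith("ACGTACGTACGTACGTACGTAC")
            assert set(quals) == {40}
        assert manifest["read_id"].is_unique

    def test_gap_support_only_zero_to_four(self):
        cfg = SimulationConfig(reads_per_pair=10_000, base_error_rate=0.0, seed=3)
        _reads, manifest = gen_chimeric_reads([self._pair()], cfg)
        gaps = set(manifest["gap_nt"])
        assert gaps == {0, 1, 2, 3, 4}

    def test_errors_get_low_quality(self):
        cfg = SimulationConfig(reads_per_pair=200, base_error_rate=0.5, seed=4)
        pair = self._pair()
        reads, _ = gen_chimeric_reads([pair], cfg)
        saw_low = False
        for _rid, seq, quals in reads:
            for q in quals:
                assert q in (40, 20)
                saw_low |= q == 20
        assert saw_low

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(reads_per_pair=20, base_error_rate=0.01, seed=5)
        a = gen_chimeric_reads([self._pair()], cfg)
        b = gen_chimeric_reads([self._pair()], cfg)
        assert a[0] == b[0]
        assert a[1].equals(b[1])


class TestAlignmentHits:
    def test_exact_match_one_clean_row(self):
        ref = {"m0": "ACGTTGCAACGGTTACGTACGC"}
        reads = [("r0", "TT" + ref["m0"] + "GGAA", [40] * 28)]
        hits = gen_alignment_hits(reads, ref, max_mismatches=0)
        plus = hits[hits.sstart <= hits.send]
        assert len(plus) == 1
        row = plus.iloc[0]
        assert row.mismatch == 0 and row.qend - row.qstart + 1 == 22
        assert row.qstart == 3  # 1-based
        assert row.gapopen == 0

    def test_no_shared_anchor_no_rows(self, rng):
        ref = {"m0": "A" * 30}
        reads = [("r0", "CGTG" * 10, [40] * 40)]
        hits = gen_alignment_hits(reads, ref)
        assert len(hits) == 0

    def test_surrogate_evalue_monotone_in_mismatches(self):
        ref_seq = "ACGTACGTACGTACGTACGTAC"
        mutated = ref_seq[:5] + "T" + ref_seq[6:10] + "C" + ref_seq[11:]
        mutated = mutated[:5] + ("A" if ref_seq[5] != "A" else "C") + mutated[6:]
        hits_exact = gen_alignment_hits(
            [("r", ref_seq, [40] * 22)], {"m": ref_seq}, max_mismatches=2)
        hits_mm = gen_alignment_hits(
            [("r", mutated, [40] * 22)], {"m": ref_seq}, max_mismatches=2)
        e_exact = hits_exact[hits_exact.sstart <= hits_exact.send].evalue.min()
        e_mm = hits_mm[hits_mm.sstart <= hits_mm.send].evalue.min()
        assert e_exact < e_mm

    def test_antisense_hit_reported_with_sstart_greater_than_send(self):
        ref = {"m0": "ACGTTGCAACGGTTACGTACGC"}
        reads = [("r0", revcomp(ref["m0"]), [40] * 22)]
        hits = gen_alignment_hits(reads, ref)
        minus = hits[hits.sstart > hits.send]
        assert len(minus) >= 1


class TestSimulatedDataset:
    def test_manifest_intervals_inside_transcripts(self, small_sim):
        for rec in small_sim.manifest.itertuples(index=False):
            L = len(small_sim.transcripts[rec.transcript_id])
            assert 0 <= rec.site_start < rec.site_end <= L
            assert 0 <= rec.gap_nt <= 4

    def test_write_round_trip_deterministic(self, small_sim, tmp_path):
        a = small_sim.write(tmp_path / "a", with_hits=False)
        b = simulate_dataset(small_sim.config).write(tmp_path / "b", with_hits=False)
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()


class TestSeparablePairs:
    def test_balanced_and_separable_by_own_seed_complement(self):
        df = gen_separable_pairs(50, seed=1, n_mirnas=4)
        assert (df.label == 1).sum() == (df.label == 0).sum() == 50
        for rec in df[df.label == 1].itertuples(index=False):
            core = revcomp(seed_region(rec.small_rna_seq))
            assert rec.site_seq.count(core) == 1
            # extensive duplex: complement of positions 2-16 present
            assert revcomp(rec.small_rna_seq[1:16]) in rec.site_seq
        for rec in df[df.label == 0].itertuples(index=False):
            core = revcomp(seed_region(rec.small_rna_seq))
            assert core not in rec.site_seq

    def test_deterministic(self):
        a = gen_separable_pairs(20, seed=3)
        b = gen_separable_pairs(20, seed=3)
        assert a.equals(b)
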