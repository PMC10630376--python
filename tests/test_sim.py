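"""Synthetic-data generator: structure, determinism, planted-truth
invariants and the statistics of simulated pileups."""

import numpy as np
import pytest

from termarrest import (
    ARREST_OFFSET,
    SimulationConfig,
    build_transcriptome,
    plant_modifications,
    simulate_pileups,
)
from termarrest.motifs import classify_motif
from termarrest.sim import TruthEntry, TruthSet


class TestConfig:
    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(cds_len=0)
        with pytest.raises(ValueError):
            SimulationConfig(cds_len=301)  # not divisible by 3
        with pytest.raises(ValueError):
            SimulationConfig(background_arrest_prob=1.5)


class TestBuildTranscriptome:
    def test_lengths_sum(self):
        cfg = SimulationConfig(n_transcripts=1, utr5_len=100, cds_len=300, utr3_len=200)
        tx = build_transcriptome(cfg)
        assert len(tx.sequences["tx0000"]) == 600
        m = tx.models[0]
        assert (m.utr5_len, m.cds_len, m.utr3_len) == (100, 300, 200)

    def test_same_seed_identical(self):
        a = build_transcriptome(SimulationConfig(n_transcripts=3, seed=5))
        b = build_transcriptome(SimulationConfig(n_transcripts=3, seed=5))
        assert a.sequences == b.sequences
        assert a.drach_anchors == b.drach_anchors

    def test_drach_anchors_are_drach(self, small_transcriptome):
        """Every recorded anchor center carries an actual DRACH 5-mer, found
        by the motif matcher on the generated sequence."""
        tx = small_transcriptome
        n_anchors = 0
        for tid, centers in tx.drach_anchors.items():
            seq = tx.sequences[tid]
            for c in centers:
                kmer = seq[c - 2 : c + 3]
                assert classify_motif(kmer) == "DRACH"
                n_anchors += 1
        assert n_anchors >= 10

    def test_acaga_anchor_sequence(self, small_transcriptome):
        tx = small_transcriptome
        for tid, centers in tx.acaga_anchors.items():
            for c in centers:
                assert tx.sequences[tid][c - 2 : c + 3] == "ACAGA"
                assert classify_motif("ACAGA") == "non_NRACN"


class TestPlantModifications:
    def test_empty_request(self, small_transcriptome):
        truth = plant_modifications(small_transcriptome, {}, seed=1)
        assert len(truth) == 0

    def test_m6a_entries_split_one(self, small_transcriptome):
        truth = plant_modifications(
            small_transcriptome, {"m6A": 10}, arrest_prob_treated=0.5, seed=1
        )
        assert len(truth) == 10
        assert all(e.split == 1.0 and e.arrest_prob_control == 0.0 for e in truth.entries)

    def test_m6a_in_drach_context(self, small_transcriptome):
        truth = plant_modifications(small_transcriptome, {"m6A": 8}, seed=2)
        for e in truth.entries:
            kmer = small_transcriptome.sequences[e.transcript_id][
                e.position - 2 : e.position + 3
            ]
            assert classify_motif(kmer) == "DRACH"

    def test_acaga_context_option(self, small_transcriptome):
        truth = plant_modifications(
            small_transcriptome, {"m6A": 3}, seed=2, m6a_context="acaga"
        )
        for e in truth.entries:
            kmer = small_transcriptome.sequences[e.transcript_id][
                e.position - 2 : e.position + 3
            ]
            assert classify_motif(kmer) == "non_NRACN"

    def test_cap_entries_near_five_prime(self, small_transcriptome):
        truth = plant_modifications(small_transcriptome, {"cap": 4}, seed=3)
        assert all(e.position <= 5 for e in truth.entries)

    def test_m1a_high_in_both_samples(self, small_transcriptome):
        truth = plant_modifications(
            small_transcriptome, {"m1A": 3}, arrest_prob_treated=0.5, seed=3
        )
        assert all(
            e.arrest_prob_treated == e.arrest_prob_control == 0.5 for e in truth.entries
        )

    def test_shortfall_error_names_deficit(self, small_transcriptome):
        n_anchors = sum(len(v) for v in small_transcriptome.drach_anchors.values())
        with pytest.raises(ValueError, match="shortfall"):
            plant_modifications(small_transcriptome, {"m6A": n_anchors + 50}, seed=1)

    def test_min_spacing_respected(self, small_transcriptome):
        truth = plant_modifications(
            small_transcriptome, {"m6A": 5, "m5C": 5, "Nm": 5}, min_spacing=10, seed=4
        )
        per_tx = {}
        for e in truth.entries:
            per_tx.setdefault(e.transcript_id, []).append(e.position)
        for positions in per_tx.values():
            positions.sort()
            assert all(b - a >= 10 for a, b in zip(positions, positions[1:]))

    def test_truthset_invariants_enforced(self):
        with pytest.raises(ValueError):
            TruthSet([TruthEntry("tx", 50, "m6A", 0.5, 0.0, split=0.7)])
        with pytest.raises(ValueError):
            TruthSet([TruthEntry("tx", 50, "Nm", 0.5, 0.0, split=1.0)])
        with pytest.raises(ValueError):
            TruthSet([TruthEntry("tx", 50, "m6A", 1.5, 0.0)])


class TestSimulatePileups:
    def test_no_arrests_without_stops(self, small_transcriptome, small_config):
        cfg = SimulationConfig(
            n_transcripts=small_config.n_transcripts,
            background_arrest_prob=0.0,
            seed=small_config.seed,
        )
        treated, control = simulate_pileups(small_transcriptome, TruthSet([]), cfg)
        for tracks in (treated, control):
            for tr in tracks.values():
                assert tr.arrest.sum() == 0

    def test_full_penetrance_full_length_reads(self):
        """One fully penetrant site, no background, unfragmented reads:
        treated arrest rate at the arrest position is 100%, control 0%."""
        cfg = SimulationConfig(
            n_transcripts=1,
            background_arrest_prob=0.0,
            read_length=600,
            read_start="transcript_end",
            mean_coverage=50,
            seed=9,
        )
        tx = build_transcriptome(cfg)
        pos = tx.drach_anchors["tx0000"][0]
        truth = TruthSet([TruthEntry("tx0000", pos, "m6A", 1.0, 0.0)])
        treated, control = simulate_pileups(tx, truth, cfg)
        a = pos - ARREST_OFFSET
        t = treated[("tx0000", "+")]
        c = control[("tx0000", "+")]
        assert t.arrest[a] == t.coverage[a] == 50
        assert c.arrest[a] == 0
        # truncation removes all treated coverage 5' of the stop
        assert t.coverage[:a].sum() == 0
        assert c.coverage[a - 1] > 0

    def test_observed_rate_within_binomial_noise(self):
        """arrest_prob 0.4 at ~1000x coverage: the observed arrest rate lies
        within 3 binomial standard deviations of 40%."""
        cfg = SimulationConfig(
            n_transcripts=1,
            background_arrest_prob=0.0,
            read_length=600,
            read_start="transcript_end",
            mean_coverage=1000,
            seed=21,
        )
        tx = build_transcriptome(cfg)
        pos = tx.drach_anchors["tx0000"][0]
        truth = TruthSet([TruthEntry("tx0000", pos, "m6A", 0.4, 0.0)])
        treated, _ = simulate_pileups(tx, truth, cfg)
        t = treated[("tx0000", "+")]
        a = pos - ARREST_OFFSET
        n = int(t.coverage[a])
        rate = t.arrest[a] / n
        sigma = np.sqrt(0.4 * 0.6 / n)
        assert abs(rate - 0.4) < 3 * sigma

    def test_conservation_arrest_le_coverage(self, m6a_experiment):
        _, _, _, treated, control = m6a_experiment
        for tracks in (treated, control):
            for tr in tracks.values():
                assert (tr.arrest <= tr.coverage).all()

    def test_determinism(self, small_transcriptome, small_config):
        truth = plant_modifications(small_transcriptome, {"m6A": 5}, seed=1)
        t1, c1 = simulate_pileups(small_transcriptome, truth, small_config)
        t2, c2 = simulate_pileups(small_transcriptome, truth, small_config)
        for k in t1:
            assert np.array_equal(t1[k].coverage, t2[k].coverage)
            assert np.array_equal(t1[k].arrest, t2[k].arrest)
            assert np.array_equal(c1[k].arrest, c2[k].arrest)

    def test_nm_split_gives_two_adjacent_stop_positions(self):
        cfg = SimulationConfig(
            n_transcripts=1,
            background_arrest_prob=0.0,
            read_length=600,
            read_start="transcript_end",
            mean_coverage=2000,
            seed=5,
        )
        tx = build_transcriptome(cfg)
        truth = TruthSet([TruthEntry("tx0000", 300, "Nm", 0.5, 0.0, split=0.5)])
        treated, _ = simulate_pileups(tx, truth, cfg)
        t = treated[("tx0000", "+")]
        a1, a2 = 300 - ARREST_OFFSET, 300 - ARREST_OFFSET - 1
        r1 = t.arrest[a1] / t.coverage[a1]
        r2 = t.arrest[a2] / t.coverage[a2]
        # equal expected arrest *rates* at both offsets for split 0.5
        assert r1 > 0.15 and r2 > 0.15
        assert abs(r1 - r2) < 0.1
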