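"""Termination-signature extraction, clustering and class calls."""

import numpy as np
import pytest

from termarrest import (
    ARREST_OFFSET,
    PileupTrack,
    SimulationConfig,
    Site,
    build_transcriptome,
    classify_clusters,
    cluster_profiles,
    control_termination_flag,
    extract_profile,
    extract_profiles,
    plant_modifications,
    simulate_pileups,
)
from termarrest.signatures import OFFSETS, SignatureProfile


def _track(coverage, arrest, ref="r"):
    return PileupTrack(ref, "+", coverage, arrest)


class TestExtractProfile:
    def test_precise_site_single_offset(self):
        # penetrant stop at arrest position 9 (site at 10), no background
        n = 20
        cov = [50] * n
        arr = [0] * n
        arr[9] = 25
        treated = _track(cov, arr)
        control = _track([50] * n, [0] * n)
        prof = extract_profile(Site("r", 10, "+"), treated, control)
        expected = np.zeros(6)
        expected[OFFSETS.index(-1)] = 50.0
        assert np.allclose(prof.signal, expected)

    def test_identical_tracks_zero_vector(self):
        t = _track([30] * 10, [0, 0, 5, 0, 0, 0, 0, 0, 0, 0])
        prof = extract_profile(Site("r", 5, "+"), t, t)
        assert np.allclose(prof.signal, 0.0)

    def test_swap_negates_signal(self):
        t = _track([40] * 12, [0, 0, 0, 0, 10, 0, 0, 0, 0, 0, 0, 0])
        c = _track([40] * 12, [0, 0, 0, 0, 2, 0, 0, 0, 0, 0, 0, 0])
        s = Site("r", 5, "+")
        assert np.allclose(
            extract_profile(s, t, c).signal, -extract_profile(s, c, t).signal
        )

    def test_window_off_end_raises(self):
        t = _track([30] * 10, [0] * 10)
        with pytest.raises(ValueError, match="off reference"):
            extract_profile(Site("r", 1, "+"), t, t)

    def test_low_coverage_raises(self):
        cov = [30] * 10
        cov[3] = 2
        t = _track(cov, [0] * 10)
        with pytest.raises(ValueError, match="coverage below"):
            extract_profile(Site("r", 5, "+"), t, t)

    def test_nm_split_two_adjacent_offsets(self):
        """Simulated stepwise site: the -1 and -2 entries are both strongly
        positive and of comparable size (simulator oracle, fixed seed)."""
        cfg = SimulationConfig(
            n_transcripts=1,
            background_arrest_prob=0.0,
            read_length=600,
            read_start="transcript_end",
            mean_coverage=3000,
            seed=13,
        )
        tx = build_transcriptome(cfg)
        from termarrest.sim import TruthEntry, TruthSet

        truth = TruthSet([TruthEntry("tx0000", 300, "Nm", 0.5, 0.0, split=0.5)])
        treated, control = simulate_pileups(tx, truth, cfg)
        prof = extract_profile(
            Site("tx0000", 300, "+"), treated[("tx0000", "+")], control[("tx0000", "+")]
        )
        i1, i2 = OFFSETS.index(-1), OFFSETS.index(-2)
        assert prof.signal[i1] > 15 and prof.signal[i2] > 15
        assert abs(prof.signal[i1] - prof.signal[i2]) < 8


def _profiles(vectors):
    return [
        SignatureProfile(site=Site("r", 100 + 10 * i, "+"), signal=np.array(v, float))
        for i, v in enumerate(vectors)
    ]


class TestClusterProfiles:
    def test_two_groups_perfect_split(self):
        precise = [0, 0, 40, 0, 0, 0]
        stepwise = [0, 20, 22, 0, 0, 0]
        res = cluster_profiles(_profiles([precise, precise, stepwise, stepwise]))
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles(_profiles([[0, 0, 40, 0, 0, 0]]))

    def test_identical_profiles_degenerate_flag(self):
        res = cluster_profiles(_profiles([[0, 0, 40, 0, 0, 0]] * 4))
        assert res.degenerate
        assert sorted(np.bincount(res.labels)[1:]) == [1, 3]

    def test_label_agreement_invariant_to_input_order(self, rng):
        precise = [[0, 0, 40 + rng.normal(0, 2), 0, 0, 0] for _ in range(20)]
        stepwise = [[0, 20 + rng.normal(0, 2), 22, 0, 0, 0] for _ in range(20)]
        profs = _profiles(precise + stepwise)
        res1 = cluster_profiles(profs)
        perm = rng.permutation(len(profs))
        res2 = cluster_profiles([profs[i] for i in perm])
        # same partition up to label swap
        part1 = {tuple(sorted(np.flatnonzero(res1.labels == c))) for c in (1, 2)}
        inv = np.empty(len(profs), dtype=int)
        for new_idx, old_idx in enumerate(perm):
            inv[old_idx] = new_idx
        part2 = {
            tuple(sorted(int(i) for i in np.flatnonzero(res2.labels[inv] == c)))
            for c in (1, 2)
        }
        assert part1 == part2

    def test_simulated_class_recovery(self):
        """100 precise + 100 stepwise simulated sites: majority-label truth
        agreement >= 95%."""
        res, truth_labels = _simulated_signature_run(seed=3)
        agreement = _majority_agreement(res.labels, truth_labels)
        assert agreement >= 0.95


def _simulated_signature_run(seed, n_each=100):
    cfg = SimulationConfig(
        n_transcripts=40, mean_coverage=60, background_arrest_prob=0.001, seed=seed
    )
    tx = build_transcriptome(cfg)
    truth = plant_modifications(
        tx,
        {"m6A": n_each, "Nm": n_each},
        arrest_prob_treated=0.5,
        min_spacing=20,
        seed=seed,
    )
    treated, control = simulate_pileups(tx, truth, cfg)
    sites = [Site(e.transcript_id, e.position, "+") for e in truth.entries]
    labels_true = [e.mod_class for e in truth.entries]
    profs, skipped = extract_profiles(sites, treated, control)
    kept = {p.site.key for p in profs}
    labels_true = [
        lab for s, lab in zip(sites, labels_true) if s.key in kept
    ]
    res = cluster_profiles(profs)
    return res, labels_true


def _majority_agreement(labels, truth_labels):
    best = 0
    for mapping in ({1: "m6A", 2: "Nm"}, {1: "Nm", 2: "m6A"}):
        ok = sum(mapping[int(l)] == t for l, t in zip(labels, truth_labels))
        best = max(best, ok / len(truth_labels))
    return best


class TestClassifyClusters:
    def test_precise_median(self):
        out = classify_clusters({1: np.array([0, 0, 40, 0, 0, 0.0])})
        assert out[1] == "precise"

    def test_stepwise_median(self):
        out = classify_clusters({1: np.array([0, 20, 22, 0, 0, 0.0])})
        assert out[1] == "stepwise"

    def test_flat_median_ambiguous(self):
        out = classify_clusters({1: np.zeros(6)})
        assert out[1] == "ambiguous"

    def test_non_adjacent_peaks_ambiguous(self):
        out = classify_clusters({1: np.array([20, 0, 22, 0, 0, 0.0])})
        assert out[1] == "ambiguous"


class TestControlTerminationFlag:
    def test_strong_control_termination_flagged(self):
        cov = [50] * 10
        arr = [0] * 10
        arr[4] = 30  # 60% control arrest at expected arrest position of site 5
        control = _track(cov, arr)
        assert control_termination_flag(Site("r", 5, "+"), control)

    def test_clean_control_not_flagged(self):
        control = _track([50] * 10, [0] * 10)
        assert not control_termination_flag(Site("r", 5, "+"), control)

    def test_m1a_flagged_and_never_called(self):
        """End-to-end: a site arresting ~50% of reads in BOTH samples is
        flagged by the control-termination check yet absent from HS and LS
        calls."""
        from termarrest import FilterConfig, call_sites_all
        from termarrest.sim import TruthEntry, TruthSet

        cfg = SimulationConfig(n_transcripts=1, mean_coverage=80, seed=17)
        tx = build_transcriptome(cfg)
        truth = TruthSet([TruthEntry("tx0000", 300, "m1A", 0.5, 0.5)])
        treated, control = simulate_pileups(tx, truth, cfg)
        assert control_termination_flag(
            Site("tx0000", 300, "+"), control[("tx0000", "+")]
        )
        for tier in ("HS", "LS"):
            recs = call_sites_all(treated, control, FilterConfig(tier=tier))
            assert 300 not in {r.modified_position for r in recs}
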