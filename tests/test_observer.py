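"""Synthetic observers: single trials, sessions, cohorts, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from metasdt.calibration import m_ratio_to_noise, noise_to_m_ratio
from metasdt.observer import (ObserverParams, TruncNormal, default_cohort_spec,
                              simulate_cohort, simulate_memory_session,
                              simulate_perceptual_session, simulate_trial,
                              _mu_for_measured_d)
from metasdt.staircase import PsychometricObserver
from metasdt.tables import counts_from_trials
from metasdt.type1 import fit_type1_equal
from metasdt.type2 import fit_meta_d


class TestSimulateTrial:
    def test_noise_free_high_sensitivity_limit(self, rng):
        params = ObserverParams(sensitivity=6.0, meta_noise_sd=0.0)
        trials = [simulate_trial(params, "S2" if i % 2 else "S1", rng)
                  for i in range(300)]
        acc = np.mean([t.correct for t in trials])
        conf = np.mean([t.confidence == 6 for t in trials])
        assert acc > 0.99
        assert conf > 0.95

    def test_zero_sensitivity_is_chance(self, rng):
        params = ObserverParams(sensitivity=0.0)
        correct = [simulate_trial(params, "S1", rng).correct
                   for _ in range(4_000)]
        assert np.mean(correct) == pytest.approx(0.5, abs=0.03)

    def test_record_fields(self, rng):
        t = simulate_trial(ObserverParams(), "S2", rng, task="memory",
                           subject_id="x", imageability="high")
        assert t.stimulus_class == "S2" and t.imageability == "high"
        assert 1 <= t.confidence <= 6 and t.rt_ms > 0 and t.ct_ms > 0
        assert t.correct == (t.response_class == t.stimulus_class)

    def test_generative_accuracy_matches_gaussian_closed_form(self, rng):
        d, c = 1.1, 0.25
        params = ObserverParams(sensitivity=d, criterion=c)
        mu = _mu_for_measured_d(d, c, 1.0, 0.0)
        expected = 0.5 * (norm.cdf(mu / 2 - c) + norm.cdf(mu / 2 + c))
        correct = [simulate_trial(params, "S2" if i % 2 else "S1", rng).correct
                   for i in range(8_000)]
        assert np.mean(correct) == pytest.approx(expected, abs=0.02)


class TestMemorySession:
    def test_default_design_cell_counts(self, rng):
        df = simulate_memory_session(ObserverParams(s=0.8), rng=rng)
        assert len(df) == 200
        cells = df.groupby(["stimulus_class", "imageability"]).size()
        assert set(cells) == {50}
        assert (df.stimulus_class == "S2").sum() == 100

    def test_minimal_design(self, rng):
        df = simulate_memory_session(ObserverParams(), n_learn=2, n_test=4,
                                     rng=rng)
        assert df.groupby(["stimulus_class", "imageability"]).size().tolist() \
            == [1, 1, 1, 1]

    def test_odd_split_rejected(self, rng):
        with pytest.raises(ValueError, match="n_test"):
            simulate_memory_session(ObserverParams(), n_learn=3, n_test=5,
                                    rng=rng)
        with pytest.raises(ValueError, match="split"):
            simulate_memory_session(ObserverParams(), n_learn=1, n_test=2,
                                    rng=rng)

    def test_wide_accuracy_range_across_cohort(self):
        trials, _ = simulate_cohort(seed=11)
        acc = trials[trials.task == "memory"].groupby("subject_id").correct.mean()
        assert acc.min() < 0.62 and acc.max() > 0.75
        assert acc.max() - acc.min() > 0.12


class TestPerceptualSession:
    def test_needs_psychometric_function(self, rng):
        with pytest.raises(ValueError, match="psychometric"):
            simulate_perceptual_session(ObserverParams(), rng=rng)

    def test_staircase_controls_accuracy(self, rng):
        params = ObserverParams(psychometric=PsychometricObserver(0.17))
        accs = [simulate_perceptual_session(params, 180, rng).correct.mean()
                for _ in range(15)]
        assert np.mean(accs) == pytest.approx(0.71, abs=0.02)

    def test_contrast_column_tracks_staircase(self, rng):
        params = ObserverParams(psychometric=PsychometricObserver(0.17))
        df = simulate_perceptual_session(params, 180, rng)
        assert df.contrast.iloc[0] == pytest.approx(0.40)
        assert (df.contrast > 0.20).all()


class TestCohort:
    def test_same_seed_identical_bytes(self):
        t1, m1 = simulate_cohort(seed=5)
        t2, m2 = simulate_cohort(seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert m1 == m2

    def test_group_sizes_and_manifest_consistency(self):
        trials, manifest = simulate_cohort(seed=3)
        subjects = trials.groupby("subject_id").group_label.first()
        assert (subjects == "SDI").sum() == 23
        assert (subjects == "control").sum() == 24
        assert set(manifest["subjects"]) == set(subjects.index)
        for sid, truth in manifest["subjects"].items():
            assert truth["group_label"] == subjects[sid]

    def test_trial_counts_per_subject(self):
        trials, _ = simulate_cohort(seed=3)
        per_task = trials.groupby(["subject_id", "task"]).size().unstack()
        assert (per_task["perceptual"] == 180).all()
        assert (per_task["memory"] == 200).all()

    def test_nonpositive_group_size_rejected(self):
        from metasdt.observer import GroupSpec
        with pytest.raises(ValueError, match="positive"):
            GroupSpec(label="x", n_subjects=0,
                      contrast_threshold=TruncNormal(0.17, 0.05, 0.04, 0.5),
                      perceptual_m_ratio=TruncNormal(1.0, 0.2, 0, 1.6),
                      memory_d_prime=TruncNormal(1.0, 0.3, 0.2, 2.0),
                      memory_m_ratio=TruncNormal(0.9, 0.2, 0, 1.6))

    def test_mean_confidence_in_observed_band(self):
        trials, _ = simulate_cohort(seed=2)
        conf = trials.groupby(["group_label", "task"]).confidence.mean()
        assert ((conf > 4.3) & (conf < 5.4)).all()


class TestCalibration:
    def test_round_trip_targets(self):
        for target in (0.3, 0.6, 0.9, 1.2):
            tau_m, tau_c = m_ratio_to_noise(target)
            assert noise_to_m_ratio(tau_m, tau_c) == pytest.approx(target,
                                                                   abs=1e-9)

    def test_channels_are_exclusive(self):
        tau_m, tau_c = m_ratio_to_noise(0.5)
        assert tau_m > 0 and tau_c == 0
        tau_m, tau_c = m_ratio_to_noise(1.3)
        assert tau_m == 0 and tau_c > 0
        with pytest.raises(ValueError):
            noise_to_m_ratio(0.5, 0.5)

    def test_confidence_informativeness_decreases_with_noise(self, rng):
        """Fitted meta-d' falls monotonically as confidence noise rises."""
        from metasdt.observer import _simulate_choices
        from metasdt.tables import RatingTable

        fitted = []
        for tau in (0.0, 1.0, 3.0):
            params = ObserverParams(sensitivity=1.2, meta_noise_sd=tau)
            stim = rng.integers(0, 2, 20_000)
            mu = _mu_for_measured_d(1.2, 0.0, 1.0, 0.0)
            resp, _, conf = _simulate_choices(rng, stim, mu, params)
            counts = np.zeros((2, 2, 6))
            np.add.at(counts, (stim, resp, conf - 1), 1.0)
            fitted.append(fit_meta_d(RatingTable(counts),
                                     variance_model="equal").meta_d)
        assert fitted[0] > fitted[1] > fitted[2]


class TestTruncNormal:
    def test_bounds_respected(self, rng):
        tn = TruncNormal(0.5, 1.0, 0.2, 0.7)
        vals = [tn.sample(rng) for _ in range(500)]
        assert min(vals) >= 0.2 and max(vals) <= 0.7

    def test_with_mean_recenters_post_truncation_expectation(self, rng):
        tn = TruncNormal.with_mean(0.19, 0.09, 0.043, 0.47)
        vals = [tn.sample(rng) for _ in range(20_000)]
        assert np.mean(vals) == pytest.approx(0.19, abs=0.005)
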