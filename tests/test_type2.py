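"""Meta-d' maximum-likelihood estimation and M-ratio."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import sim_rating_counts
from metasdt.tables import S1, S2, RatingTable, pad_counts
from metasdt.type1 import Type1Results, fit_type1_equal
from metasdt.type2 import (MetaDSDT, fit_meta_d, m_ratio, type2_predicted_probs,
                           _conditional_probs, _mu_from_meta_d)


def expected_count_table(meta_d, d1, c1, K=6, n=100_000.0, s=1.0,
                         offsets=(0.25, 0.55, 0.9, 1.3, 1.8)):
    """Expected (noise-free) counts: type-1 choices from a d1/c1 SDT model,
    confidence from the type-2 model with the given meta-d."""
    counts = np.zeros((2, 2, K))
    rel_c = c1 / d1
    # type-1 response probabilities
    for stim, (m, sd) in enumerate([(-d1 / 2, 1.0), (d1 / 2, 1.0 / s)]):
        p_s1 = norm.cdf(c1, loc=m, scale=sd)
        mu2 = _mu_from_meta_d(meta_d, s)
        meta_c = rel_c * mu2
        crit1 = meta_c - np.cumsum(offsets)[::-1]
        crit2 = meta_c + np.cumsum(offsets)
        cond = _conditional_probs(mu2, meta_c, crit1, crit2, s)
        counts[stim, S1, :] = (n / 2) * p_s1 * cond[stim, S1, :]
        counts[stim, S2, :] = (n / 2) * (1 - p_s1) * cond[stim, S2, :]
    return RatingTable(counts)


class TestPredictedProbs:
    def test_probabilities_sum_to_one_per_cell(self, rng):
        for _ in range(20):
            md = float(rng.uniform(-2, 2))
            mc = float(rng.uniform(-0.5, 0.5))
            inc = rng.uniform(0.05, 0.8, size=(2, 5))
            c1 = mc - np.cumsum(inc[0])[::-1]
            c2 = mc + np.cumsum(inc[1])
            s = float(rng.uniform(0.6, 1.4))
            probs = type2_predicted_probs(md, mc, c1, c2, s=s)
            np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-10)
            assert np.all(probs >= 0)

    def test_zero_meta_d_equalizes_correct_and_error_ratings(self):
        c1 = -np.cumsum([0.3, 0.3, 0.3, 0.3, 0.3])[::-1]
        c2 = -c1[::-1]
        probs = type2_predicted_probs(0.0, 0.0, c1, c2, s=1.0)
        # rating distribution independent of the stimulus on each response side
        np.testing.assert_allclose(probs[S1], probs[S2], atol=1e-12)

    def test_hand_computed_gaussian_areas(self):
        """meta-d = 1.5, centered criterion, equal 0.4-spaced criteria."""
        md, spacing = 1.5, 0.4
        c2 = np.cumsum([spacing] * 5)
        c1 = -c2[::-1]
        probs = type2_predicted_probs(md, 0.0, c1, c2, s=1.0)
        # independent arithmetic: stimulus S2 ~ N(0.75, 1), response S2 side
        z = lambda x: norm.cdf(x - 0.75)
        p_resp = 1 - z(0.0)
        expected_conf1 = (z(0.4) - z(0.0)) / p_resp
        expected_conf6 = (1 - z(2.0)) / p_resp
        assert probs[S2, S2, 0] == pytest.approx(expected_conf1, abs=1e-12)
        assert probs[S2, S2, 5] == pytest.approx(expected_conf6, abs=1e-12)

    def test_non_monotone_criteria_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            type2_predicted_probs(1.0, 0.0, [-1, -2, -0.5, -0.4, -0.3],
                                  [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_criteria_on_wrong_side_rejected(self):
        with pytest.raises(ValueError, match="side"):
            type2_predicted_probs(1.0, 0.0, [-1, -0.8, -0.6, -0.4, 0.2],
                                  [0.1, 0.2, 0.3, 0.4, 0.5])


class TestFit:
    def test_recovers_meta_d_from_exact_model_counts(self):
        tab = expected_count_table(meta_d=1.0, d1=1.5, c1=0.2)
        fit = fit_meta_d(tab, variance_model="equal")
        assert fit.converged
        assert fit.meta_d == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("true_meta_d", [0.0, 0.5, 1.0, 1.5])
    @pytest.mark.parametrize("d1", [1.0, 1.5])
    def test_recovery_grid(self, true_meta_d, d1):
        tab = expected_count_table(meta_d=true_meta_d, d1=d1, c1=-0.1, n=10_000)
        fit = fit_meta_d(tab, variance_model="equal")
        assert fit.meta_d == pytest.approx(true_meta_d, abs=0.1)

    def test_ideal_observer_meta_d_matches_d_prime(self, large_ideal_table):
        t1 = fit_type1_equal(large_ideal_table)
        fit = fit_meta_d(large_ideal_table, type1=t1, variance_model="equal")
        assert fit.meta_d == pytest.approx(t1.d_prime, abs=0.05 * t1.d_prime)

    def test_anticorrelated_confidence_gives_negative_meta_d(self, rng):
        counts = sim_rating_counts(rng, 5_000, d=1.2, tau=0.8,
                                   flip_confidence=True)
        fit = fit_meta_d(RatingTable(counts), variance_model="equal")
        assert fit.meta_d < -0.2  # returned as-is, never clipped

    def test_equal_fit_is_s1_special_case_of_unequal(self, medium_table):
        eq = fit_meta_d(medium_table, variance_model="equal")
        t1u = Type1Results(
            d_prime=eq.type1.d_prime, criterion_c=eq.type1.criterion_c,
            hit_rate=eq.type1.hit_rate, fa_rate=eq.type1.fa_rate,
            s=1.0, da=eq.type1.d_prime, variance_model="unequal",
            padding_applied=eq.type1.padding_applied,
            n_trials=eq.type1.n_trials)
        uneq = fit_meta_d(medium_table, type1=t1u, variance_model="unequal")
        assert uneq.meta_d == pytest.approx(eq.meta_d, abs=1e-4)

    def test_metacognitive_noise_lowers_fitted_meta_d(self, rng):
        fits = []
        for tau in (0.0, 0.7, 1.5):
            tab = RatingTable(sim_rating_counts(rng, 30_000, d=1.2, tau=tau))
            fits.append(fit_meta_d(tab, variance_model="equal").meta_d)
        assert fits[0] > fits[1] > fits[2]

    def test_constant_confidence_is_degenerate(self):
        counts = np.zeros((2, 2, 6))
        counts[:, :, 3] = 25.0
        with pytest.raises(ValueError, match="degenerate"):
            MetaDSDT(RatingTable(counts), variance="equal")

    def test_fit_metadata(self, medium_table):
        fit = fit_meta_d(medium_table, variance_model="equal")
        assert fit.log_likelihood <= 0
        assert np.all(np.diff(fit.t2_criteria_S1resp) > 0)
        assert np.all(np.diff(fit.t2_criteria_S2resp) > 0)
        assert fit.t2_criteria_S1resp[-1] <= fit.meta_c <= fit.t2_criteria_S2resp[0]
        assert fit.n_trials >= 300
        assert fit.meta_d_se is None or fit.meta_d_se > 0


class TestOracleEquivalence:
    def test_optimizer_matches_dense_grid_on_random_tables(self):
        from _oracle import grid_meta_d

        rng = np.random.default_rng(77)
        checked = 0
        while checked < 6:
            n = int(rng.integers(50, 500))
            counts = sim_rating_counts(
                rng, n, d=float(rng.uniform(0.3, 2.0)),
                c=float(rng.uniform(-0.3, 0.3)), tau=float(rng.uniform(0, 1.5)))
            try:
                fit = MetaDSDT(RatingTable(counts), variance="equal").fit()
            except ValueError:
                continue
            oracle = grid_meta_d(pad_counts(RatingTable(counts)),
                                 fit.type1.relative_criterion, s=1.0)
            assert fit.meta_d == pytest.approx(oracle, abs=0.01)
            checked += 1


class TestMRatio:
    def test_identity_when_meta_d_equals_d_prime(self, large_ideal_table):
        t1 = fit_type1_equal(large_ideal_table)
        fit = fit_meta_d(large_ideal_table, type1=t1, variance_model="equal")
        mm = m_ratio(t1, fit)
        assert mm.m_ratio == fit.meta_d / t1.d_prime
        assert mm.variant == "equal"

    def test_negative_meta_d_preserved(self, rng):
        counts = sim_rating_counts(rng, 5_000, d=1.2, tau=0.8,
                                   flip_confidence=True)
        fit = fit_meta_d(RatingTable(counts), variance_model="equal")
        mm = m_ratio(fit.type1, fit)
        assert mm.m_ratio < 0
        assert mm.type1_sensitivity > 0

    def test_direct_division(self, medium_table):
        fit = fit_meta_d(medium_table, variance_model="equal")
        assert fit.m_ratio == pytest.approx(fit.meta_d / fit.type1.d_prime)

    def test_zero_sensitivity_undefined(self, medium_table):
        fit = fit_meta_d(medium_table, variance_model="equal")
        t1 = Type1Results(0.0, 0.0, 0.5, 0.5, 1.0, 0.0, "equal", False, 100)
        with pytest.raises(ValueError, match="undefined"):
            m_ratio(t1, fit)
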