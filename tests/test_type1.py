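"""Type-1 SDT estimation: closed-form d'/c and unequal-variance zROC fits."""

import numpy as np
import pytest
from scipy.stats import norm

from conftest import sim_rating_counts
from metasdt.tables import S1, S2, RatingTable
from metasdt.type1 import Type1SDT, fit_type1_equal, fit_type1_unequal


def table_from_rates(hit, fa, n=10_000, K=6):
    """2x2-determined table with confidence spread over two levels."""
    counts = np.zeros((2, 2, K))
    counts[S2, S2, 3] = hit * n / 2
    counts[S2, S2, 5] = hit * n / 2
    counts[S2, S1, 3] = (1 - hit) * n / 2
    counts[S2, S1, 5] = (1 - hit) * n / 2
    counts[S1, S2, 3] = fa * n / 2
    counts[S1, S2, 5] = fa * n / 2
    counts[S1, S1, 3] = (1 - fa) * n / 2
    counts[S1, S1, 5] = (1 - fa) * n / 2
    return RatingTable(counts)


def gaussian_zroc_table(mu, s, criteria, n=1000.0):
    """Exact expected counts from S1 ~ N(0,1), S2 ~ N(mu, 1/s).

    `criteria` are the 2K-1 ascending cuts; the middle one is the type-1
    criterion.  Produces a perfectly linear zROC with slope exactly s.
    """
    criteria = np.asarray(criteria, dtype=float)
    K = (len(criteria) + 1) // 2
    counts = np.zeros((2, 2, K))
    for stim, (m, sd) in enumerate([(0.0, 1.0), (mu, 1.0 / s)]):
        cdf = norm.cdf(criteria, loc=m, scale=sd)
        areas = np.diff(np.concatenate([[0.0], cdf, [1.0]])) * n
        counts[stim, S1, :] = areas[:K][::-1]
        counts[stim, S2, :] = areas[K:]
    return RatingTable(counts)


class TestEqualVariance:
    def test_closed_form_at_71_29(self):
        fit = fit_type1_equal(table_from_rates(0.71, 0.29))
        assert fit.d_prime == pytest.approx(1.1067694391, abs=1e-9)
        assert fit.criterion_c == pytest.approx(0.0, abs=1e-12)
        assert fit.s == 1.0 and fit.da == fit.d_prime

    def test_no_sensitivity_when_hit_equals_fa(self):
        fit = fit_type1_equal(table_from_rates(0.4, 0.4))
        assert fit.d_prime == pytest.approx(0.0, abs=1e-12)

    def test_unbiased_symmetric_case(self):
        fit = fit_type1_equal(table_from_rates(0.5, 0.5))
        assert fit.criterion_c == pytest.approx(0.0, abs=1e-12)

    def test_matches_quantile_closed_form_to_machine_precision(self, rng):
        for _ in range(10):
            tab = RatingTable(sim_rating_counts(
                rng, 400, d=float(rng.uniform(0.2, 2.5)),
                c=float(rng.uniform(-0.5, 0.5)), tau=0.5))
            fit = fit_type1_equal(tab)
            expected = norm.ppf(fit.hit_rate) - norm.ppf(fit.fa_rate)
            assert fit.d_prime == pytest.approx(expected, abs=1e-13)

    def test_monotone_in_generating_sensitivity(self, rng):
        fits = [fit_type1_equal(RatingTable(
            sim_rating_counts(rng, 50_000, d=d))).d_prime
            for d in (0.5, 1.0, 1.5, 2.0)]
        assert np.all(np.diff(fits) > 0)


class TestUnequalVariance:
    def test_exact_linear_zroc_recovers_slope(self):
        criteria = [-1.2, -0.7, -0.3, 0.1, 0.15, 0.5, 0.8, 1.1, 1.5, 1.9, 2.4]
        tab = gaussian_zroc_table(mu=1.0, s=0.9, criteria=criteria)
        fit = fit_type1_unequal(tab)
        assert fit.s == pytest.approx(0.9, abs=1e-9)

    def test_slope_one_reduces_da_to_d_prime(self):
        criteria = [-1.2, -0.7, -0.3, 0.1, 0.15, 0.5, 0.8, 1.1, 1.5, 1.9, 2.4]
        tab = gaussian_zroc_table(mu=1.3, s=1.0, criteria=criteria)
        fit = fit_type1_unequal(tab)
        assert fit.s == pytest.approx(1.0, abs=1e-9)
        assert fit.da == pytest.approx(fit.d_prime, abs=1e-9)

    def test_parameter_recovery_s08_at_10k_trials(self):
        rng = np.random.default_rng(20)
        tab = RatingTable(sim_rating_counts(rng, 10_000, d=1.2, s=0.8, tau=0.3))
        fit = fit_type1_unequal(tab)
        assert fit.s == pytest.approx(0.8, abs=0.05)

    def test_equal_variance_simulation_yields_slope_near_one(self, rng):
        tab = RatingTable(sim_rating_counts(rng, 20_000, d=1.2, tau=0.3))
        fit = fit_type1_unequal(tab)
        assert fit.s == pytest.approx(1.0, abs=0.05)
        assert fit.da == pytest.approx(fit.d_prime, abs=0.05)

    def test_needs_three_confidence_levels(self):
        tab = RatingTable(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="K >= 3"):
            Type1SDT(tab, variance="unequal")

    def test_degenerate_roc_rejected(self):
        # every trial in one rating category per stimulus: 1 usable point
        counts = np.zeros((2, 2, 6))
        counts[S1, S1, 2] = 40
        counts[S1, S2, 2] = 10
        counts[S2, S2, 2] = 40
        counts[S2, S1, 2] = 10
        with pytest.raises(ValueError, match="degenerate ROC"):
            fit_type1_unequal(RatingTable(counts), padding="none")


def test_estimates_invariant_to_padding_provenance(medium_table):
    """Fitting a pre-padded table equals fitting with internal padding."""
    from metasdt.tables import pad_counts
    direct = fit_type1_equal(medium_table)
    padded = fit_type1_equal(pad_counts(medium_table))
    assert direct.d_prime == pytest.approx(padded.d_prime, abs=1e-12)
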