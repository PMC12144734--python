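"""Parametric laws: generalized gamma, accrual entry, censoring calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from niswitch import (
    DropoutSpec,
    EntrySpec,
    GenGammaSpec,
    admin_censor_prob,
    gg_moment,
    gg_survival,
    sample_censoring,
    sample_entry,
    scale_from_median,
    solve_dropout_param,
    total_censor_prob,
    true_rmst,
)

LN2 = np.log(2.0)


class TestGenGamma:
    def test_scale_from_median_exponential_closed_form(self):
        spec = scale_from_median(6.0, 1.0, 1.0)
        assert spec.scale == pytest.approx(6.0 / LN2, abs=1e-12)

    def test_scale_from_median_weibull_matches_reported_calibration(self):
        # Weibull with shape 1.25 and median 1 has scale 1/(ln 2)^{1/1.25} ~ 1.34
        spec = scale_from_median(1.0, shape_b=1.25, shape_k=1.0)
        assert spec.scale == pytest.approx(1.0 / LN2 ** (1 / 1.25), abs=1e-12)
        assert spec.scale == pytest.approx(1.34, abs=0.005)

    @pytest.mark.parametrize("median", [0.5, 1.0, 6.0, 47.8])
    @pytest.mark.parametrize("b,k", [(1, 1), (1.25, 1), (1, 1.53), (0.75, 2.2)])
    def test_median_roundtrip(self, median, b, k):
        spec = scale_from_median(median, b, k)
        assert spec.survival(median) == pytest.approx(0.5, abs=1e-10)
        assert spec.median == pytest.approx(median, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            scale_from_median(bad)
        with pytest.raises(ValueError):
            GenGammaSpec(scale=1.0, shape_b=bad)

    def test_survival_at_zero_is_one(self):
        assert gg_survival(0.0, GenGammaSpec(2.0, 1.3, 0.7)) == 1.0

    def test_survival_five_year_recurrence_example(self):
        # a 7% event probability at 5 years corresponds to median -5 ln2/ln(.93)
        spec = scale_from_median(-5 * LN2 / np.log(0.93))
        assert spec.survival(5.0) == pytest.approx(0.93, abs=1e-10)

    def test_gamma_survival_published_pairing(self):
        # gamma with shape 1.53 and scale 0.83: median ~1, S(2.5) ~ 0.113
        spec = GenGammaSpec(scale=0.83, shape_b=1.0, shape_k=1.53)
        assert spec.median == pytest.approx(1.0, abs=0.01)
        assert spec.survival(2.5) == pytest.approx(0.113, abs=0.002)

    @pytest.mark.parametrize("b,k,scale", [(1, 1, 2.0), (1.25, 1, 1.3), (0.8, 2.5, 0.7)])
    def test_survival_is_one_minus_density_integral(self, b, k, scale):
        spec = GenGammaSpec(scale, b, k)
        for t in (0.3, 1.0, 2.7):
            integral, _ = integrate.quad(spec.density, 0, t, limit=200)
            assert spec.survival(t) == pytest.approx(1 - integral, abs=1e-6)

    def test_exponential_moments(self):
        spec = GenGammaSpec(scale=3.7)
        assert gg_moment(spec, 1) == pytest.approx(3.7, rel=1e-12)
        assert gg_moment(spec, 2) == pytest.approx(2 * 3.7**2, rel=1e-12)

    def test_weibull_moment_against_monte_carlo(self, rng):
        spec = scale_from_median(1.0, shape_b=1.25)
        draws = spec.rvs(10**6, rng)
        assert gg_moment(spec, 1) == pytest.approx(draws.mean(), rel=5e-3)

    def test_rvs_distribution_matches_survival(self, rng):
        spec = GenGammaSpec(scale=1.7, shape_b=1.3, shape_k=0.8)
        draws = spec.rvs(10**5, rng)
        for t in (0.5, 1.5, 3.0):
            assert np.mean(draws > t) == pytest.approx(spec.survival(t), abs=0.006)


class TestTrueRMST:
    def test_no_events_gives_tau(self):
        assert true_rmst(lambda t: 1.0, 5.0) == pytest.approx(5.0, abs=1e-8)

    def test_exponential_closed_form(self):
        spec = scale_from_median(6.0)
        expected = (1 - 2.0 ** (-2)) * 6.0 / LN2
        assert true_rmst(spec, 12.0) == pytest.approx(expected, abs=1e-8)

    def test_small_tau_limit(self):
        spec = scale_from_median(6.0)
        values = [true_rmst(spec, tau) for tau in (1.0, 0.1, 0.01)]
        assert values == sorted(values, reverse=True)
        assert values[-1] < 0.011

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            true_rmst(scale_from_median(1.0), 0.0)

    def test_weibull_and_gamma_calibrated_alike_give_close_rmst(self):
        """Two families matched on the median and one survival point agree on RMST."""
        weib = scale_from_median(1.0, shape_b=1.25)
        target = weib.survival(2.5)

        def gap(k):
            return scale_from_median(1.0, 1.0, k).survival(2.5) - target

        k = optimize.brentq(gap, 0.2, 10.0)
        gam = scale_from_median(1.0, 1.0, k)
        assert k == pytest.approx(1.53, abs=0.05)
        r_w = true_rmst(weib, 5.0)
        r_g = true_rmst(gam, 5.0)
        assert r_g == pytest.approx(r_w, rel=0.02)


class TestEntry:
    def test_zero_accrual_returns_zeros(self, rng):
        out = sample_entry(EntrySpec("increasing", 0.0), 10, rng)
        assert np.all(out == 0.0)

    @pytest.mark.parametrize("pattern", ["decreasing", "unif", "increasing"])
    def test_empirical_cdf_matches_analytic(self, pattern, rng):
        entry = EntrySpec(pattern, 3.0)
        draws = entry.sample(10**6, rng)
        assert draws.min() >= 0 and draws.max() <= 3.0
        grid = np.linspace(0, 3, 301)
        ecdf = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
        assert np.max(np.abs(ecdf - entry.cdf(grid))) < 0.005

    def test_increasing_median_closed_form(self, rng):
        draws = sample_entry(EntrySpec("increasing", 3.0), 10**6, rng)
        assert np.median(draws) == pytest.approx(3 / np.sqrt(2), abs=0.01)

    def test_decreasing_mean_closed_form(self, rng):
        draws = sample_entry(EntrySpec("decreasing", 3.0), 10**6, rng)
        assert draws.mean() == pytest.approx(1.0, abs=0.005)

    @pytest.mark.parametrize("pattern", ["decreasing", "unif", "increasing"])
    def test_density_integrates_to_one(self, pattern):
        entry = EntrySpec(pattern, 3.0)
        integral, _ = integrate.quad(entry.pdf, 0, 3.0)
        assert integral == pytest.approx(1.0, abs=1e-10)
        assert np.all(entry.pdf(np.linspace(0, 3, 50)) >= 0)


class TestCensoring:
    def test_admin_prob_instant_accrual(self, exp_median6):
        # everybody followed the full trial: censoring prob is S(Te)
        p = admin_censor_prob(exp_median6, EntrySpec("unif", 0.0), 26.0)
        assert p == pytest.approx(2.0 ** (-26 / 6), abs=1e-10)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_admin_prob_radiotherapy_example(self):
        law = scale_from_median(47.8)
        p = admin_censor_prob(law, EntrySpec("unif", 3.5), 12.0)
        assert p == pytest.approx(0.862, abs=0.0005)

    def test_admin_prob_tends_to_one_without_events(self):
        law = GenGammaSpec(scale=1e9)
        assert admin_censor_prob(law, EntrySpec("unif", 3.0), 5.0) > 0.999999

    def test_admin_prob_requires_te_at_least_ta(self, exp_median1):
        with pytest.raises(ValueError):
            admin_censor_prob(exp_median1, EntrySpec("unif", 6.0), 5.0)

    @pytest.mark.parametrize("family", ["unif", "exp"])
    def test_dropout_calibration_base_scenario(self, family, exp_median1,
                                               uniform_entry3, rng):
        """Re-simulated control-arm censoring fraction reproduces the 0.2 target."""
        d = solve_dropout_param(0.2, exp_median1, uniform_entry3, 5.0, family)
        n = 10**6
        v = uniform_entry3.sample(n, rng)
        t = exp_median1.rvs(n, rng)
        c = sample_censoring(d, v, rng)
        assert np.mean(c < t) == pytest.approx(0.2, abs=0.002)

    def test_dropout_calibration_radiotherapy_example(self, rng):
        law = scale_from_median(47.8)
        entry = EntrySpec("unif", 3.5)
        d = solve_dropout_param(0.902, law, entry, 12.0, "unif")
        n = 10**6
        v = entry.sample(n, rng)
        t = law.rvs(n, rng)
        c = sample_censoring(d, v, rng)
        assert np.mean(c < t) == pytest.approx(0.902, abs=0.002)

    def test_target_at_admin_floor_returns_no_dropout(self, exp_median1, uniform_entry3):
        admin = admin_censor_prob(exp_median1, uniform_entry3, 5.0)
        with pytest.warns(UserWarning, match="administrative"):
            d = solve_dropout_param(admin, exp_median1, uniform_entry3, 5.0, "unif")
        assert d.family == "none"

    def test_infeasible_target_names_both_values(self, exp_median1, uniform_entry3):
        with pytest.raises(ValueError, match="administrative-censoring floor"):
            solve_dropout_param(0.01, exp_median1, uniform_entry3, 5.0, "unif")

    def test_no_dropout_censoring_is_admin_horizon(self, rng):
        d = DropoutSpec(family="none", trial_duration=5.0)
        assert sample_censoring(d, 1.0, rng) == 4.0

    def test_exponential_atom_mass(self, rng):
        lam = 0.4
        d = DropoutSpec(family="exp", trial_duration=5.0, param=lam)
        draws = np.array([sample_censoring(d, np.zeros(10**5), rng)]).ravel()
        assert np.mean(draws == 5.0) == pytest.approx(np.exp(-lam * 5.0), abs=0.005)

    def test_uniform_support_inside_horizon_has_no_atom(self, rng):
        d = DropoutSpec(family="unif", trial_duration=5.0, param=2.0)
        draws = sample_censoring(d, np.full(1000, 1.0), rng)
        assert np.all(draws < 4.0)

    def test_entry_beyond_trial_end_rejected(self, rng):
        d = DropoutSpec(family="none", trial_duration=5.0)
        with pytest.raises(ValueError):
            sample_censoring(d, 6.0, rng)

    def test_total_censor_prob_reduces_to_admin_without_dropout(
        self, exp_median1, uniform_entry3
    ):
        d = DropoutSpec(family="none", trial_duration=5.0)
        assert total_censor_prob(exp_median1, uniform_entry3, d) == pytest.approx(
            admin_censor_prob(exp_median1, uniform_entry3, 5.0), abs=1e-8
        )


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    median=st.floats(0.2, 50),
    b=st.floats(0.5, 3),
    k=st.floats(0.5, 3),
)
def test_survival_monotone_and_median_half(median, b, k):
    spec = scale_from_median(median, b, k)
    grid = np.linspace(0, 4 * median, 64)
    s = spec.survival(grid)
    assert s[0] == 1.0
    assert np.all(np.diff(s) <= 1e-12)
    assert spec.survival(median) == pytest.approx(0.5, abs=1e-10)
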