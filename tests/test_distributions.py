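import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qalytree.distributions import (
    InfeasibleMomentsError,
    ParameterSampler,
    ParameterSpec,
    beta_from_moments,
    gamma_from_moments,
    lognormal_from_moments,
    sample,
    sample_many,
)
from qalytree.om85 import PARAMETER_TABLE


class TestBetaFromMoments:
    def test_p_repeat_row(self):
        a, b = beta_from_moments(0.20, 0.05)
        assert a == pytest.approx(12.6)
        assert b == pytest.approx(50.4)

    def test_u_base_row(self):
        a, b = beta_from_moments(0.94, 0.01)
        assert a == pytest.approx(529.22)
        assert b == pytest.approx(33.78)

    def test_infeasible_moments(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(0.5, 0.5)

    @pytest.mark.parametrize("mean,sd", [(0.0, 0.1), (1.0, 0.1), (0.5, 0.0)])
    def test_domain_errors(self, mean, sd):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_moments(mean, sd)


class TestGammaFromMoments:
    def test_drug_cost_row(self):
        shape, scale = gamma_from_moments(74.0, 18.5)
        assert shape == pytest.approx(16.0)
        assert scale == pytest.approx(4.625)

    def test_rti_cost_row(self):
        shape, scale = gamma_from_moments(2022.0, 505.0)
        assert shape == pytest.approx((2022.0 / 505.0) ** 2)
        assert scale == pytest.approx(505.0**2 / 2022.0)

    @pytest.mark.parametrize("m", [0.5, 1.0, 42.0])
    def test_unit_cv_gives_exponential(self, m):
        shape, scale = gamma_from_moments(m, m)
        assert shape == pytest.approx(1.0)
        assert scale == pytest.approx(m)

    def test_domain_errors(self):
        with pytest.raises(InfeasibleMomentsError):
            gamma_from_moments(-1.0, 1.0)
        with pytest.raises(InfeasibleMomentsError):
            gamma_from_moments(1.0, 0.0)


class TestLognormalFromMoments:
    def test_reduction_row(self):
        mu, sigma = lognormal_from_moments(0.65, 0.07)
        assert mu == pytest.approx(-0.43655, abs=5e-6)
        assert sigma == pytest.approx(0.10738, abs=5e-6)

    def test_degenerate_limit(self):
        mu, sigma = lognormal_from_moments(1.0, 1e-9)
        assert mu == pytest.approx(0.0, abs=1e-12)
        assert sigma == pytest.approx(1e-9, rel=1e-3)

    def test_unit_cv(self):
        mu, sigma = lognormal_from_moments(2.0, 2.0)
        assert sigma**2 == pytest.approx(math.log(2.0))

    def test_domain_errors(self):
        with pytest.raises(InfeasibleMomentsError):
            lognormal_from_moments(0.0, 1.0)


class TestMomentRoundTrip:
    """moments -> parameters -> analytic moments must be exact."""

    @given(
        mean=st.floats(0.01, 0.99),
        cv=st.floats(0.05, 0.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_beta_round_trip(self, mean, cv):
        sd = cv * math.sqrt(mean * (1 - mean))
        spec = ParameterSpec("x", mean, "beta", sd, kind="probability")
        m, s = spec.fit().mean_sd()
        assert m == pytest.approx(mean, rel=1e-12)
        assert s == pytest.approx(sd, rel=1e-9)

    @given(mean=st.floats(0.1, 1e5), cv=st.floats(0.01, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_gamma_round_trip(self, mean, cv):
        spec = ParameterSpec("x", mean, "gamma", cv * mean, kind="cost")
        m, s = spec.fit().mean_sd()
        assert m == pytest.approx(mean, rel=1e-12)
        assert s == pytest.approx(cv * mean, rel=1e-9)

    @given(mean=st.floats(0.1, 1e3), cv=st.floats(0.01, 2.0))
    @settings(max_examples=200, deadline=None)
    def test_lognormal_round_trip(self, mean, cv):
        spec = ParameterSpec("x", mean, "lognormal", cv * mean, kind="other")
        m, s = spec.fit().mean_sd()
        assert m == pytest.approx(mean, rel=1e-9)
        assert s == pytest.approx(cv * mean, rel=1e-9)


class TestSampling:
    def test_fixed_always_returns_base(self):
        spec = ParameterSpec("wtp", 5180.0, "fixed", 0.0, kind="wtp")
        rng = np.random.default_rng(0)
        assert all(sample(spec, rng) == 5180.0 for _ in range(10))

    def test_empirical_moments_u_rti(self):
        # the widest Table-style row: mean 0.87, sd 0.2
        spec = ParameterSpec("u_rti", 0.87, "beta", 0.2, kind="utility")
        values, clamped = sample_many(spec, np.random.default_rng(7), 200_000)
        assert clamped == 0
        assert values.mean() == pytest.approx(0.87, abs=0.002)
        assert values.std(ddof=1) == pytest.approx(0.2, abs=0.003)

    def test_determinism_same_seed_same_draws(self):
        spec = ParameterSpec("c", 2022.0, "gamma", 505.0, kind="cost")
        a, _ = sample_many(spec, np.random.default_rng(123), 1000)
        b, _ = sample_many(spec, np.random.default_rng(123), 1000)
        np.testing.assert_array_equal(a, b)

    def test_reduction_clamp_rate_matches_lognormal_tail(self):
        # P(draw > 1) = P(Z > -mu/sigma) = sf(4.065) ~ 2.4e-5, i.e. ~24
        # clamps per 10^6 draws (and usually none in a 10^4-draw PSA)
        import scipy.stats

        spec = ParameterSpec("reduction", 0.65, "lognormal", 0.07, kind="effect")
        mu, sigma = spec.fit().params
        expected = scipy.stats.norm.sf(-mu / sigma)
        with pytest.warns(RuntimeWarning, match="clamped"):
            _, clamped = sample_many(spec, np.random.default_rng(11), 1_000_000)
        assert clamped == pytest.approx(expected * 1_000_000, abs=4 * (expected * 1e6) ** 0.5)

    def test_clamping_counts_and_warns(self):
        spec = ParameterSpec("eff", 0.95, "lognormal", 0.4, kind="effect")
        with pytest.warns(RuntimeWarning, match="clamped"):
            values, clamped = sample_many(spec, np.random.default_rng(3), 10_000)
        assert clamped > 0
        assert values.max() <= 1.0

    def test_cost_draws_not_clamped_to_unit(self):
        spec = ParameterSpec("c", 2022.0, "gamma", 505.0, kind="cost")
        values, clamped = sample_many(spec, np.random.default_rng(5), 1000)
        assert clamped == 0
        assert values.max() > 1.0


class TestParameterSampler:
    def test_substreams_reproducible(self):
        specs = {s.name: s for s in PARAMETER_TABLE}
        d1 = ParameterSampler(specs, seed=42).draw(500)
        d2 = ParameterSampler(specs, seed=42).draw(500)
        for name in specs:
            np.testing.assert_array_equal(d1[name], d2[name])

    def test_parameter_stream_invariant_to_other_parameters(self):
        # dropping an unrelated parameter must not change another's draws
        specs = {s.name: s for s in PARAMETER_TABLE}
        full = ParameterSampler(specs, seed=9).draw(200)
        subset = {k: v for k, v in specs.items() if k != "u_base"}
        partial = ParameterSampler(subset, seed=9).draw(200)
        np.testing.assert_array_equal(full["c_rti"], partial["c_rti"])


def test_feasibility_screen_accepts_every_table_row():
    for spec in PARAMETER_TABLE:
        spec.fit()  # must not raise
    # the tightest case: sd^2 = 0.04 < 0.87 * 0.13 = 0.1131
    assert 0.2**2 < 0.87 * (1 - 0.87)


def test_fixed_spec_rejects_nonzero_sd():
    with pytest.raises(ValueError, match="sd 0"):
        ParameterSpec("wtp", 5180.0, "fixed", 1.0, kind="wtp")


def test_infeasible_spec_names_parameter():
    with pytest.raises(InfeasibleMomentsError, match="p_bad"):
        ParameterSpec("p_bad", 0.5, "beta", 0.5, kind="probability")


def test_dsa_bounds_must_bracket_base():
    with pytest.raises(ValueError, match="dsa_low"):
        ParameterSpec("x", 0.2, "beta", 0.05, kind="probability", dsa_low=0.3, dsa_high=0.4)
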