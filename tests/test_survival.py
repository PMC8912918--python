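"""Piecewise-exponential hazard model: likelihood closed forms, interval
bookkeeping, posterior recovery, credible intervals, rate-law helpers."""

import math

import numpy as np
import pandas as pd
import pytest

import poremap
from poremap import survival as sv
from poremap.events import events_to_frame


def make_events(times, system="s", censored=None):
    n = len(times)
    censored = [False] * n if censored is None else censored
    return pd.DataFrame({
        "membrane_id": "m", "system": system, "replica": range(n),
        "t_ns": times, "x_rel": 0.5, "y_rel": 0.5, "censored": censored})


class TestMakeIntervals:
    def test_ten_intervals_over_fifteen_ns(self):
        pts = sv.make_intervals(15.0, 1.5)
        assert len(pts) == 11
        assert pts[0] == 0.0 and pts[-1] == pytest.approx(15.0)

    def test_short_horizon_single_interval(self):
        assert np.allclose(sv.make_intervals(1.0, 1.5), [0.0, 1.0])

    def test_strictly_increasing(self):
        for horizon in (0.7, 3.0, 14.9, 15.1):
            assert (np.diff(sv.make_intervals(horizon)) > 0).all()

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            sv.make_intervals(10.0, 0.0)


class TestLoglik:
    def test_reduces_to_exponential_closed_form(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5.0, 200)
        events = make_events(t)
        endpoints = np.array([0.0, t.max() + 1])
        lam = 0.21
        ll = sv.loglik(events, endpoints, [lam], {"s": 0.0})
        assert ll == pytest.approx(200 * math.log(lam) - lam * t.sum(), rel=1e-12)

    def test_censored_observation_adds_cumulative_hazard_only(self):
        events = make_events([2.0], censored=[False])
        endpoints = np.array([0.0, 10.0])
        base = sv.loglik(events, endpoints, [0.3], {"s": 0.4})
        with_cens = sv.loglik(
            pd.concat([events, make_events([5.0], censored=[True])],
                      ignore_index=True),
            endpoints, [0.3], {"s": 0.4})
        assert with_cens - base == pytest.approx(-0.3 * 5.0 * math.exp(0.4))

    def test_zero_exposure_interval_rate_is_irrelevant(self):
        events = make_events([1.0, 2.0])
        endpoints = np.array([0.0, 5.0, 10.0])
        a = sv.loglik(events, endpoints, [0.2, 0.1], {"s": 0.0})
        b = sv.loglik(events, endpoints, [0.2, 7.3], {"s": 0.0})
        assert a == b

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(1)
        events = make_events(rng.uniform(0.5, 9.5, 40))
        endpoints = np.array([0.0, 3.0, 10.0])
        lam, beta = [0.1, 0.4], {"s": 0.2}
        whole = sv.loglik(events, endpoints, lam, beta)
        parts = (sv.loglik(events.iloc[:17], endpoints, lam, beta)
                 + sv.loglik(events.iloc[17:], endpoints, lam, beta))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_reparameterization_ridge(self):
        # lambda -> lambda/c, beta -> beta + log c leaves the likelihood fixed
        events = make_events([1.0, 4.0, 7.0])
        endpoints = np.array([0.0, 3.0, 10.0])
        c = 2.7
        a = sv.loglik(events, endpoints, [0.2, 0.5], {"s": 0.3})
        b = sv.loglik(events, endpoints, [0.2 / c, 0.5 / c],
                      {"s": 0.3 + math.log(c)})
        assert a == pytest.approx(b, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sv.loglik(make_events([1.0]), np.array([0.0, 5.0]), [-0.1], {"s": 0.0})


class TestCredibleInterval:
    def test_uniform_order_statistics(self):
        draws = np.random.default_rng(2).random(1_000_000)
        lo, hi = sv.credible_interval(draws, 0.94)
        assert lo == pytest.approx(0.03, abs=0.005)
        assert hi == pytest.approx(0.97, abs=0.005)

    def test_contains_median(self):
        draws = np.random.default_rng(3).lognormal(0, 1, 5000)
        lo, hi = sv.credible_interval(draws)
        assert lo <= np.median(draws) <= hi

    def test_point_mass_zero_width(self):
        lo, hi = sv.credible_interval(np.full(500, 2.5))
        assert lo == hi == 2.5

    def test_monotone_in_mass(self):
        draws = np.random.default_rng(4).normal(0, 1, 10000)
        widths = [np.diff(sv.credible_interval(draws, m))[0]
                  for m in (0.5, 0.8, 0.94, 0.99)]
        assert all(np.diff(widths) > 0)

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            sv.credible_interval(np.ones(200), 1.5)


@pytest.fixture(scope="module")
def two_system_posterior():
    spec = poremap.HazardSpec([0.0, 20.0], [0.25], {"a": 0.0, "b": math.log(3)},
                              censor_time=None)
    events = events_to_frame(poremap.sample_poration_dataset(spec, 300, seed=21))
    mspec = sv.HazardModelSpec(width=1.5, systems=["a", "b"])
    return events, sv.fit_hazard(events, mspec, seed=2)


class TestFitHazard:
    def test_rate_ratio_recovery(self, two_system_posterior):
        events, post = two_system_posterior
        rr = sv.rate_ratio(post, "b", "a")
        assert 2.2 <= rr["median"] <= 4.0   # truth 3, ~3 sigma band at n=300
        assert rr["interval"][0] < rr["median"] < rr["interval"][1]
        # the posterior agrees with the dataset's own exponential-MLE ratio
        sums = events.groupby("system")["t_ns"].sum()
        mle = sums["a"] / sums["b"]
        assert abs(math.log(rr["median"] / mle)) < 0.25

    def test_identity_ratio_is_one(self, two_system_posterior):
        _, post = two_system_posterior
        rr = sv.rate_ratio(post, "a", "a")
        assert np.all(rr["draws"] == 1.0)

    def test_barrier_difference_antisymmetric(self, two_system_posterior):
        _, post = two_system_posterior
        ab = sv.barrier_difference(post, "a", "b")
        ba = sv.barrier_difference(post, "b", "a")
        assert ab["median"] == pytest.approx(-ba["median"], abs=1e-12)
        # faster system b has the lower effective barrier (Delta ~ -log 3)
        assert ab["median"] > 0

    def test_two_regime_baseline_recovered(self):
        spec = poremap.HazardSpec([0.0, 3.0, 15.0], [0.0, 0.3], {"s": 0.0},
                                  censor_time=15.0)
        events = events_to_frame(poremap.sample_poration_dataset(spec, 240, seed=22))
        mspec = sv.HazardModelSpec(width=1.5, systems=["s"])
        post = sv.fit_hazard(events, mspec, seed=3)
        med = np.median(post.lambda_draws, axis=0)
        early = med[:2].max()          # intervals inside [0, 3) ns
        plateau = np.median(med[2:8])
        assert early < 0.2 * plateau   # dead time then steady-state rate
        assert plateau == pytest.approx(0.3, rel=0.35)

    def test_single_interval_matches_conjugate_gamma(self):
        rng = np.random.default_rng(23)
        t = rng.exponential(4.0, 500)
        events = make_events(t)
        mspec = sv.HazardModelSpec(endpoints=np.array([0.0, t.max() + 1]),
                                   systems=["s"])
        post = sv.fit_hazard(events, mspec, n_steps=4000, n_burn=2000, seed=4)
        # conjugate posterior Gamma(shape + n, rate + sum t)
        expected = (mspec.gamma_shape + 500) / (mspec.gamma_rate + t.sum())
        assert np.median(post.lambda_draws) == pytest.approx(expected, rel=0.05)

    def test_posterior_predictive_self_consistency(self, two_system_posterior):
        events, post = two_system_posterior
        ppc = sv.posterior_predictive(post, events, seed=0)
        assert ppc["p_value"] > 0.01
        again = sv.posterior_predictive(post, events, seed=0)
        assert np.array_equal(ppc["times"], again["times"])

    def test_no_uncensored_events_rejected(self):
        events = make_events([5.0, 6.0], censored=[True, True])
        with pytest.raises(ValueError):
            sv.fit_hazard(events)

    def test_time_varying_variant_tracks_constant_beta(self):
        spec = poremap.HazardSpec([0.0, 3.0, 15.0], [0.0, 0.25],
                                  {"a": 0.0, "b": 0.8}, censor_time=15.0)
        events = events_to_frame(poremap.sample_poration_dataset(spec, 80, seed=3))
        mspec = sv.HazardModelSpec(width=1.5, systems=["a", "b"])
        post = sv.fit_hazard(events, mspec, variant="time-varying",
                             n_steps=3000, n_burn=1500, seed=0)
        assert post.beta_time_draws.shape[1:] == (2, len(post.endpoints) - 1)
        # the random-walk beta_b(t) should track the constant truth where
        # events are plentiful (steady-state intervals)
        med = np.median(post.beta_time_draws[:, 1, 2:8], axis=0)
        assert 0.2 < med.mean() < 1.6

    def test_deterministic_given_seed(self):
        spec = poremap.HazardSpec([0.0, 20.0], [0.3], {"s": 0.0})
        events = events_to_frame(poremap.sample_poration_dataset(spec, 40, seed=24))
        mspec = sv.HazardModelSpec(systems=["s"])
        a = sv.fit_hazard(events, mspec, n_steps=800, n_burn=400, seed=6)
        b = sv.fit_hazard(events, mspec, n_steps=800, n_burn=400, seed=6)
        assert np.array_equal(a.lambda_draws, b.lambda_draws)


class TestPredictiveSimulation:
    def test_zero_hazard_leading_interval(self):
        post = sv.HazardPosterior(
            systems=["s"], endpoints=np.array([0.0, 3.0, 10.0]),
            lambda_draws=np.tile([0.0, 0.5], (200, 1)),
            beta_draws=np.zeros((200, 1)), beta_time_draws=None,
            rhat={"max": 1.0}, converged=True, variant="constant")
        events = make_events([4.0, 5.0])
        ppc = sv.posterior_predictive(post, events, seed=1)
        assert (ppc["times"] >= 3.0).all()


class TestRateLaw:
    def test_zero_barrier_zero_voltage_gives_prefactor(self):
        law = sv.RateLaw(prefactor=2.0, barrier=0.0, b_coefficient=1.0, voltage=0.0)
        assert sv.eval_rate_law(law) == 2.0

    def test_voltage_independent_when_b_zero(self):
        law = sv.RateLaw(1.0, barrier=3.0, b_coefficient=0.0, voltage=0.8)
        assert sv.eval_rate_law(law) == pytest.approx(math.exp(-3.0))

    def test_monotone_in_voltage_magnitude(self):
        rates = [sv.eval_rate_law(sv.RateLaw(1.0, 5.0, 2.0, v))
                 for v in (0.0, 0.5, 1.0, 1.5)]
        assert all(np.diff(rates) > 0)


class TestE2Response:
    def test_exact_quadratic_recovered(self):
        E = np.array([0.0, 42.5, 63.8, 85.1, 106.3])
        fit = sv.fit_e2_response(E, -3e-5 * E ** 2)
        assert fit["slope"] == pytest.approx(-3e-5, rel=1e-12)
        assert np.allclose(fit["residuals"], 0.0)

    def test_noise_stderr_matches_sampling(self):
        rng = np.random.default_rng(7)
        E = np.array([0.0, 42.5, 63.8, 85.1, 106.3])
        sigma = 0.01
        slopes = [sv.fit_e2_response(E, 2e-5 * E ** 2
                                     + rng.normal(0, sigma, len(E)))["slope"]
                  for _ in range(300)]
        theory = sigma / math.sqrt(((E ** 2) ** 2).sum())
        assert np.std(slopes) == pytest.approx(theory, rel=0.15)

    def test_requires_zero_field_reference(self):
        with pytest.raises(ValueError):
            sv.fit_e2_response([10.0, 20.0, 30.0], [1.0, 4.0, 9.0])

    def test_beta_response_correlation(self):
        betas = np.array([0.0, 1.1, -0.7, -0.5])
        slopes = 0.5 * betas + np.array([0.01, -0.02, 0.015, 0.0])
        out = sv.beta_response_correlation(betas, slopes)
        assert out["pearson_r"] > 0.95
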