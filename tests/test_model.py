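"""Core latency-learning model: analytics, updates, likelihood, simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from postlearn.model import (
    AgentParams,
    ModelState,
    PostTimeline,
    mean_latency,
    negative_log_likelihood,
    optimal_latency,
    prediction_error,
    simulate_agent,
    trace_from_timeline,
    update_state,
)


def params(**kw):
    kw.setdefault("alpha", 0.1)
    kw.setdefault("P", 3.0)
    kw.setdefault("C", 1.0)
    return AgentParams(**kw)


class TestMeanLatency:
    @pytest.mark.parametrize(
        "policy, alpha, rbar, expected",
        [
            (math.log(48.0), 0.1, 0.0, 48.0),  # no reward-rate term
            (3.0, 0.1, 2.0, math.exp(2.8)),
        ],
    )
    def test_exponent_identity(self, policy, alpha, rbar, expected):
        st_ = ModelState(policy=policy, rbar=rbar)
        assert mean_latency(st_, params(alpha=alpha)) == pytest.approx(expected)

    def test_null_model_is_constant(self):
        p = AgentParams(P=math.log(24.0), variant="null_no_learning")
        for pol, rb in [(0.0, 0.0), (5.0, -3.0), (-2.0, 10.0)]:
            assert mean_latency(ModelState(policy=pol, rbar=rb), p) == pytest.approx(24.0)

    def test_overflow_clamped_with_warning(self):
        st_ = ModelState(policy=100.0, rbar=0.0)
        with pytest.warns(RuntimeWarning):
            mu = mean_latency(st_, params())
        assert np.isfinite(mu) and mu > 0


class TestPredictionError:
    @pytest.mark.parametrize(
        "variant, R, C, tau, rbar, expected",
        [
            ("rbar_full", 5.0, 2.0, 2.0, 1.0, 2.0),       # 5 - 1 - 2
            ("rbar_full", 3.0, 4.0, 0.5, 2.0, -6.0),      # 3 - 8 - 1
            ("no_effort_cost", 0.0, 1.0, 2.0, 0.0, 0.0),  # no reward, no cost
            ("no_effort_cost", 5.0, 99.0, 2.0, 1.0, 3.0),
            ("fixed_effort_cost", 5.0, 2.0, 2.0, 1.0, 1.0),
            ("increasing_effort_cost", 5.0, 2.0, 2.0, 1.0, -1.0),
            ("pavlovian_only", 5.0, 2.0, 2.0, 1.0, 2.0),
        ],
    )
    def test_variants(self, variant, R, C, tau, rbar, expected):
        p = params(C=C, variant=variant)
        st_ = ModelState(policy=1.0, rbar=rbar)
        assert prediction_error(R, tau, st_, p) == pytest.approx(expected)

    def test_nonpositive_latency_rejected(self):
        with pytest.raises(ValueError):
            prediction_error(1.0, 0.0, ModelState(policy=1.0), params())

    @given(
        R=st.floats(0, 50), C=st.floats(0.01, 50), tau=st.floats(0.01, 200),
        rbar=st.floats(-10, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_decomposition_identity(self, R, C, tau, rbar):
        """delta + C/tau + rbar*tau recovers the reward exactly (full model)."""
        d = prediction_error(R, tau, ModelState(policy=0.0, rbar=rbar),
                             params(C=C))
        assert d + C / tau + rbar * tau == pytest.approx(R, rel=1e-9, abs=1e-9)


class TestUpdateState:
    def test_policy_gradient_step(self):
        st_ = ModelState(policy=3.0, rbar=0.0)
        new = update_state(st_, 4.0, 5.0, 2.0, params(alpha=0.1))
        assert new.policy == pytest.approx(2.8)

    def test_zero_error_is_fixed_point(self):
        st_ = ModelState(policy=3.0, rbar=1.5, t=4)
        new = update_state(st_, 4.0, 5.0, 0.0, params(alpha=0.5))
        assert (new.policy, new.rbar) == (3.0, 1.5)
        assert new.t == 5

    def test_reward_rate_update(self):
        st_ = ModelState(policy=0.0, rbar=1.0)
        new = update_state(st_, 1.0, 1.0, -2.0, params(alpha=0.5))
        assert new.rbar == pytest.approx(0.0)

    def test_first_step_skips_policy_update(self):
        st_ = ModelState(policy=3.0, rbar=0.0)
        new = update_state(st_, 4.0, None, 2.0, params(alpha=0.1))
        assert new.policy == 3.0  # gradient needs two latencies
        assert new.rbar == pytest.approx(0.2)

    def test_pavlovian_policy_frozen(self):
        p = params(variant="pavlovian_only")
        st_ = ModelState(policy=p.P, rbar=0.0)
        new = update_state(st_, 4.0, 5.0, 2.0, p)
        assert new.policy == p.P
        assert new.rbar != 0.0


class TestOptimalLatency:
    @pytest.mark.parametrize("C, rbar, expected", [(4, 1, 2.0), (1, 1, 1.0), (1, 4, 0.5)])
    def test_closed_form(self, C, rbar, expected):
        assert optimal_latency(C, rbar) == pytest.approx(expected)

    def test_matches_grid_maximization(self, rng):
        """sqrt(C/rbar) agrees with brute-force maximization of the net
        reward over a fine latency grid, within 1%, for 100 random pairs."""
        for _ in range(100):
            C = float(10 ** rng.uniform(-1, 1.5))
            rbar = float(10 ** rng.uniform(-2, 1))
            grid = np.geomspace(1e-3, 1e4, 200_000)
            delta = 5.0 - C / grid - rbar * grid
            tau_grid = grid[np.argmax(delta)]
            assert optimal_latency(C, rbar) == pytest.approx(tau_grid, rel=0.01)

    def test_decreasing_in_reward_rate(self):
        taus = [optimal_latency(2.0, r) for r in (0.1, 0.5, 1.0, 5.0)]
        assert all(a > b for a, b in zip(taus, taus[1:]))

    def test_no_finite_optimum_without_positive_rate(self):
        with pytest.raises(ValueError):
            optimal_latency(1.0, 0.0)
        with pytest.raises(ValueError):
            optimal_latency(0.0, 1.0)


class TestLikelihood:
    def test_null_closed_form(self):
        tau = np.array([10.0, 20.0, 30.0])
        tl = PostTimeline("u", np.concatenate([[0.0], np.cumsum(tau)]),
                          np.zeros(4))
        p = AgentParams(P=math.log(20.0), variant="null_no_learning")
        nll = negative_log_likelihood(p, tl, enforce_min_posts=False)
        assert nll == pytest.approx(3 * math.log(20.0) + 3.0, abs=1e-9)

    def test_null_mle_at_mean_latency(self, null_timeline):
        tau = null_timeline.latencies
        P_hat = math.log(tau.mean())
        best = negative_log_likelihood(
            AgentParams(P=P_hat, variant="null_no_learning"), null_timeline)
        for dP in (-0.2, -0.01, 0.01, 0.2):
            other = negative_log_likelihood(
                AgentParams(P=P_hat + dP, variant="null_no_learning"),
                null_timeline)
            assert other > best

    def test_full_model_nests_null(self, null_timeline):
        """As the learning rate vanishes the full model reproduces the
        no-learning likelihood exactly."""
        P = math.log(20.0)
        nll_null = negative_log_likelihood(
            AgentParams(P=P, variant="null_no_learning"), null_timeline)
        nll_full = negative_log_likelihood(
            AgentParams(alpha=1e-12, P=P, C=1.0), null_timeline)
        assert nll_full == pytest.approx(nll_null, abs=1e-7)

    def test_trace_reproduces_likelihood(self, small_learning_cohort):
        """The forward trace and the compiled likelihood kernel implement
        the same recursion."""
        tl = small_learning_cohort.timelines[0]
        p = small_learning_cohort.true_params[0]
        trace = trace_from_timeline(p, tl)
        nll_trace = float(np.sum(np.log(trace.mu) + trace.tau / trace.mu))
        assert nll_trace == pytest.approx(
            negative_log_likelihood(p, tl), rel=1e-10)

    def test_min_posts_enforced(self):
        tl = PostTimeline("u", np.array([0.0, 1.0, 2.0]), np.zeros(3))
        with pytest.raises(ValueError, match="10 posts"):
            negative_log_likelihood(params(), tl)


class TestSimulateAgent:
    def test_null_agent_sample_mean(self):
        p = AgentParams(P=math.log(24.0), variant="null_no_learning")
        trace = simulate_agent(p, lambda i, t: 0.0, 4000, seed=1)
        assert trace.tau.mean() == pytest.approx(24.0, rel=0.05)

    def test_vanishing_learning_rate_matches_null(self):
        reward = lambda i, t: 5.0
        t_full = simulate_agent(params(alpha=1e-12, P=3.0), reward, 200, seed=7)
        p_null = AgentParams(P=3.0, variant="null_no_learning")
        t_null = simulate_agent(p_null, reward, 200, seed=7)
        np.testing.assert_allclose(t_full.tau, t_null.tau, rtol=1e-6)

    def test_bit_reproducible(self):
        p = params(alpha=1e-3)
        a = simulate_agent(p, lambda i, t: float(i % 7), 300, seed=42)
        b = simulate_agent(p, lambda i, t: float(i % 7), 300, seed=42)
        np.testing.assert_array_equal(a.tau, b.tau)
        np.testing.assert_array_equal(a.rbar, b.rbar)

    def test_higher_reward_rate_shortens_latency(self):
        """Directional vigor prediction: richer like rates produce shorter
        mean latencies (paired seeds, full model)."""
        diffs = []
        for s in range(8):
            p = AgentParams(alpha=3e-4, P=math.log(24.0), C=1.0)
            rng_lo = np.random.default_rng(1000 + s)
            rng_hi = np.random.default_rng(1000 + s)
            lo = simulate_agent(p, lambda i, t: float(rng_lo.poisson(1.0)), 300,
                                seed=s)
            hi = simulate_agent(p, lambda i, t: float(rng_hi.poisson(10.0)), 300,
                                seed=s)
            diffs.append(np.log(lo.tau.mean()) - np.log(hi.tau.mean()))
        assert np.mean(diffs) > 0


class TestValidation:
    def test_timestamps_must_increase(self):
        with pytest.raises(ValueError):
            PostTimeline("u", np.array([0.0, 2.0, 2.0]), np.zeros(3))

    def test_likes_nonnegative(self):
        with pytest.raises(ValueError):
            PostTimeline("u", np.array([0.0, 1.0]), np.array([1.0, -2.0]))

    @pytest.mark.parametrize(
        "kw",
        [dict(alpha=0.0), dict(alpha=1.5), dict(C=0.0), dict(C=-1.0),
         dict(P=-0.1), dict(variant="nope")],
    )
    def test_parameter_bounds(self, kw):
        with pytest.raises(ValueError):
            params(**kw)

    def test_null_model_ignores_learning_bounds(self):
        AgentParams(P=1.0, variant="null_no_learning")  # only P constrained
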