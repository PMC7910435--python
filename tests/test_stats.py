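"""Reward-sensitivity statistics: dichotomization, law of effect,
panel Granger causality, and the latency mixed models."""

import numpy as np
import pandas as pd
import pytest

from postlearn.simulate import CohortSpec, generate_cohort
from postlearn.stats import (
    PanelSeries,
    build_panel,
    build_regression_table,
    calibrate_granger_lags,
    dichotomize_rbar,
    fit_rate_reward,
    law_of_effect,
    mixed_model_latency,
    panel_granger,
)


class TestDichotomize:
    @pytest.mark.parametrize("n", [5, 7, 11])
    def test_odd_monotone_split(self, n):
        low = dichotomize_rbar(np.arange(n, dtype=float))
        # median rank standardizes to exactly 0 -> Low by the tie rule
        assert (low == 0).sum() == n // 2

    def test_reversal_flips_labels(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert np.array_equal(dichotomize_rbar(x), 1 - dichotomize_rbar(-x))

    def test_even_distinct_balanced(self):
        low = dichotomize_rbar(np.array([4.0, 1.0, 3.0, 2.0]))
        assert low.sum() == 2

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_rbar(np.ones(8))


class TestLawOfEffect:
    def test_exact_hyperbola(self):
        r = np.linspace(0.5, 20, 12)
        rate = 3.0 * r / (r + 4.0)
        out = fit_rate_reward(r, rate)
        assert out["R2_hyperbolic"] == pytest.approx(1.0, abs=1e-6)
        assert out["R2_hyperbolic"] > out["R2_linear"]

    def test_exact_line(self):
        r = np.linspace(0.5, 20, 12)
        out = fit_rate_reward(r, 0.3 + 0.1 * r)
        assert out["R2_linear"] == pytest.approx(1.0, abs=1e-12)

    def test_time_unit_invariance(self):
        """Rescaling hours to minutes rescales both rates; the hyperbolic
        R^2 is unchanged."""
        rng = np.random.default_rng(1)
        r = np.linspace(0.5, 10, 10)
        rate = 2.0 * r / (r + 3.0) + rng.normal(0, 0.05, 10)
        a = fit_rate_reward(r, rate)
        b = fit_rate_reward(r * 60.0, rate * 60.0)
        assert a["R2_hyperbolic"] == pytest.approx(b["R2_hyperbolic"], abs=1e-5)
        assert 0.0 <= a["R2_hyperbolic"] <= 1.0

    def test_windowing_and_skips(self, small_null_cohort):
        tl = small_null_cohort.timelines[0]
        out = law_of_effect(tl, window=10)
        assert out is None or 0 <= out["R2_hyperbolic"] <= 1
        assert law_of_effect(tl, window=40) is None  # too few bins


class TestPanelGranger:
    def _iid_panel(self, n_users=40, T=80, lag=1, seed=0):
        rng = np.random.default_rng(seed)
        dt = [rng.normal(size=T) for _ in range(n_users)]
        dl = [rng.normal(size=T) for _ in range(n_users)]
        return PanelSeries(dtau=dt, dlikes=dl, lag=lag)

    def test_independent_series_not_rejected(self):
        res = panel_granger(self._iid_panel(seed=3))
        assert res["p"] > 0.01
        assert 0.0 <= res["user_rejection_rate"] <= 0.15

    def test_lagged_copy_detected(self):
        """A latency series that is a lagged copy of likes is maximal
        Granger causality."""
        rng = np.random.default_rng(5)
        dt, dl = [], []
        for _ in range(20):
            x = rng.normal(size=81)
            y = np.empty(81)
            y[1:] = x[:-1]
            y[0] = rng.normal()
            dl.append(x)
            dt.append(y + rng.normal(0, 1e-3, 81))
        res = panel_granger(PanelSeries(dtau=dt, dlikes=dl, lag=1))
        assert res["p"] < 1e-10 and res["Zbar_tilde"] > 10

    def test_type_one_error_in_band(self, ):
        """Per-user rejection rate on a no-learning cohort stays near the
        nominal level (wide band for this reduced-size check)."""
        cohort = generate_cohort(
            CohortSpec(n_users=400, posts_per_user=60,
                       variant="null_no_learning", seed=77))
        res = panel_granger(build_panel(cohort.timelines, 1))
        assert 0.02 <= res["user_rejection_rate"] <= 0.10

    def test_augmented_own_lags_remove_panel_bias(self):
        """First-differencing leaves MA structure that inflates the panel
        statistic; augmenting the own-lag order removes the inflation."""
        cohort = generate_cohort(
            CohortSpec(n_users=600, posts_per_user=60,
                       variant="null_no_learning", seed=78))
        plain = panel_granger(build_panel(cohort.timelines, 1))
        aug = panel_granger(build_panel(cohort.timelines, 1), y_lags=8)
        assert abs(aug["Zbar_tilde"]) < abs(plain["Zbar_tilde"])
        assert abs(aug["Zbar_tilde"]) < 2.5

    def test_length_rule_drops_short_users(self):
        panel = self._iid_panel(n_users=5, T=80, lag=1)
        panel.dtau.append(np.ones(3))
        panel.dlikes.append(np.ones(3))
        res = panel_granger(panel)
        assert res["n_users"] == 5 and res["n_dropped"] == 1


class TestCalibrateLags:
    def test_null_vs_null_reports_no_qualifying_lag(self):
        cohort_a = generate_cohort(
            CohortSpec(n_users=60, posts_per_user=60,
                       variant="null_no_learning", seed=5))
        cohort_b = generate_cohort(
            CohortSpec(n_users=60, posts_per_user=60,
                       variant="null_no_learning", seed=6))
        chosen, report = calibrate_granger_lags(
            cohort_a.timelines, cohort_b.timelines, [1, 2, 3],
            subpanel_size=20)
        assert len(report) == 3
        assert set(report.columns) >= {"lag", "power", "fpr"}
        # exchangeable cohorts: power cannot systematically exceed FPR
        if chosen is not None:
            row = report[report.lag == chosen].iloc[0]
            assert row.power <= row.fpr + 0.35

    def test_report_rows_match_candidates(self):
        cohort = generate_cohort(
            CohortSpec(n_users=40, posts_per_user=60,
                       variant="null_no_learning", seed=7))
        _, report = calibrate_granger_lags(
            cohort.timelines, cohort.timelines, [1, 4], subpanel_size=20)
        assert list(report["lag"]) == [1, 4]


class TestMixedModel:
    def _synthetic_table(self, beta=0.2, n_users=40, n_obs=60, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for u in range(n_users):
            icpt = rng.normal(0, 0.5)
            low = rng.integers(0, 2, n_obs)
            rows.append(pd.DataFrame({
                "user_id": f"u{u}",
                "log_tau": icpt + beta * low + rng.normal(0, 0.5, n_obs),
                "low_prev": low,
                "rbar_z_prev": -low + rng.normal(0, 0.1, n_obs),
                "likes_prev": rng.normal(size=n_obs),
                "post_number": np.linspace(-1, 1, n_obs),
                "weekday": rng.integers(0, 7, n_obs),
            }))
        return pd.concat(rows, ignore_index=True)

    def test_recovers_generative_effect(self):
        data = self._synthetic_table(beta=0.2, seed=1)
        res = mixed_model_latency(data)
        se = float(res.table.set_index("term").loc["low_prev", "se"])
        assert res.coef("low_prev") == pytest.approx(0.2, abs=3 * se + 0.02)
        assert res.percent_effect == pytest.approx(np.exp(0.2) - 1, abs=0.05)
        assert res.aic_weight > 0.95

    def test_zero_effect_calibration(self):
        """Without a true effect the |z| statistic exceeds 2 only at the
        nominal rate."""
        hits = 0
        for s in range(25):
            data = self._synthetic_table(beta=0.0, n_users=15, n_obs=30, seed=s)
            res = mixed_model_latency(data, covariates=False)
            z = float(res.table.set_index("term").loc["low_prev", "z"])
            hits += abs(z) > 2
        assert hits <= 4

    def test_continuous_term_has_opposite_sign(self):
        data = self._synthetic_table(beta=0.25, seed=2)
        dich = mixed_model_latency(data)
        cont = mixed_model_latency(data, rbar_term="continuous")
        assert dich.coef("low_prev") > 0 > cont.coef("rbar_z_prev")

    def test_interaction_with_model_fit_weight(self):
        data = self._synthetic_table(beta=0.2, seed=3)
        rng = np.random.default_rng(9)
        aicw = pd.Series(rng.uniform(0.3, 0.95, 40),
                         index=[f"u{u}" for u in range(40)])
        res = mixed_model_latency(data, aicw=aicw)
        assert "low_prev:aicw_c" in set(res.table["term"])

    def test_needs_two_users(self):
        data = self._synthetic_table(n_users=1, seed=4)
        with pytest.raises(ValueError):
            mixed_model_latency(data)


class TestRegressionTable:
    def test_alignment_and_standardization(self, small_learning_cohort):
        traces = small_learning_cohort.traces
        ids = [tl.user_id for tl in small_learning_cohort.timelines]
        tab = build_regression_table(traces, ids)
        assert {"user_id", "log_tau", "low_prev", "likes_prev",
                "post_number", "weekday"} <= set(tab.columns)
        g = tab.groupby("user_id")
        # within-user standardization: mean ~ 0, sd ~ 1
        assert np.allclose(g["likes_prev"].mean(), 0, atol=1e-9)
        m = len(traces[0])
        assert g.size().iloc[0] == m - 1  # one row per lagged latency
        # the indicator is lagged: row t uses rbar at t-1
        tr = traces[0]
        from postlearn.stats import dichotomize_rbar as d

        np.testing.assert_array_equal(
            tab[tab.user_id == ids[0]]["low_prev"].to_numpy(),
            d(tr.rbar)[:-1])
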