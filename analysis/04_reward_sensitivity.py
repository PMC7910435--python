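"""Reward-sensitivity analyses of the simulated cohorts.

Three analyses: (1) the dichotomized average-reward-rate mixed model on
the default generative cohort — the headline simulation effect (~18%
longer latencies under a low subjective reward rate); (2) the law of
effect across interval schedules (hyperbolic vs linear rate-reward law);
(3) the panel Granger causality calibration, which on this clean
generative family is an honest negative: the whitened panel test has
little power because likes add no linear predictive information beyond
the latency series' own past (see docs/methods.md).
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from postlearn.model import AgentParams
from postlearn.simulate import (
    CohortSpec,
    STRONG_LEARNING_DISTRIBUTIONS,
    generate_cohort,
    generate_schedule_curve,
)
from postlearn.stats import (
    build_panel,
    build_regression_table,
    calibrate_granger_lags,
    fit_rate_reward,
    mixed_model_latency,
    panel_granger,
)

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

# -- 1. dichotomized reward-rate effect ------------------------------------
cohort = generate_cohort(CohortSpec(n_users=500, posts_per_user=250, seed=31))
keep = [i for i, tr in enumerate(cohort.traces) if not tr.diverged]
table = build_regression_table([cohort.traces[i] for i in keep],
                               [cohort.timelines[i].user_id for i in keep])
mm = mixed_model_latency(table, covariates=False)
beta = mm.coef("low_prev")
print(f"low-vs-high reward rate on log latency: beta = {beta:.3f} "
      f"({mm.percent_effect:+.1%} latency when low)")
mm.table.to_csv(OUT / "reward_rate_mixed_model.csv", index=False)

# -- 2. law of effect across interval schedules ----------------------------
rng = np.random.default_rng(32)
r2 = []
for u in range(40):
    p = AgentParams(
        alpha=float(np.exp(rng.uniform(math.log(2e-4), math.log(6e-4)))),
        P=float(rng.uniform(math.log(8.0), math.log(24.0))),
        C=float(np.exp(rng.uniform(math.log(0.3), math.log(1.0)))))
    out = generate_schedule_curve(p, np.geomspace(8, 0.4, 8), seed=2000 + u)
    if out is None:
        continue
    f = fit_rate_reward(*out)
    r2.append({"agent": u, "R2_hyperbolic": f["R2_hyperbolic"],
               "R2_linear": f["R2_linear"]})
law = pd.DataFrame(r2)
law.to_csv(OUT / "law_of_effect.csv", index=False)
print(f"law of effect over {len(law)} agents: mean R2 hyperbolic "
      f"{law['R2_hyperbolic'].mean():.3f} vs linear "
      f"{law['R2_linear'].mean():.3f}")

# -- 3. Granger causality calibration --------------------------------------
null = generate_cohort(CohortSpec(n_users=2000, posts_per_user=60,
                                  variant="null_no_learning", seed=33))
panel = build_panel(null.timelines, 1)
raw = panel_granger(panel)["user_rejection_rate"]
aug = panel_granger(panel, y_lags=8)["user_rejection_rate"]
print(f"Granger type-I error on 2000 null users: {aug:.3f} whitened "
      f"({raw:.3f} with the classical common-lag regression; nominal 0.05)")

learn = generate_cohort(CohortSpec(
    n_users=600, posts_per_user=200,
    param_distributions=dict(STRONG_LEARNING_DISTRIBUTIONS),
    like_process="poisson_drift", poisson_lambda=20.0, drift_sd=0.6,
    drift_corr=20.0, seed=34))
keep_tl = [tl for tl, tr in zip(learn.timelines, learn.traces)
           if not tr.diverged]
null2 = generate_cohort(CohortSpec(
    n_users=600, posts_per_user=200, variant="null_no_learning",
    like_process="poisson_drift", poisson_lambda=20.0, drift_sd=0.6,
    drift_corr=20.0, seed=35))
chosen, report = calibrate_granger_lags(keep_tl, null2.timelines, [1, 2, 3],
                                        subpanel_size=100)
report.to_csv(OUT / "granger_calibration.csv", index=False)
print(f"calibrated lag: {chosen}")
print(report.to_string(index=False))
print("\nThe type-I error is controlled, but the honestly-whitened panel "
      "test has limited power against this generative family: the "
      "latency series' own past already carries the reward-rate state, "
      "so lagged likes add little linear information.")
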