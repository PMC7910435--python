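"""End-to-end orchestration of the analysis chain.

A pipeline run takes timelines (from files or a synthetic cohort spec),
applies the inclusion filters, fits and compares the latency models per
user, runs the reward-sensitivity statistics and the phenotyping, and
writes machine-readable JSON plus a human-readable Markdown summary with
full provenance (resolved config and seeds).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from postlearn import io as plio
from postlearn import stats as plstats
from postlearn.fitting import FitOptions, fit_models, group_bms
from postlearn.model import (
    MIN_POSTS,
    AgentParams,
    PostTimeline,
    trace_from_timeline,
)
from postlearn.phenotyping import cluster_parameters, stability_report
from postlearn.simulate import CohortSpec, generate_cohort

logger = logging.getLogger("postlearn.pipeline")

__all__ = [
    "PipelineConfig",
    "apply_filters",
    "run_full_analysis",
    "run_experiment_analysis",
]


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run (serialized next to outputs)."""

    input_path: str | None = None
    cohort: CohortSpec | None = None
    min_posts: int = MIN_POSTS
    decile_filter_mean_tau: bool = False
    decile_filter_post_count: bool = False
    drop_divergent: bool = True
    partitions: int = 1
    models: tuple[str, ...] = ("null_no_learning", "rbar_full")
    granger_lag: int = 1
    law_window: int = 10
    fit_starts: int = 10
    seed: int = 0
    output_dir: str = "results/pipeline"

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


def apply_filters(
    timelines: list[PostTimeline], config: PipelineConfig
) -> tuple[list[PostTimeline], pd.DataFrame]:
    """Deterministic inclusion filtering with a full exclusion ledger.

    Rules, in order: minimum post count (default 10); optionally, removal
    of users whose mean latency falls outside the 20th-80th percentile
    band of the cohort; optionally the same for post counts.  The ledger
    has one row per excluded user with the rule that fired; retained +
    excluded always equals the input count.
    """
    ledger = []
    kept = []
    for tl in timelines:
        if tl.n_posts < config.min_posts:
            ledger.append({"user_id": tl.user_id, "rule": "min_posts",
                           "value": tl.n_posts})
        else:
            kept.append(tl)
    if config.decile_filter_mean_tau and kept:
        mt = np.array([tl.latencies.mean() for tl in kept])
        lo, hi = np.percentile(mt, [20, 80])
        nxt = []
        for tl, m in zip(kept, mt):
            if lo < m < hi:
                nxt.append(tl)
            else:
                ledger.append({"user_id": tl.user_id,
                               "rule": "mean_tau_decile", "value": m})
        kept = nxt
    if config.decile_filter_post_count and kept:
        nc = np.array([tl.n_posts for tl in kept])
        lo, hi = np.percentile(nc, [20, 80])
        nxt = []
        for tl, c in zip(kept, nc):
            if lo < c < hi:
                nxt.append(tl)
            else:
                ledger.append({"user_id": tl.user_id,
                               "rule": "post_count_decile", "value": c})
        kept = nxt
    ledger_df = pd.DataFrame(ledger, columns=["user_id", "rule", "value"])
    assert len(kept) + len(ledger_df) == len(timelines)
    return kept, ledger_df


def _stage(name: str):
    logger.info("stage=%s", name)


def run_full_analysis(config: PipelineConfig, write: bool = True) -> dict:
    """Run the full chain: ingest, filter, fit, compare, regress, stats,
    phenotype; returns the report dict and optionally writes artifacts.

    Stage failures raise with a stage-tagged error; partial outputs
    written so far are left in place.
    """
    out = Path(config.output_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
    report: dict = {"config": json.loads(config.to_json()), "stages": {}}

    stage = "ingest"
    try:
        _stage(stage)
        traces = None
        if config.cohort is not None:
            cohort = generate_cohort(config.cohort)
            timelines = cohort.timelines
            traces = {tl.user_id: tr for tl, tr in zip(cohort.timelines, cohort.traces)}
            if config.drop_divergent:
                ok = [tl.user_id for tl in timelines if not traces[tl.user_id].diverged]
                report["stages"]["ingest"] = {
                    "n_divergent_dropped": len(timelines) - len(ok)}
                timelines = [tl for tl in timelines if tl.user_id in set(ok)]
        elif config.input_path is not None:
            timelines = plio.read_timelines(config.input_path)
        else:
            raise ValueError("config needs input_path or cohort")

        stage = "filter"
        _stage(stage)
        timelines, ledger = apply_filters(timelines, config)
        report["stages"]["filter"] = {
            "n_retained": len(timelines), "n_excluded": len(ledger)}
        if write:
            ledger.to_csv(out / "exclusions.csv", index=False)

        stage = "fit"
        _stage(stage)
        opts = FitOptions(n_starts=config.fit_starts, seed=config.seed)
        fits = [fit_models(tl, config.models, opts) for tl in timelines]
        aic = np.array([[fr.entries[m].aic for m in config.models] for fr in fits])
        finite = np.isfinite(aic).all(axis=1)
        aic = aic[finite]
        fits = [f for f, ok in zip(fits, finite) if ok]
        timelines = [t for t, ok in zip(timelines, finite) if ok]

        stage = "compare"
        _stage(stage)
        gc = group_bms(aic, config.models, seed=config.seed)
        report["stages"]["compare"] = json.loads(
            gc.as_frame().to_json(orient="records"))
        if config.partitions > 1 and len(aic) >= 2 * config.partitions:
            # robustness: the comparison repeated on equal user partitions
            parts = np.array_split(np.arange(len(aic)), config.partitions)
            report["stages"]["compare_partitions"] = [
                json.loads(group_bms(aic[idx], config.models,
                                     seed=config.seed).as_frame()
                           .to_json(orient="records"))
                for idx in parts
            ]

        stage = "mixed_model"
        _stage(stage)
        # latent reward-rate series under each user's fitted full model
        full = "rbar_full"
        rbar_traces = []
        ids = []
        for fr, tl in zip(fits, timelines):
            e = fr.entries.get(full)
            if e is None or e.failed:
                continue
            rbar_traces.append(trace_from_timeline(e.params, tl))
            ids.append(tl.user_id)
        table = plstats.build_regression_table(rbar_traces, ids)
        mm = plstats.mixed_model_latency(table)
        aicw_full = pd.Series({fr.user_id: fr.aic_w.get(full, np.nan) for fr in fits})
        report["stages"]["mixed_model"] = {
            "beta_low_rbar": mm.coef("low_prev"),
            "percent_effect": mm.percent_effect,
            "aic_weight_vs_covariates_only": mm.aic_weight,
            "table": json.loads(mm.table.to_json(orient="records")),
        }

        stage = "law_of_effect"
        _stage(stage)
        law = plstats.cohort_law_of_effect(timelines, window=config.law_window)
        if len(law):
            report["stages"]["law_of_effect"] = {
                "n_users": int(len(law)),
                "mean_R2_hyperbolic": float(law["R2_hyperbolic"].mean()),
                "mean_R2_linear": float(law["R2_linear"].mean()),
            }

        stage = "granger"
        _stage(stage)
        panel = plstats.build_panel(timelines, config.granger_lag)
        granger = plstats.panel_granger(panel)
        report["stages"]["granger"] = {
            k: granger[k] for k in
            ("Zbar_tilde", "p", "n_users", "n_dropped", "lag",
             "user_rejection_rate")
        }

        stage = "phenotype"
        _stage(stage)
        params_rows = {
            fr.user_id: fr.entries[full].params
            for fr in fits
            if full in fr.entries and not fr.entries[full].failed
        }
        if len(params_rows) >= 10:
            ptab = pd.DataFrame(
                {"alpha": [p.alpha for p in params_rows.values()],
                 "P": [p.P for p in params_rows.values()],
                 "C": [p.C for p in params_rows.values()]},
                index=list(params_rows.keys()),
            )
            sol = cluster_parameters(ptab, k_range=(2, 6), seed=config.seed,
                                     n_init=10)
            boot = stability_report(ptab, sol, n_boot=20, seed=config.seed)
            report["stages"]["phenotype"] = {
                "k": sol.k,
                "votes": sol.criteria_votes,
                "mean_bootstrap_ari": boot.attrs.get("mean_ari"),
            }
            if write:
                pd.DataFrame({"user_id": ptab.index,
                              "cluster": sol.assignments}).to_csv(
                    out / "phenotype_assignments.csv", index=False)
                sol.profiles.to_csv(out / "phenotype_profiles.csv")
                pd.DataFrame(sol.pca_scores, columns=["pc1", "pc2"]).to_csv(
                    out / "phenotype_pca.csv", index=False)
    except Exception as err:  # noqa: BLE001 - stage tagging then re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    if write:
        plio.write_json(report, out / "report.json")
        (out / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict) -> str:
    lines = ["# Pipeline report", ""]
    st = report["stages"]
    if "filter" in st:
        lines.append(f"- Retained {st['filter']['n_retained']} users "
                     f"({st['filter']['n_excluded']} excluded).")
    if "compare" in st:
        for row in st["compare"]:
            lines.append(
                f"- Model `{row['model']}`: mean AIC weight "
                f"{row['mean_aicw']:.3f}, xp {row['xp']:.3f}, "
                f"best for {row['best_proportion']:.1%} of users.")
    if "mixed_model" in st:
        mm = st["mixed_model"]
        lines.append(
            f"- Low-vs-high reward-rate effect on log latency: "
            f"beta = {mm['beta_low_rbar']:.3f} "
            f"({mm['percent_effect']:+.1%} latency when the rate is low).")
    if "law_of_effect" in st:
        le = st["law_of_effect"]
        lines.append(
            f"- Law of effect: mean R2 hyperbolic {le['mean_R2_hyperbolic']:.3f}"
            f" vs linear {le['mean_R2_linear']:.3f} over {le['n_users']} users.")
    if "granger" in st:
        g = st["granger"]
        lines.append(
            f"- Panel Granger (lag {g['lag']}): Z = {g['Zbar_tilde']:.2f}, "
            f"p = {g['p']:.3g}, user rejection rate "
            f"{g['user_rejection_rate']:.3f}.")
    if "phenotype" in st:
        ph = st["phenotype"]
        lines.append(f"- Phenotypes: k = {ph['k']} (votes {ph['votes']}), "
                     f"bootstrap ARI {ph['mean_bootstrap_ari']}.")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# two-block experiment analysis
# ---------------------------------------------------------------------------

#: reference parameters (minute scale) used to derive subjective
#: reward-rate series from observed experiment sessions
EXPERIMENT_REFERENCE_PARAMS = AgentParams(alpha=5e-3, P=float(np.log(2.0)), C=5.0)


def run_experiment_analysis(
    log: pd.DataFrame,
    min_posts: int = 5,
    min_posts_model: int = 10,
    reference_params: AgentParams = EXPERIMENT_REFERENCE_PARAMS,
) -> dict:
    """Block-effect and model-based analyses of two-block session logs.

    ``log`` needs columns participant_id, latency_min, likes, block
    ('low'/'high').  Participants with fewer than ``min_posts`` posts are
    excluded (logged).  The block effect is a mixed model of log latency
    on the low-block indicator with a participant random intercept
    (single-participant input falls back to OLS with a warning).  The
    model-based variant replaces the block indicator with a dichotomized
    subjective reward-rate series generated by running the latency model
    under ``reference_params`` on each participant's observed posts
    (participants with at least ``min_posts_model`` posts).
    """
    import statsmodels.formula.api as smf

    counts = log.groupby("participant_id").size()
    keep = counts[counts >= min_posts].index
    excluded = sorted(set(counts.index) - set(keep))
    df = log[log["participant_id"].isin(keep)].copy()
    if df.empty:
        raise ValueError("no participants satisfy the minimum post count")
    df["log_tau"] = np.log(df["latency_min"])
    df["low"] = (df["block"] == "low").astype(int)

    n_participants = df["participant_id"].nunique()
    if n_participants >= 2:
        model = smf.mixedlm("log_tau ~ low", df, groups=df["participant_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
        beta, se = float(res.fe_params["low"]), float(res.bse_fe["low"])
    else:
        warnings.warn("single participant: fixed-effects (OLS) fallback",
                      RuntimeWarning)
        res = smf.ols("log_tau ~ low", df).fit()
        beta, se = float(res.params["low"]), float(res.bse["low"])
    z = beta / se
    out = {
        "n_participants": int(n_participants),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "block_effect": {"beta_low": beta, "se": se, "z": z,
                         "p": float(2 * scipy.stats.norm.sf(abs(z))),
                         "percent": float(np.exp(beta) - 1)},
    }

    # model-based variant: subjective reward rate instead of block labels
    rows = []
    for pid, g in df.groupby("participant_id"):
        if len(g) < min_posts_model:
            continue
        from postlearn.model import monotonic_timestamps

        ts = monotonic_timestamps(g["latency_min"].to_numpy())
        tl = PostTimeline(user_id=str(pid), timestamps=ts,
                          likes=np.concatenate([[0.0], g["likes"].to_numpy()]))
        trace = trace_from_timeline(reference_params, tl)
        try:
            low = plstats.dichotomize_rbar(trace.rbar)
        except ValueError:
            continue
        rows.append(pd.DataFrame({
            "user_id": str(pid),
            "log_tau": np.log(trace.tau[1:]),
            "low_prev": low[:-1],
        }))
    if rows:
        mdf = pd.concat(rows, ignore_index=True)
        if mdf["user_id"].nunique() >= 2:
            model = smf.mixedlm("log_tau ~ low_prev", mdf, groups=mdf["user_id"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mres = model.fit(reml=False)
            b, s = float(mres.fe_params["low_prev"]), float(mres.bse_fe["low_prev"])
            out["rbar_effect"] = {
                "beta_low": b, "se": s, "z": b / s,
                "p": float(2 * scipy.stats.norm.sf(abs(b / s))),
                "n_participants": int(mdf["user_id"].nunique()),
            }
    return out
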