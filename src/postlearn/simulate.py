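"""Synthetic cohorts, reinforcement schedules, and two-block experiment
sessions.

Everything the analysis pipeline consumes can be generated here with a
documented statistical structure: cohorts of learning agents (and
no-learning null agents) posting with exponential latencies and receiving
Poisson-distributed likes, free-operant sessions on ratio/interval
reinforcement schedules, and two-block sessions in which the like range
shifts between a low (0-9) and a high (10-19) regime halfway through.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from postlearn.model import AgentParams, ModelTrace, PostTimeline, simulate_agent

__all__ = [
    "CohortSpec",
    "Cohort",
    "ExperimentSessionSpec",
    "ScheduleSpec",
    "generate_cohort",
    "generate_experiment",
    "generate_schedule_session",
    "generate_schedule_curve",
    "DEFAULT_PARAM_DISTRIBUTIONS",
    "STRONG_LEARNING_DISTRIBUTIONS",
    "MINUTES_PER_HOUR",
]

#: single documented constant converting experiment clocks (minutes) to
#: the hour unit used by the posting model
MINUTES_PER_HOUR = 60.0

#: Default sampling laws for (alpha, P, C), as (law, low, high) triples.
#: The learning rate is confined to the regime where the policy-gradient
#: recursion is stable at hour-scale latencies and like-scale rewards:
#: the policy step is alpha * delta_tau * delta, of order
#: alpha * (tens of hours) * (several likes), so alpha much beyond ~1e-3
#: sends a growing fraction of agents into numerical divergence.  P spans
#: initial mean latencies of 12 h to 48 h (about one post every half day
#: to two days); C spans weak to moderate effort sensitivity.  See the
#: methods note for the calibration of these ranges.
DEFAULT_PARAM_DISTRIBUTIONS: dict[str, tuple[str, float, float]] = {
    "alpha": ("loguniform", 4.5e-5, 1.35e-4),
    "P": ("uniform", math.log(12.0), math.log(48.0)),
    "C": ("loguniform", 0.1, 2.0),
}

#: Sampling laws for clearly-learning agents used by recovery and
#: causality-calibration analyses: the upper stable learning-rate band.
STRONG_LEARNING_DISTRIBUTIONS: dict[str, tuple[str, float, float]] = {
    "alpha": ("loguniform", 1e-4, 1e-3),
    "P": ("uniform", math.log(12.0), math.log(48.0)),
    "C": ("loguniform", 0.5, 30.0),
}

_LIKE_PROCESSES = (
    "poisson_constant",
    "poisson_per_user",
    "uniform_block",
    "poisson_drift",
)


def _draw(law: tuple[str, float, float], rng: np.random.Generator) -> float:
    kind, lo, hi = law
    if kind == "uniform":
        return float(rng.uniform(lo, hi))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if kind == "constant":
        return float(lo)
    raise ValueError(f"unknown sampling law {kind!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a reproducible synthetic cohort.

    posts_per_user may be a single count or an inclusive (low, high)
    range sampled uniformly per user.  like_process: 'poisson_constant'
    draws likes i.i.d. Poisson with one lambda for every individual;
    'poisson_per_user' perturbs lambda per user (uniform on
    [0.5, 1.5] * poisson_lambda); 'uniform_block' switches the like range
    from 0-9 to 10-19 at the session midpoint.
    """

    n_users: int = 1000
    posts_per_user: int | tuple[int, int] = 250
    param_distributions: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_DISTRIBUTIONS)
    )
    like_process: str = "poisson_constant"
    poisson_lambda: float = 5.0
    #: log-scale stationary sd and relaxation time (posts) of the slowly
    #: drifting like rate used by like_process='poisson_drift'
    drift_sd: float = 0.4
    drift_corr: float = 50.0
    variant: str = "rbar_full"
    rbar0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be >= 1")
        if self.poisson_lambda < 0:
            raise ValueError("poisson_lambda must be >= 0")
        if self.like_process not in _LIKE_PROCESSES:
            raise ValueError(f"unknown like_process {self.like_process!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


@dataclass
class Cohort:
    """Generated timelines plus the ground truth that produced them."""

    timelines: list[PostTimeline]
    true_params: list[AgentParams]
    traces: list[ModelTrace]
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.timelines)

    @property
    def n_posts_total(self) -> int:
        return sum(t.n_posts for t in self.timelines)


def _sample_params(spec: CohortSpec, rng: np.random.Generator) -> AgentParams:
    laws = spec.param_distributions
    P = _draw(laws["P"], rng)
    if spec.variant == "null_no_learning":
        return AgentParams(P=P, variant=spec.variant)
    return AgentParams(
        alpha=_draw(laws["alpha"], rng),
        P=P,
        C=_draw(laws["C"], rng),
        variant=spec.variant,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort of agents posting under the given like process.

    Each user's timeline is produced by the generative latency model with
    its own parameter draw; ground-truth parameters and latent traces are
    kept alongside for recovery and reward-sensitivity analyses.
    Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    timelines: list[PostTimeline] = []
    params_list: list[AgentParams] = []
    traces: list[ModelTrace] = []
    for u in range(spec.n_users):
        params = _sample_params(spec, rng)
        if isinstance(spec.posts_per_user, int):
            n_posts = spec.posts_per_user
        else:
            lo, hi = spec.posts_per_user
            n_posts = int(rng.integers(lo, hi + 1))
        lam = spec.poisson_lambda
        if spec.like_process == "poisson_per_user":
            lam = float(rng.uniform(0.5, 1.5) * spec.poisson_lambda)

        if spec.like_process == "uniform_block":
            half = (n_posts - 1) // 2

            def reward_process(i: int, tau: float, _rng=rng, _half=half) -> float:
                lo_, hi_ = (0, 9) if i < _half else (10, 19)
                return float(_rng.integers(lo_, hi_ + 1))

        elif spec.like_process == "poisson_drift":
            # mean-reverting log like-rate: the user's popularity wanders
            # slowly, so the reward rate carries low-frequency variance
            theta = 1.0 / spec.drift_corr
            sig = spec.drift_sd * math.sqrt(2.0 * theta)
            z0 = float(rng.normal(0.0, spec.drift_sd))
            state_z = {"z": z0}

            def reward_process(i: int, tau: float, _rng=rng, _st=state_z,
                               _lam=lam, _th=theta, _sig=sig) -> float:
                _st["z"] += -_th * _st["z"] + _sig * float(_rng.normal())
                return float(_rng.poisson(_lam * math.exp(_st["z"])))

        else:

            def reward_process(i: int, tau: float, _rng=rng, _lam=lam) -> float:
                return float(_rng.poisson(_lam))

        trace = simulate_agent(
            params, reward_process, n_posts, seed=rng, rbar0=spec.rbar0
        )
        if spec.like_process == "uniform_block":
            first_like = float(rng.integers(0, 10))
        else:
            first_like = float(rng.poisson(lam))
        timelines.append(trace.to_timeline(user_id=f"u{u:05d}", first_like=first_like))
        params_list.append(params)
        traces.append(trace)
    return Cohort(timelines=timelines, true_params=params_list, traces=traces, spec=spec)


# ---------------------------------------------------------------------------
# two-block experiment sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSessionSpec:
    """A timed online session split into two equal-length like regimes.

    Participants post freely for session_length minutes.  Likes per post
    are uniform integers on 0-9 in the low block and 10-19 in the high
    block; block order alternates across participants so that exactly
    ceil(n/2) start low.  Agent parameters are sampled on the minute
    scale (initial mean latencies of ~1-4 min).  The subjective reward
    rate starts at its steady state under the session-average like rate
    (rbar_init='steady'): participants arrive with prior reward
    experience, so the two blocks perturb the rate symmetrically instead
    of riding a cold-start transient.
    """

    n_participants: int = 176
    session_length: float = 25.0  # minutes
    param_distributions: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: {
            "alpha": ("loguniform", 1e-2, 5e-2),
            "P": ("uniform", math.log(1.0), math.log(4.0)),
            "C": ("loguniform", 1.0, 10.0),
        }
    )
    rbar_init: str | float = "steady"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")


def generate_experiment(
    spec: ExperimentSessionSpec,
) -> tuple[pd.DataFrame, list[AgentParams]]:
    """Simulate two-block sessions driven by learning agents.

    Returns an event log (participant_id, post_index, time_min, latency_min,
    likes, block, order) with one row per emitted post after the first,
    plus each participant's ground-truth parameters.  Block mean likes are
    4.5 (low) and 14.5 (high) in expectation.
    """
    from postlearn.model import ModelState, mean_latency, prediction_error, update_state
    import warnings as _warnings

    rng = np.random.default_rng(spec.seed)
    rows = []
    truths: list[AgentParams] = []
    half = spec.session_length / 2.0
    for u in range(spec.n_participants):
        order = "low_first" if u % 2 == 0 else "high_first"
        laws = spec.param_distributions
        params = AgentParams(
            alpha=_draw(laws["alpha"], rng),
            P=_draw(laws["P"], rng),
            C=_draw(laws["C"], rng),
        )
        truths.append(params)
        if spec.rbar_init == "steady":
            # steady state of the reward-rate update under the
            # session-average like rate
            mu0 = math.exp(params.P)
            rbar0 = (9.5 - params.C / mu0) / mu0
        else:
            rbar0 = float(spec.rbar_init)
        state = ModelState(policy=params.P, rbar=rbar0)
        t = 0.0
        tau_prev = None
        k = 0
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            while True:
                mu = mean_latency(state, params)
                tau = float(rng.exponential(mu))
                t += tau
                if t > spec.session_length:
                    break
                block = "low" if (t <= half) == (order == "low_first") else "high"
                likes = int(rng.integers(0, 10) if block == "low" else rng.integers(10, 20))
                k += 1
                rows.append(
                    dict(participant_id=f"p{u:04d}", post_index=k, time_min=t,
                         latency_min=tau, likes=likes, block=block, order=order)
                )
                d = prediction_error(likes, tau, state, params)
                state = update_state(state, tau, tau_prev, d, params)
                tau_prev = tau
    log = pd.DataFrame(
        rows,
        columns=["participant_id", "post_index", "time_min", "latency_min",
                 "likes", "block", "order"],
    )
    return log, truths


# ---------------------------------------------------------------------------
# reinforcement schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleSpec:
    """A classic free-operant reinforcement schedule.

    kind='ratio': every ``parameter``-th response is rewarded with
    ``magnitude`` likes.  kind='interval': reward arms after an
    exponentially distributed delay with mean ``parameter`` hours and is
    collected (magnitude likes) by the first response thereafter.
    """

    kind: str = "interval"
    parameter: float = 24.0
    magnitude: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("ratio", "interval"):
            raise ValueError("schedule kind must be 'ratio' or 'interval'")
        if self.parameter <= 0:
            raise ValueError("schedule parameter must be positive")
        if self.magnitude < 0:
            raise ValueError("reward magnitude must be >= 0")


def generate_schedule_session(
    spec: ScheduleSpec,
    params: AgentParams,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> ModelTrace:
    """Run one agent for n responses on a reinforcement schedule.

    The reward process is stateful: on a ratio schedule reward arrives on
    every ``parameter``-th response; on an interval schedule reward arms at
    exponential times and waits for the next response, so the obtainable
    reward rate saturates at magnitude/parameter no matter how fast the
    agent responds — the situation in which response rates classically
    follow a saturating (hyperbolic) function of reward rates.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec.kind == "ratio":
        period = max(1, int(round(spec.parameter)))
        counter = {"n": 0}

        def reward_process(i: int, tau: float) -> float:
            counter["n"] += 1
            if counter["n"] >= period:
                counter["n"] = 0
                return spec.magnitude
            return 0.0

    else:
        state = {"next_arm": float(rng.exponential(spec.parameter)), "clock": 0.0}

        def reward_process(i: int, tau: float) -> float:
            state["clock"] += tau
            if state["clock"] >= state["next_arm"]:
                state["next_arm"] = state["clock"] + float(
                    rng.exponential(spec.parameter)
                )
                return spec.magnitude
            return 0.0

    return simulate_agent(params, reward_process, n + 1, seed=rng)


def generate_schedule_curve(
    params: AgentParams,
    magnitudes: Sequence[float],
    interval: float = 12.0,
    n_block: int = 300,
    burn: int = 150,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Steady-state response-rate vs reward-rate curve across schedules.

    One continuing agent works through consecutive blocks of an interval
    schedule whose reward magnitude steps through ``magnitudes`` (order as
    given; rich-to-lean avoids cold starts on lean blocks, mirroring how
    schedule experiments run conditions in sequence with carryover).  Per
    block the first ``burn`` responses are discarded and the remaining
    responses yield one (obtained reward rate, response rate) point, both
    per hour.  Returns None if the agent's dynamics diverged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mags = list(magnitudes)
    st = {"next": float(rng.exponential(interval)), "clock": 0.0}

    def reward_process(i: int, tau: float) -> float:
        b = min(i // n_block, len(mags) - 1)
        st["clock"] += tau
        if st["clock"] >= st["next"]:
            st["next"] = st["clock"] + float(rng.exponential(interval))
            return mags[b]
        return 0.0

    trace = simulate_agent(params, reward_process, n_block * len(mags) + 1, seed=rng)
    if trace.diverged:
        return None
    rates, rrates = [], []
    for b in range(len(mags)):
        sl = slice(b * n_block + burn, (b + 1) * n_block)
        tau = trace.tau[sl]
        total = float(tau.sum())
        rates.append(len(tau) / total)
        rrates.append(float(trace.reward[sl].sum()) / total)
    return np.asarray(rrates), np.asarray(rates)
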