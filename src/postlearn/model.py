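"""Average-reward reinforcement-learning model of posting latencies.

The model treats posting on a social platform as free-operant behavior:
the agent chooses *when* to emit its next response (post), and the latency
between successive posts is the behavioral variable.  Each latency is a
draw from an exponential distribution whose mean is set by a dynamic
response policy.  After each post the agent observes a social reward
(likes) and computes a net reward prediction error that balances the
reward against the effort cost of responding quickly and the opportunity
cost of responding slowly; the prediction error drives policy-gradient
updates of the policy and of the subjective average net reward rate.

Units: latencies in hours, rewards in likes, the average reward rate in
likes per hour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "VARIANTS",
    "AgentParams",
    "ModelState",
    "PostTimeline",
    "ModelTrace",
    "mean_latency",
    "prediction_error",
    "update_state",
    "optimal_latency",
    "simulate_agent",
    "negative_log_likelihood",
    "trace_from_timeline",
    "EXP_CLAMP",
    "MIN_POSTS",
]

#: Hard bound on the exponent of the latency policy.  exp(+/-50) spans
#: ~5e-22 .. 5e21 hours, far outside any behaviorally meaningful range,
#: so the clamp only engages when the update dynamics diverge.
EXP_CLAMP = 50.0

#: Minimum number of posts required for likelihood-based analyses.
MIN_POSTS = 10

VARIANTS = (
    "rbar_full",
    "null_no_learning",
    "no_effort_cost",
    "fixed_effort_cost",
    "increasing_effort_cost",
    "pavlovian_only",
)

# integer codes used by the compiled likelihood kernel
_VARIANT_CODE = {name: i for i, name in enumerate(VARIANTS)}

# number of free parameters per variant (alpha, P, C as applicable)
_N_FREE = {
    "rbar_full": 3,
    "null_no_learning": 1,
    "no_effort_cost": 2,
    "fixed_effort_cost": 3,
    "increasing_effort_cost": 3,
    "pavlovian_only": 3,
}


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the latency-learning model.

    alpha : learning rate / step size, shared by every update term
        (0 < alpha <= 1).
    P : initial response policy in log-hours (0 <= P < inf); the initial
        mean latency is exp(P).
    C : effort-cost sensitivity in likes*hours (0 < C < inf); the cost of
        a response amortizes over the latency as C / tau.
    variant : which model family member the parameters belong to.  The
        no-learning null model uses only P.
    """

    alpha: float = 0.01
    P: float = math.log(24.0)
    C: float = 1.0
    variant: str = "rbar_full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant != "null_no_learning":
            if not (0.0 < self.alpha <= 1.0):
                raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
            if not (0.0 < self.C < math.inf):
                raise ValueError(f"C must be in (0, inf), got {self.C}")
        if not (0.0 <= self.P < math.inf):
            raise ValueError(f"P must be in [0, inf), got {self.P}")

    @property
    def n_free(self) -> int:
        return _N_FREE[self.variant]


@dataclass
class ModelState:
    """Evolving state of one agent: the log-latency policy, the subjective
    average net reward rate (may be negative), and the 1-based post index."""

    policy: float
    rbar: float = 0.0
    t: int = 1

    def __post_init__(self) -> None:
        if not (math.isfinite(self.policy) and math.isfinite(self.rbar)):
            raise ValueError("policy and rbar must be finite")
        if self.t < 1:
            raise ValueError("post index starts at 1")


@dataclass(frozen=True)
class PostTimeline:
    """One user's ordered posting record.

    timestamps are hours since an arbitrary epoch, strictly increasing;
    likes are the non-negative integer rewards per post.  Latencies are
    the successive timestamp differences and exist from the second post.
    """

    user_id: str
    timestamps: np.ndarray
    likes: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        lk = np.asarray(self.likes, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "likes", lk)
        if ts.ndim != 1 or lk.shape != ts.shape:
            raise ValueError("timestamps and likes must be 1-D and equal length")
        if len(ts) >= 2 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(lk < 0):
            raise ValueError("likes must be non-negative")

    @property
    def n_posts(self) -> int:
        return len(self.timestamps)

    @property
    def latencies(self) -> np.ndarray:
        """Inter-post latencies in hours (length n_posts - 1)."""
        return np.diff(self.timestamps)


@dataclass
class ModelTrace:
    """Per-latency evolution of the model.  Arrays are aligned on latency
    index i = 1..m, where latency i separates post i and post i+1 and
    reward[i] is the likes of post i+1 (the post that closes the wait)."""

    policy: np.ndarray
    rbar: np.ndarray
    delta: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    reward: np.ndarray
    params: AgentParams | None = None

    def __post_init__(self) -> None:
        n = len(self.tau)
        for name in ("policy", "rbar", "delta", "mu", "reward"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace arrays must have equal length")
        if np.any(self.mu <= 0):
            raise ValueError("predicted mean latencies must be positive")

    def __len__(self) -> int:
        return len(self.tau)

    @property
    def diverged(self) -> bool:
        """True when the latency exponent ever reached the clamp bound,
        i.e. the update recursion left the numerically meaningful range."""
        return bool(np.max(np.abs(np.log(self.mu))) >= EXP_CLAMP - 1e-9)

    def to_timeline(self, user_id: str = "sim", first_like: float = 0.0) -> PostTimeline:
        ts = monotonic_timestamps(self.tau)
        likes = np.concatenate([[first_like], self.reward])
        return PostTimeline(user_id=user_id, timestamps=ts, likes=likes)


def monotonic_timestamps(tau: np.ndarray) -> np.ndarray:
    """Cumulative timestamps from latencies, strictly increasing.

    A latency below the float resolution of the running clock would stall
    the timestamp sequence; such steps are bumped to the next
    representable value (only engages in degenerate regimes)."""
    ts = np.concatenate([[0.0], np.cumsum(tau)])
    for i in range(1, len(ts)):
        if ts[i] <= ts[i - 1]:
            ts[i] = np.nextafter(ts[i - 1], np.inf)
    return ts


def _clamped_exponent(policy: float, alpha: float, rbar: float) -> float:
    x = policy - alpha * rbar
    if x > EXP_CLAMP or x < -EXP_CLAMP:
        warnings.warn(
            f"latency exponent {x:.2f} clamped to +/-{EXP_CLAMP:g}",
            RuntimeWarning,
            stacklevel=3,
        )
        x = max(-EXP_CLAMP, min(EXP_CLAMP, x))
    return x


def mean_latency(state: ModelState, params: AgentParams) -> float:
    """Predicted mean latency mu = exp(policy - alpha * rbar), in hours.

    The subtraction term transmits a motivational ("Pavlovian") effect of
    the average reward rate on response speed that bypasses the learned
    instrumental policy.  The no-learning null model ignores the state and
    returns the constant exp(P).
    """
    if params.variant == "null_no_learning":
        return math.exp(min(EXP_CLAMP, params.P))
    return math.exp(_clamped_exponent(state.policy, params.alpha, state.rbar))


def prediction_error(
    reward: float, tau: float, state: ModelState, params: AgentParams
) -> float:
    """Net reward prediction error delta for one completed latency.

    The reference level subtracted from the experienced reward combines
    the effort cost of fast responding and the opportunity cost of slow
    responding (rbar * tau).  The effort term depends on the variant:
    amortized C / tau for the full and pavlovian models, absent, constant
    C, or growing C * tau for the reconstructed alternatives.
    """
    if tau <= 0:
        raise ValueError("latency must be positive")
    v = params.variant
    if v in ("rbar_full", "pavlovian_only"):
        effort = params.C / tau
    elif v == "no_effort_cost":
        effort = 0.0
    elif v == "fixed_effort_cost":
        effort = params.C
    elif v == "increasing_effort_cost":
        effort = params.C * tau
    else:  # null model has no prediction error
        raise ValueError("the no-learning null model defines no prediction error")
    return reward - effort - state.rbar * tau


def update_state(
    state: ModelState,
    tau_t: float,
    tau_prev: float | None,
    delta: float,
    params: AgentParams,
) -> ModelState:
    """Policy-gradient update after one latency.

    policy' = policy + alpha * (tau_t - tau_prev) * delta, defined once
    two successive latencies exist; rbar' = rbar + alpha * delta always
    (same step size for every update term).  The pavlovian-only variant
    freezes the instrumental policy at its initial value.
    """
    if params.variant == "null_no_learning":
        return ModelState(policy=state.policy, rbar=state.rbar, t=state.t + 1)
    policy = state.policy
    if tau_prev is not None and params.variant != "pavlovian_only":
        policy = policy + params.alpha * (tau_t - tau_prev) * delta
    rbar = state.rbar + params.alpha * delta
    policy = float(np.clip(policy, -1e12, 1e12))
    rbar = float(np.clip(rbar, -1e12, 1e12))
    return ModelState(policy=policy, rbar=rbar, t=state.t + 1)


def optimal_latency(C: float, rbar: float) -> float:
    """Latency that maximizes the net reward for a fixed reward amount.

    delta(tau) = R - C/tau - rbar*tau is concave in tau with maximum at
    tau* = sqrt(C / rbar); the optimum shortens as the average reward
    rate rises, which is the vigor effect the model formalizes.
    """
    if C <= 0:
        raise ValueError("effort cost C must be positive")
    if rbar <= 0:
        raise ValueError(
            "no finite optimal latency when the average reward rate is <= 0"
        )
    return math.sqrt(C / rbar)


def simulate_agent(
    params: AgentParams,
    reward_process: Callable[[int, float], float],
    n_posts: int,
    seed: int | np.random.Generator | None = None,
    rbar0: float = 0.0,
) -> ModelTrace:
    """Generate one agent's posting trace.

    Each of the n_posts - 1 latencies is drawn from an exponential
    distribution with the current predicted mean; the reward for the post
    that ends the wait comes from ``reward_process(i, tau)`` with i the
    0-based latency index.  Fully reproducible given a seed.
    """
    if n_posts < 2:
        raise ValueError("need at least two posts to define a latency")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = n_posts - 1
    policy = np.empty(m)
    rbar = np.empty(m)
    delta = np.empty(m)
    mu = np.empty(m)
    tau = np.empty(m)
    reward = np.empty(m)

    state = ModelState(policy=params.P, rbar=rbar0)
    tau_prev: float | None = None
    null = params.variant == "null_no_learning"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(m):
            mu_i = mean_latency(state, params)
            tau_i = rng.exponential(mu_i)
            r_i = float(reward_process(i, tau_i))
            d_i = 0.0 if null else prediction_error(r_i, tau_i, state, params)
            policy[i], rbar[i] = state.policy, state.rbar
            mu[i], tau[i], reward[i], delta[i] = mu_i, tau_i, r_i, d_i
            state = update_state(state, tau_i, tau_prev, d_i, params)
            tau_prev = tau_i
    return ModelTrace(policy=policy, rbar=rbar, delta=delta, mu=mu, tau=tau,
                      reward=reward, params=params)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _nll_core(tau, reward, alpha, P, C, variant_code, rbar0, clamp):
    """Sequential negative log-likelihood; compiled with numba below."""
    m = tau.shape[0]
    policy = P
    rbar = rbar0
    nll = 0.0
    tau_prev = -1.0
    for i in range(m):
        if variant_code == 1:  # null: constant policy
            x = P
        else:
            x = policy - alpha * rbar
        if x > clamp:
            x = clamp
        elif x < -clamp:
            x = -clamp
        t = tau[i]
        nll += x + t * math.exp(-x)
        if variant_code != 1:
            if variant_code == 2:
                effort = 0.0
            elif variant_code == 3:
                effort = C
            elif variant_code == 4:
                effort = C * t
            else:  # full (0) and pavlovian (5)
                effort = C / t
            d = reward[i] - effort - rbar * t
            if tau_prev >= 0.0 and variant_code != 5:
                policy = policy + alpha * (t - tau_prev) * d
                if policy > 1e12:
                    policy = 1e12
                elif policy < -1e12:
                    policy = -1e12
            rbar = rbar + alpha * d
            if rbar > 1e12:
                rbar = 1e12
            elif rbar < -1e12:
                rbar = -1e12
        tau_prev = t
    return nll


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _nll_core = njit(cache=False)(_nll_core)
except ImportError:  # pragma: no cover
    pass


def negative_log_likelihood(
    params: AgentParams,
    timeline: PostTimeline,
    rbar0: float = 0.0,
    enforce_min_posts: bool = True,
) -> float:
    """Negative log-likelihood (nats) of a timeline under the model.

    The state is run forward on the observed latencies and likes, and each
    latency tau_i contributes -log f(tau_i | mu_i) for the exponential
    density with the current predicted mean, i.e. log mu_i + tau_i / mu_i.
    The reward paired with latency i is the likes of the post that ends
    it, so the first post's likes only seed the display and are never
    scored.
    """
    if enforce_min_posts and timeline.n_posts < MIN_POSTS:
        raise ValueError(
            f"user {timeline.user_id}: need >= {MIN_POSTS} posts, "
            f"got {timeline.n_posts}"
        )
    tau = timeline.latencies
    if np.any(tau <= 0):
        raise ValueError("all latencies must be positive")
    reward = timeline.likes[1:]
    val = _nll_core(
        np.ascontiguousarray(tau, dtype=np.float64),
        np.ascontiguousarray(reward, dtype=np.float64),
        float(params.alpha),
        float(params.P),
        float(params.C),
        _VARIANT_CODE[params.variant],
        float(rbar0),
        EXP_CLAMP,
    )
    return float(val)


def trace_from_timeline(
    params: AgentParams, timeline: PostTimeline, rbar0: float = 0.0
) -> ModelTrace:
    """Run the model forward on observed data and return its latent trace.

    Used to extract the subjective average-reward-rate series implied by
    fitted parameters; mirrors the likelihood recursion step by step.
    """
    tau_arr = timeline.latencies
    reward_arr = timeline.likes[1:]
    m = len(tau_arr)
    policy = np.empty(m)
    rbar = np.empty(m)
    delta = np.empty(m)
    mu = np.empty(m)
    state = ModelState(policy=params.P, rbar=rbar0)
    tau_prev: float | None = None
    null = params.variant == "null_no_learning"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(m):
            policy[i], rbar[i] = state.policy, state.rbar
            mu[i] = mean_latency(state, params)
            d = 0.0 if null else prediction_error(reward_arr[i], tau_arr[i], state, params)
            delta[i] = d
            state = update_state(state, tau_arr[i], tau_prev, d, params)
            tau_prev = tau_arr[i]
    return ModelTrace(policy=policy, rbar=rbar, delta=delta, mu=mu,
                      tau=tau_arr.copy(), reward=np.asarray(reward_arr, float),
                      params=params)
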