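"""Distributional temporal-difference model with asymmetric learning rates.

Each simulated neuron i keeps its own value estimate V[i, t] over a short
deterministic state chain and learns with a pair of learning rates: positive
TD errors are scaled by alpha_plus_i, negative ones by alpha_minus_i.  Under
this rule a neuron's reward-state value settles (in distribution) around the
tau-expectile of the reward distribution, tau = a+/(a+ + a-): optimistic
neurons (tau > 0.5) converge above the mean, pessimistic ones below.  A
population of neurons with heterogeneous asymmetries therefore encodes the
reward distribution rather than only its mean.

Training rewards are Gaussian (mean 5, SD 5 by default); agents are
evaluated on a wider uniform range (0-20) by the mean squared error between
test rewards and each neuron's converged reward-state value.  Learning-rate
pairs are fit to observed activity distributions (Gaussian KDE of
standardized reward responses) by grid search on the pair's stationary
reward-state TD error, computed analytically through the expectile relation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = [
    "TDConfig",
    "TDAgent",
    "TDTrace",
    "ActivityDistribution",
    "FitResult",
    "EvaluationResult",
    "td_error",
    "apply_update",
    "make_agent",
    "train_agent",
    "expectile_oracle",
    "stationary_td_error",
    "estimate_activity_distribution",
    "fit_learning_rates",
    "evaluate_agent",
    "build_projection_agents",
]


@dataclass(frozen=True)
class TDConfig:
    """Model and environment settings.

    The training reward "N(5, 5)" is read as mean 5, SD 5 (``reward_sd`` is
    a standard deviation); the chain has ``n_states`` states traversed
    deterministically with reward only at ``reward_state`` (terminal by
    default), after which the episode restarts.
    """

    gamma: float = 0.9
    n_states: int = 5
    reward_state: int = 4
    reward_mean: float = 5.0
    reward_sd: float = 5.0
    test_range: tuple[float, float] = (0.0, 20.0)
    n_neurons: int = 50
    n_training_trials: int = 10_000
    tail_fraction: float = 0.5       # fraction of final episodes averaged as "converged"
    grid_step: float = 0.01          # learning-rate grid 0.01..1.00 on both axes
    n_test_rewards: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0 <= self.reward_state < self.n_states:
            raise ValueError("reward_state outside the chain")
        if not 0 < self.grid_step <= 1:
            raise ValueError("grid_step must be in (0, 1]")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in (0, 1]")

    def learning_rate_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.grid_step))
        return np.arange(1, n + 1) / n


@dataclass
class TDAgent:
    """An array of simulated neurons sharing one environment."""

    V: np.ndarray                    # n_neurons x n_states
    alpha_plus: np.ndarray
    alpha_minus: np.ndarray
    label: str = "agent"
    converged_V: np.ndarray | None = None   # tail-averaged values, same shape as V

    @property
    def n_neurons(self) -> int:
        return self.V.shape[0]

    @property
    def asymmetry(self) -> np.ndarray:
        return self.alpha_plus / (self.alpha_plus + self.alpha_minus)


@dataclass
class TDTrace:
    """Per-episode record of the reward-state update."""

    rewards: np.ndarray              # episodes x neurons reward draws
    delta_reward_state: np.ndarray   # episodes x neurons
    v_reward_state: np.ndarray       # episodes x neurons, value after update


def td_error(v_t: float, r: float, gamma: float, v_next: float) -> float:
    """delta = r + gamma * V(next) - V(current)."""
    return r + gamma * v_next - v_t


def apply_update(v, delta, alpha_plus, alpha_minus):
    """Asymmetric update: positive errors scaled by alpha_plus, negative by
    alpha_minus; a zero error leaves the value unchanged."""
    step = np.where(delta > 0, alpha_plus * delta,
                    np.where(delta < 0, alpha_minus * delta, 0.0))
    return v + step


def make_agent(
    config: TDConfig,
    rng: np.random.Generator,
    alpha_plus: np.ndarray | None = None,
    alpha_minus: np.ndarray | None = None,
    label: str = "agent",
) -> TDAgent:
    """Fresh agent with zero values; rates default to U(0, 1) draws."""
    n = config.n_neurons
    if alpha_plus is None:
        alpha_plus = rng.uniform(0.0, 1.0, n)
    if alpha_minus is None:
        alpha_minus = rng.uniform(0.0, 1.0, n)
    alpha_plus = np.clip(np.asarray(alpha_plus, float), 1e-6, 1.0)
    alpha_minus = np.clip(np.asarray(alpha_minus, float), 1e-6, 1.0)
    V = np.zeros((n, config.n_states))
    return TDAgent(V, alpha_plus, alpha_minus, label=label)


def train_agent(
    agent: TDAgent,
    config: TDConfig,
    rng: np.random.Generator,
    record_trace: bool = False,
    divergence_bound: float = 1e6,
) -> tuple[TDAgent, TDTrace | None]:
    """Run ``n_training_trials`` episodes over the deterministic chain,
    updating all neurons in parallel.  The "converged" value reported per
    neuron/state is the time average of V over the final ``tail_fraction``
    of episodes (a fixed-learning-rate agent fluctuates around its
    stationary point rather than converging pointwise)."""
    n_ep = config.n_training_trials
    gamma = config.gamma
    rs = config.reward_state
    V = agent.V
    ap, am = agent.alpha_plus, agent.alpha_minus

    tail_start = int(np.floor(n_ep * (1.0 - config.tail_fraction)))
    tail_sum = np.zeros_like(V)
    tail_n = 0
    # rewards are drawn per neuron (r_{t,i}): each simulated neuron sees its
    # own draw from the training distribution
    rewards = rng.normal(config.reward_mean, config.reward_sd,
                         size=(n_ep, agent.n_neurons))
    trace_delta = np.empty((n_ep, agent.n_neurons)) if record_trace else None
    trace_v = np.empty((n_ep, agent.n_neurons)) if record_trace else None

    # Within an episode each state's bootstrap target V[:, t+1] is read
    # before state t+1 is updated, so all per-state TD errors of an episode
    # can be computed at once from the pre-episode values.
    r_mat = np.zeros((agent.n_neurons, config.n_states))
    ap_col, am_col = ap[:, None], am[:, None]
    for ep in range(n_ep):
        r_mat[:, rs] = rewards[ep]
        v_next = np.concatenate([V[:, 1:], np.zeros((V.shape[0], 1))], axis=1)
        delta = r_mat + gamma * v_next - V
        V += np.where(delta > 0, ap_col * delta,
                      np.where(delta < 0, am_col * delta, 0.0))
        if record_trace:
            trace_delta[ep] = delta[:, rs]
            trace_v[ep] = V[:, rs]
        if np.any(np.abs(V) > divergence_bound):
            raise FloatingPointError("value estimates diverged")
        if ep >= tail_start:
            tail_sum += V
            tail_n += 1
    agent.converged_V = tail_sum / max(tail_n, 1)
    trace = TDTrace(rewards, trace_delta, trace_v) if record_trace else None
    return agent, trace


# ---------------------------------------------------------------------------
# expectile oracle and the stationary TD error
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _standard_expectile(tau: float) -> float:
    """tau-expectile of the standard normal (cached; erf-based for speed)."""
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)

    def imbalance(z: float) -> float:
        pdf = math.exp(-0.5 * z * z) * inv_sqrt2pi
        sf = 0.5 * math.erfc(z * inv_sqrt2)
        upper = -z * sf + pdf               # E[(X-z)+]
        lower = z * (1.0 - sf) + pdf        # E[(z-X)+]
        return tau * upper - (1.0 - tau) * lower

    if imbalance(-12.0) * imbalance(12.0) > 0:
        raise ValueError("no bracket for expectile root")
    return float(brentq(imbalance, -12.0, 12.0, xtol=1e-12))


def expectile_oracle(tau: float, mu: float, sigma: float) -> float:
    """tau-expectile of N(mu, sigma): the root e of
    tau * E[(X-e)+] = (1-tau) * E[(e-X)+], via closed-form partial
    expectations and bracketing root-finding."""
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return mu + sigma * _standard_expectile(float(tau))


def stationary_td_error(tau, mu: float, sigma: float):
    """Expected reward-state TD error once values sit at their stationary
    point: mu - expectile_tau(mu, sigma).  Vectorized over tau."""
    taus = np.atleast_1d(np.asarray(tau, float))
    uniq, inverse = np.unique(taus, return_inverse=True)
    vals = np.array([mu - expectile_oracle(t, mu, sigma) for t in uniq])
    out = vals[inverse].reshape(np.shape(tau))
    return float(out) if np.isscalar(tau) else out


# ---------------------------------------------------------------------------
# activity distributions and fitting
# ---------------------------------------------------------------------------

@dataclass
class ActivityDistribution:
    """Gaussian-kernel density estimate of standardized reward responses."""

    label: str
    sample: np.ndarray
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    degenerate: bool = False
    _kde: object | None = None

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.degenerate or self._kde is None:
            return self.sample[0] + rng.normal(0.0, self.bandwidth, n)
        return self._kde.resample(n, seed=rng)[0]


def estimate_activity_distribution(
    responses: np.ndarray,
    label: str = "population",
    degenerate_bandwidth: float = 1e-3,
) -> ActivityDistribution:
    """KDE with Silverman's-rule bandwidth; support grid extends 4
    bandwidths beyond the sample range.  A zero-variance sample is flagged
    degenerate (draws are the value plus bandwidth-scale kernel noise)."""
    x = np.asarray(responses, float)
    if x.size < 5:
        raise ValueError("need at least 5 responses")
    if np.ptp(x) == 0:
        bw = degenerate_bandwidth
        grid = np.linspace(x[0] - 4 * bw, x[0] + 4 * bw, 512)
        density = stats.norm.pdf(grid, x[0], bw)
        return ActivityDistribution(label, x, bw, grid, density, degenerate=True)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, 512)
    density = kde(grid)
    return ActivityDistribution(label, x, bw, grid, density, _kde=kde)


@dataclass
class FitResult:
    label: str
    alpha_plus: np.ndarray
    alpha_minus: np.ndarray
    loss: np.ndarray
    targets: np.ndarray

    @property
    def asymmetry(self) -> np.ndarray:
        return self.alpha_plus / (self.alpha_plus + self.alpha_minus)


def fit_learning_rates(
    activity: ActivityDistribution,
    config: TDConfig,
    rng: np.random.Generator,
) -> FitResult:
    """Grid-search fit: one target TD error drawn from the activity
    distribution per neuron; the (a+, a-) pair whose stationary expected
    reward-state TD error is closest (squared difference) wins, ties broken
    toward the smaller a+ + a-."""
    grid = config.learning_rate_grid()
    ap, am = np.meshgrid(grid, grid, indexing="ij")
    ap, am = ap.ravel(), am.ravel()
    # sort by rate sum so np.argmin's first-minimum rule = smallest-sum tie-break
    order = np.argsort(ap + am, kind="stable")
    ap, am = ap[order], am[order]
    tau = ap / (ap + am)
    delta_bar = stationary_td_error(tau, config.reward_mean, config.reward_sd)

    targets = activity.draw(config.n_neurons, rng)
    losses = (delta_bar[None, :] - targets[:, None]) ** 2
    if not np.all(np.isfinite(losses).any(axis=1)):
        raise ValueError("non-finite loss over the whole grid")
    best = np.argmin(losses, axis=1)
    return FitResult(
        label=activity.label,
        alpha_plus=ap[best],
        alpha_minus=am[best],
        loss=losses[np.arange(targets.size), best],
        targets=targets,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    label: str
    test_rewards: np.ndarray         # Y
    predictions: np.ndarray          # Y-hat, one converged value per neuron
    mse_per_cell: np.ndarray
    mean_mse: float
    bias: float                      # mean(Y-hat) - mean(Y); negative = underestimation


def evaluate_agent(
    agent: TDAgent,
    config: TDConfig,
    rng: np.random.Generator,
) -> EvaluationResult:
    """Frozen-value test: rewards drawn uniformly over the test range are
    compared against each neuron's converged reward-state value (no learning
    during the test phase)."""
    if agent.converged_V is None:
        raise ValueError("agent must be trained before evaluation")
    lo, hi = config.test_range
    Y = rng.uniform(lo, hi, config.n_test_rewards)
    Yhat = agent.converged_V[:, config.reward_state]
    mse = np.mean((Y[None, :] - Yhat[:, None]) ** 2, axis=1)
    return EvaluationResult(
        label=agent.label,
        test_rewards=Y,
        predictions=Yhat,
        mse_per_cell=mse,
        mean_mse=float(mse.mean()),
        bias=float(Yhat.mean() - Y.mean()),
    )


def build_projection_agents(
    population_samples: dict[str, np.ndarray],
    config: TDConfig,
    rng: np.random.Generator,
    train: bool = True,
) -> dict[str, tuple[TDAgent, FitResult]]:
    """One fitted agent per population plus a 'unified' agent fit to the
    pooled sample; each agent has ``config.n_neurons`` neurons."""
    if not population_samples:
        raise ValueError("need at least one population sample")
    samples = dict(population_samples)
    samples["unified"] = np.concatenate([np.asarray(v, float)
                                         for v in population_samples.values()])
    out: dict[str, tuple[TDAgent, FitResult]] = {}
    for label, sample in samples.items():
        activity = estimate_activity_distribution(sample, label=label)
        fit = fit_learning_rates(activity, config, rng)
        agent = make_agent(config, rng, fit.alpha_plus, fit.alpha_minus, label=label)
        if train:
            train_agent(agent, config, rng)
        out[label] = (agent, fit)
    return out
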