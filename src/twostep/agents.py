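"""Model-free, model-based and hybrid reinforcement-learning agents.

The hybrid model mixes a model-free SARSA(lambda) learner with a
model-based evaluator that knows the true transition structure:

    Q_MB(a)  = p_common * V(major(a)) + (1 - p_common) * V(other(a))
    net(a)   = w * Q_MB(a) + (1 - w) * Q_MF(a) + persev * 1[a == prev]
    P(a)     = softmax(beta * net)(a)

After observing (choice c, second-stage state s, reward r), with the
pre-update values:

    d1 = V(s) - Q_MF(c);        Q_MF(c) += alpha * d1
    d2 = r - V(s);              Q_MF(c) += alpha * lam * d2
    V(s) += alpha * d2

Pure model-free behaviour is w = 0, pure model-based w = 1.  There is
no choice at the second stage, so V(s) is a state value learned from
reward alone and the eligibility trace ``lam`` controls how strongly
the second-stage prediction error reaches the first-stage values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .task import RewardWalks, TaskConfig, init_walks, majority_destination
from .transforms import PARAM_NAMES, natural_to_unconstrained, unconstrained_to_natural

__all__ = [
    "AgentParams",
    "AgentState",
    "PopulationSpec",
    "q_model_based",
    "choice_probabilities",
    "update_model_free",
    "simulate_agent",
    "sample_population",
    "simulate_cohort",
]

_RANGES = {
    "alpha": (0.0, 1.0),
    "beta": (0.0, 20.0),
    "w": (0.0, 1.0),
    "lam": (0.0, 1.0),
    "persev": (-1.0, 1.0),
}


@dataclass(frozen=True)
class AgentParams:
    """The five hybrid-model parameters on their natural scales.

    alpha : learning rate in [0, 1]
    beta  : softmax inverse temperature in [0, 20]
    w     : model-based weight in [0, 1]
    lam   : eligibility-trace parameter in [0, 1]
    persev: perseveration (choice stickiness) in [-1, 1]
    """

    alpha: float
    beta: float
    w: float
    lam: float
    persev: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not np.isfinite(v) or not lo <= v <= hi:
                raise ConfigError(f"{name}={v} outside [{lo}, {hi}]")

    def to_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.w, self.lam, self.persev], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "AgentParams":
        return cls(*(float(x) for x in np.asarray(arr, dtype=float)))


@dataclass
class AgentState:
    """Mutable learner state carried across trials."""

    q_mf: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    v2: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    prev_choice: int | None = None

    def copy(self) -> "AgentState":
        return AgentState(self.q_mf.copy(), self.v2.copy(), self.prev_choice)


@dataclass(frozen=True)
class PopulationSpec:
    """A simulated cohort: parameter means plus spread in unconstrained space.

    Individual agents are drawn by adding Normal(0, sd_unconstrained)
    noise to each parameter's unconstrained coordinate, then mapping back
    to the natural scale, so every draw respects the parameter ranges.
    """

    mu_natural: AgentParams
    sd_unconstrained: float = 0.2
    n_agents: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd_unconstrained < 0:
            raise ConfigError("sd_unconstrained must be >= 0")
        if self.n_agents < 1:
            raise ConfigError("n_agents must be >= 1")


def q_model_based(v2: np.ndarray, config: TaskConfig) -> np.ndarray:
    """Model-based action values from the true transition matrix."""
    v2 = np.asarray(v2, dtype=float)
    p = config.p_common
    return np.array(
        [p * v2[0] + (1 - p) * v2[1], p * v2[1] + (1 - p) * v2[0]]
    )


def choice_probabilities(
    q_mb: np.ndarray,
    q_mf: np.ndarray,
    params: AgentParams,
    prev_choice: int | None,
) -> np.ndarray:
    """Softmax choice distribution over the two first-stage actions.

    The perseveration bonus is added to the net value of the previously
    chosen action *before* the softmax, so beta = 0 yields (0.5, 0.5)
    regardless of value differences or stickiness.
    """
    net = params.w * np.asarray(q_mb, float) + (1.0 - params.w) * np.asarray(q_mf, float)
    if prev_choice is not None:
        net = net.copy()
        net[prev_choice] += params.persev
    z = params.beta * net
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def update_model_free(
    state: AgentState,
    choice: int,
    state2: int,
    reward: int,
    params: AgentParams,
) -> AgentState:
    """SARSA(lambda) update after one trial; returns a new state.

    Both prediction errors are computed from the pre-update values; the
    eligibility-trace credit (alpha * lam * d2) reaches the first-stage
    value before V(s2) itself is moved.
    """
    new = state.copy()
    d1 = state.v2[state2] - state.q_mf[choice]
    new.q_mf[choice] += params.alpha * d1
    d2 = reward - state.v2[state2]
    new.q_mf[choice] += params.alpha * params.lam * d2
    new.v2[state2] += params.alpha * d2
    new.prev_choice = choice
    return new


def simulate_agent(
    params: AgentParams,
    config: TaskConfig,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "sim",
    walks: RewardWalks | None = None,
    value_init: float = 0.5,
    include_keys: bool = True,
) -> pd.DataFrame:
    """Simulate one full session and return a tidy trial log.

    Columns: subject_id, trial, block, choice, transition, state2,
    reward, plus (if ``include_keys``) the pressed side ``key`` under a
    per-trial random left/right placement of the two options — raw-key
    patterns are therefore decoupled from location choices, as in the
    on-screen task where option positions shuffle.

    Deterministic given ``seed`` (or a Generator); a fresh reward walk is
    drawn from the same stream unless ``walks`` is supplied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    if walks is None:
        walks = init_walks(config, rng)
    state = AgentState(np.full(2, value_init), np.full(2, value_init))
    rows = []
    for t in range(config.n_trials):
        q_mb = q_model_based(state.v2, config)
        p = choice_probabilities(q_mb, state.q_mf, params, state.prev_choice)
        choice = int(rng.random() < p[1])
        label, state2 = _sample_transition_rng(choice, config, rng)
        reward = int(rng.random() < walks.p_reward[state2, t])
        row = {
            "subject_id": subject_id,
            "trial": t,
            "block": config.block_of(t),
            "choice": choice,
            "transition": label,
            "state2": state2,
            "reward": reward,
        }
        if include_keys:
            side_of_0 = int(rng.random() < 0.5)  # screen side of option 0 this trial
            row["key"] = side_of_0 if choice == 0 else 1 - side_of_0
        rows.append(row)
        state = update_model_free(state, choice, state2, reward, params)
    columns = ["subject_id", "trial", "block", "choice", "transition", "state2", "reward"]
    if include_keys:
        columns.append("key")
    return pd.DataFrame(rows, columns=columns)


def _sample_transition_rng(choice, config, rng):
    major = majority_destination(choice)
    if rng.random() < config.p_common:
        return "common", major
    return "rare", 1 - major


def sample_population(spec: PopulationSpec) -> list[AgentParams]:
    """Draw a cohort of agent parameter sets around the cohort means.

    Each parameter is sampled independently as
    Normal(unconstrained(mu), sd_unconstrained) and mapped back to its
    natural scale.
    """
    rng = np.random.default_rng(spec.seed)
    mu_u = natural_to_unconstrained(spec.mu_natural.to_array())
    draws = rng.normal(mu_u, spec.sd_unconstrained, size=(spec.n_agents, 5))
    return [AgentParams.from_array(unconstrained_to_natural(d)) for d in draws]


def simulate_cohort(
    spec: PopulationSpec,
    config: TaskConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[AgentParams]]:
    """Sample a cohort and simulate one session per agent.

    Per-agent simulation seeds are derived as (seed + index) mod 2^31 so
    cohorts are reproducible agent by agent.  Returns the concatenated
    trial log (subject ids ``agent000`` ...) and the generating
    parameters in the same order.
    """
    if seed is None:
        seed = 0 if spec.seed is None else spec.seed
    cohort = sample_population(spec if spec.seed is not None else replace(spec, seed=seed))
    logs = [
        simulate_agent(
            p, config, seed=(seed + 1 + i) % 2**31, subject_id=f"agent{i:03d}"
        )
        for i, p in enumerate(cohort)
    ]
    return pd.concat(logs, ignore_index=True), cohort
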