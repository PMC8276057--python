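"""Generative model of the simplified two-stage Markov decision task.

The task presents a single first-stage choice between two options
(forest / desert).  Each option leads to one of two second-stage states
(blue / purple alien) through a fixed probabilistic transition: the
*common* destination is reached with probability ``p_common`` (0.7 by
default) and the *rare* one otherwise.  Each second-stage state pays a
unit reward with a probability that drifts across trials as a Gaussian
random walk reflected inside fixed bounds, which keeps agents learning
throughout the session.

Conventions used everywhere in this package: actions, states and trials
are 0-based; action 0 (forest) commonly leads to state 0 (blue), action 1
(desert) to state 1 (purple).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ValidationError

__all__ = [
    "TaskConfig",
    "RewardWalks",
    "init_walks",
    "sample_transition",
    "sample_reward",
    "reflect",
    "majority_destination",
]

TransitionLabel = Literal["common", "rare"]


@dataclass(frozen=True)
class TaskConfig:
    """Immutable description of the task environment.

    Parameters
    ----------
    n_trials, n_blocks, block_size
        Session structure: ``n_blocks * block_size`` must equal
        ``n_trials``.  The default session is 201 trials in 3 blocks
        of 67.
    p_common
        Probability that a first-stage choice leads to its majority
        (common) second-stage state.  Must lie in (0.5, 1].
    reward_value
        Value of one coin in cents; bookkeeping only, never enters the
        learning model (rewards are 0/1).
    walk_sd
        Standard deviation of the per-trial Gaussian increment of each
        reward probability.
    walk_bounds
        Reflecting (lower, upper) bounds for the reward probabilities.
    walk_init
        Either ``"uniform"`` (initial probabilities drawn uniformly
        inside the bounds) or a fixed pair of probabilities.
    seed
        Default seed used when no explicit RNG is supplied to the
        sampling helpers.
    """

    n_trials: int = 201
    n_blocks: int = 3
    block_size: int = 67
    p_common: float = 0.7
    reward_value: int = 5
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    walk_init: str | tuple[float, float] = "uniform"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_blocks * self.block_size != self.n_trials:
            raise ConfigError(
                f"n_blocks * block_size = {self.n_blocks * self.block_size} "
                f"!= n_trials = {self.n_trials}"
            )
        if not 0.5 < self.p_common <= 1.0:
            raise ConfigError(f"p_common must be in (0.5, 1], got {self.p_common}")
        lo, hi = self.walk_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"walk_bounds must satisfy 0 <= lo < hi <= 1, got {self.walk_bounds}")
        if self.walk_sd < 0:
            raise ConfigError(f"walk_sd must be >= 0, got {self.walk_sd}")
        if self.walk_init != "uniform":
            init = tuple(self.walk_init)
            if len(init) != 2 or not all(lo <= p <= hi for p in init):
                raise ConfigError(
                    f"fixed walk_init must be a pair inside walk_bounds, got {self.walk_init}"
                )
            object.__setattr__(self, "walk_init", init)

    def block_of(self, t: int) -> int:
        """Block index (0-based) of trial ``t``."""
        return t // self.block_size


@dataclass(frozen=True)
class RewardWalks:
    """Reward probabilities for both second-stage states on every trial.

    ``p_reward`` has shape ``(2, n_trials)``; row ``s`` is the payout
    probability of second-stage state ``s`` across the session.
    """

    p_reward: np.ndarray
    bounds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_reward, dtype=float)
        if p.ndim != 2 or p.shape[0] != 2:
            raise ConfigError(f"p_reward must have shape (2, n_trials), got {p.shape}")
        lo, hi = self.bounds
        if p.size and (p.min() < lo - 1e-12 or p.max() > hi + 1e-12):
            raise ConfigError("reward walk leaves its bounds")
        object.__setattr__(self, "p_reward", p)

    @property
    def n_trials(self) -> int:
        return self.p_reward.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export for audit: columns trial, p_state0, p_state1."""
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "p_state0": self.p_reward[0],
                "p_state1": self.p_reward[1],
            }
        )


def majority_destination(choice: int) -> int:
    """Second-stage state most commonly reached from ``choice``.

    The canonical orientation is the identity map: forest (0) -> blue (0),
    desert (1) -> purple (1).
    """
    if choice not in (0, 1):
        raise ValidationError(f"choice must be 0 or 1, got {choice}")
    return choice


def reflect(x: np.ndarray | float, lo: float, hi: float) -> np.ndarray | float:
    """Fold ``x`` back into ``[lo, hi]`` by repeated boundary reflection.

    A value that overshoots a bound is mirrored about it (p -> 2*bound - p),
    as many times as needed; implemented in closed form via the sawtooth
    (triangle-wave) identity so arbitrarily large excursions are handled.
    """
    width = hi - lo
    y = np.mod(np.asarray(x, dtype=float) - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    out = lo + y
    return float(out) if np.isscalar(x) else out


def _as_rng(rng: np.random.Generator | int | None, config: TaskConfig) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is None:
        rng = config.seed
    return np.random.default_rng(rng)


def init_walks(config: TaskConfig, rng: np.random.Generator | int | None = None) -> RewardWalks:
    """Generate the session's reflected Gaussian reward-probability walks.

    Row ``s``, trial ``t``:  p[s, t] = reflect(p[s, t-1] + N(0, walk_sd^2)).
    Deterministic given the RNG state / seed.
    """
    rng = _as_rng(rng, config)
    lo, hi = config.walk_bounds
    n = config.n_trials
    p = np.empty((2, n), dtype=float)
    if n == 0:
        return RewardWalks(p, bounds=config.walk_bounds)
    if config.walk_init == "uniform":
        p[:, 0] = rng.uniform(lo, hi, size=2)
    else:
        p[:, 0] = config.walk_init
    steps = rng.normal(0.0, config.walk_sd, size=(2, n - 1)) if n > 1 else None
    for t in range(1, n):
        p[:, t] = reflect(p[:, t - 1] + steps[:, t - 1], lo, hi)
    return RewardWalks(p, bounds=config.walk_bounds)


def sample_transition(
    choice: int, config: TaskConfig, rng: np.random.Generator | int | None = None
) -> tuple[TransitionLabel, int]:
    """Draw the transition for a first-stage choice.

    Returns ``("common", majority_destination(choice))`` with probability
    ``p_common``, otherwise ``("rare", other_state)``.
    """
    rng = _as_rng(rng, config)
    major = majority_destination(choice)
    if rng.random() < config.p_common:
        return "common", major
    return "rare", 1 - major


def sample_reward(
    state2: int,
    t: int,
    walks: RewardWalks,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Bernoulli reward draw for second-stage state ``state2`` on trial ``t``."""
    if state2 not in (0, 1):
        raise ValidationError(f"state2 must be 0 or 1, got {state2}")
    if not 0 <= t < walks.n_trials:
        raise ValidationError(f"trial index {t} out of range [0, {walks.n_trials})")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return int(rng.random() < walks.p_reward[state2, t])
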