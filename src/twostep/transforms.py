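"""Bijections between natural and unconstrained parameter scales.

MCMC and optimisation run on an unconstrained 5-vector; the natural
scales are recovered through these maps:

* ``alpha``, ``w``, ``lam``  in [0, 1]      <->  logit / logistic
* ``beta``                   in [0, 20]     <->  20 * logistic(x)
* ``persev``                 in [-1, 1]     <->  2 * logistic(x) - 1

Boundary values (exactly 0, 1, etc.) are clamped into the open interval
by a configurable epsilon before the logit, so pure agents (w = 0 or 1)
have finite unconstrained coordinates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "PARAM_NAMES",
    "BETA_MAX",
    "natural_to_unconstrained",
    "unconstrained_to_natural",
]

PARAM_NAMES: tuple[str, ...] = ("alpha", "beta", "w", "lam", "persev")
BETA_MAX: float = 20.0
DEFAULT_EPS: float = 1e-6


def natural_to_unconstrained(values: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Map natural-scale parameter vectors (..., 5) to the unconstrained scale."""
    v = np.asarray(values, dtype=float)
    u = np.empty_like(v)
    unit = np.clip(v[..., [0, 2, 3]], eps, 1.0 - eps)
    u[..., [0, 2, 3]] = logit(unit)
    u[..., 1] = logit(np.clip(v[..., 1] / BETA_MAX, eps, 1.0 - eps))
    u[..., 4] = logit(np.clip((v[..., 4] + 1.0) / 2.0, eps, 1.0 - eps))
    return u


def unconstrained_to_natural(values: np.ndarray) -> np.ndarray:
    """Inverse of :func:`natural_to_unconstrained` (exact, no clamping)."""
    u = np.asarray(values, dtype=float)
    v = np.empty_like(u)
    v[..., [0, 2, 3]] = expit(u[..., [0, 2, 3]])
    v[..., 1] = BETA_MAX * expit(u[..., 1])
    v[..., 4] = 2.0 * expit(u[..., 4]) - 1.0
    return v
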