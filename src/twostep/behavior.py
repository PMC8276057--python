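"""Stay/switch analysis and response-quality checks.

The central behavioural signature of the task lives in the probability
of repeating the previous first-stage choice (*staying*) as a function
of the previous trial's reward and transition type.  Model-free
learners stay more after reward regardless of transition; model-based
learners show a reward x transition crossover because a reward reached
through a rare transition is credited to the unchosen option.

This module provides the 2x2 stay table, a hierarchical (mixed-effects)
logistic regression of stay on previous reward, previous transition and
their interaction with a full per-subject random-effect structure

    stay ~ reward * transition + (1 + reward * transition | subject)

estimated by Bayesian MCMC (adaptive Metropolis-within-Gibbs on a
non-centred parameterisation, JIT-compiled), and the response-quality
flagger used by the online task to catch disengaged responding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import norm

from .exceptions import ValidationError

__all__ = [
    "StayTable",
    "GlmmResult",
    "QCThresholds",
    "QCReport",
    "stay_table",
    "stay_frame",
    "fit_stay_glmm",
    "qc_flags",
]

FIXED_TERMS = ("intercept", "reward", "transition", "reward:transition")


# ---------------------------------------------------------------------------
# Stay tables


@dataclass(frozen=True)
class StayTable:
    """Stay counts and proportions in the 2x2 previous-outcome design.

    ``cells`` maps (transition, reward) — e.g. ("common", "rewarded") —
    to (stays, opportunities).  ``proportion`` is NaN where a cell has
    no opportunities (undefined, not zero).
    """

    cells: dict[tuple[str, str], tuple[int, int]]

    def proportion(self, transition: str, reward: str) -> float:
        stays, n = self.cells[(transition, reward)]
        return stays / n if n > 0 else math.nan

    @property
    def n_opportunities(self) -> int:
        return sum(n for _, n in self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (trans, rew), (stays, n) in self.cells.items():
            rows.append(
                {
                    "transition": trans,
                    "reward": rew,
                    "stays": stays,
                    "opportunities": n,
                    "proportion": stays / n if n > 0 else math.nan,
                }
            )
        return pd.DataFrame(rows)


def stay_frame(logs: pd.DataFrame, exclude_block_starts: bool = False) -> pd.DataFrame:
    """Per-trial stay outcomes with previous-trial predictors.

    One row per stay opportunity (every trial after the first, per
    subject): columns subject_id, stay (0/1), prev_reward (0/1),
    prev_transition ('common'/'rare').  With ``exclude_block_starts``
    the first trial of each block is dropped from the outcomes.
    """
    if "subject_id" not in logs.columns:
        logs = logs.assign(subject_id="s0")
    parts = []
    for sid, g in logs.groupby("subject_id", sort=False):
        g = g.sort_values("trial")
        if len(g) < 2:
            continue
        cur = g.iloc[1:]
        prev = g.iloc[:-1]
        part = pd.DataFrame(
            {
                "subject_id": sid,
                "trial": cur["trial"].to_numpy(),
                "stay": (cur["choice"].to_numpy() == prev["choice"].to_numpy()).astype(int),
                "prev_reward": prev["reward"].to_numpy(),
                "prev_transition": prev["transition"].to_numpy(),
            }
        )
        if exclude_block_starts and "block" in g.columns:
            block_changed = cur["block"].to_numpy() != prev["block"].to_numpy()
            part = part[~block_changed]
        parts.append(part)
    if not parts:
        raise ValidationError("need at least one subject with >= 2 trials")
    return pd.concat(parts, ignore_index=True)


def stay_table(log: pd.DataFrame, exclude_block_starts: bool = False) -> StayTable:
    """2x2 stay table over (previous transition) x (previous reward)."""
    if len(log) < 2:
        raise ValidationError(f"need >= 2 trials for a stay table, got {len(log)}")
    sf = stay_frame(log, exclude_block_starts=exclude_block_starts)
    cells = {}
    for trans in ("common", "rare"):
        for rew_label, rew in (("rewarded", 1), ("unrewarded", 0)):
            sel = sf[(sf.prev_transition == trans) & (sf.prev_reward == rew)]
            cells[(trans, rew_label)] = (int(sel.stay.sum()), int(len(sel)))
    return StayTable(cells)


# ---------------------------------------------------------------------------
# Hierarchical logistic regression


@dataclass(frozen=True)
class GlmmResult:
    """Population-level estimates from the hierarchical stay regression.

    ``fixed`` holds one row per fixed effect (posterior mean, posterior
    SD as the standard error, z = mean/sd and the two-sided normal
    p-value).  ``re_sd`` are posterior-mean random-effect standard
    deviations for the subject-level intercept and slopes.
    """

    fixed: pd.DataFrame
    re_sd: dict[str, float]
    n_subjects: int
    n_observations: int
    coding: str
    rhat: np.ndarray
    converged: bool

    def coef(self, term: str) -> float:
        return float(self.fixed.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.fixed.loc[term, "p"])


@njit(cache=True)
def _glmm_mwg(X, y, start, stop, n_warmup, n_draws, seed):  # pragma: no cover
    """Adaptive Metropolis-within-Gibbs for the random-slope logistic model.

    Non-centred parameterisation: eta_n = x_n . beta + x_n . (sigma * z_i(n)),
    z_i ~ N(0, I4), beta_k ~ N(0, 5^2), sigma_k ~ half-normal(1).
    Returns draws of (beta[0..3], sigma[0..3]) with shape (n_draws, 8).
    """
    np.random.seed(seed)
    n_sub = start.shape[0]
    n_obs = X.shape[0]
    p = X.shape[1]

    beta = np.zeros(p)
    z = np.zeros((n_sub, p))
    ls = np.full(p, -1.5)  # log sigma
    sigma = np.exp(ls)

    eta = np.zeros(n_obs)

    def row_ll(eta_n, y_n):
        # y*eta - log(1 + exp(eta)), numerically stable
        a = eta_n if eta_n > 0.0 else 0.0
        return y_n * eta_n - (a + np.log(np.exp(0.0 - a) + np.exp(eta_n - a)))

    # adaptation scales
    s_z = np.full(n_sub, 0.3)
    s_b = np.full(p, 0.05)
    s_s = np.full(p, 0.3)
    acc_z = np.zeros(n_sub)
    acc_b = np.zeros(p)
    acc_s = np.zeros(p)

    draws = np.empty((n_draws, 2 * p))
    total = n_warmup + n_draws
    adapt_every = 50

    for it in range(total):
        # --- subject blocks
        for i in range(n_sub):
            prop = z[i] + s_z[i] * np.random.standard_normal(p)
            d_lp = 0.0
            for k in range(p):
                d_lp -= 0.5 * (prop[k] * prop[k] - z[i, k] * z[i, k])
            for n in range(start[i], stop[i]):
                de = 0.0
                for k in range(p):
                    de += X[n, k] * sigma[k] * (prop[k] - z[i, k])
                d_lp += row_ll(eta[n] + de, y[n]) - row_ll(eta[n], y[n])
            if np.log(np.random.random()) < d_lp:
                for n in range(start[i], stop[i]):
                    de = 0.0
                    for k in range(p):
                        de += X[n, k] * sigma[k] * (prop[k] - z[i, k])
                    eta[n] += de
                z[i] = prop
                acc_z[i] += 1.0

        # --- fixed effects, componentwise
        for k in range(p):
            d = s_b[k] * np.random.standard_normal()
            new_b = beta[k] + d
            d_lp = -0.5 * (new_b * new_b - beta[k] * beta[k]) / 25.0
            for n in range(n_obs):
                d_lp += row_ll(eta[n] + X[n, k] * d, y[n]) - row_ll(eta[n], y[n])
            if np.log(np.random.random()) < d_lp:
                for n in range(n_obs):
                    eta[n] += X[n, k] * d
                beta[k] = new_b
                acc_b[k] += 1.0

        # --- random-effect scales, componentwise
        for k in range(p):
            new_ls = ls[k] + s_s[k] * np.random.standard_normal()
            new_sig = np.exp(new_ls)
            # half-normal(1) prior on sigma plus log-Jacobian of exp
            d_lp = -0.5 * (new_sig * new_sig - sigma[k] * sigma[k]) + (new_ls - ls[k])
            d_sig = new_sig - sigma[k]
            for i in range(n_sub):
                zk = z[i, k]
                for n in range(start[i], stop[i]):
                    d_lp += row_ll(eta[n] + X[n, k] * zk * d_sig, y[n]) - row_ll(eta[n], y[n])
            if np.log(np.random.random()) < d_lp:
                for i in range(n_sub):
                    zk = z[i, k]
                    for n in range(start[i], stop[i]):
                        eta[n] += X[n, k] * zk * d_sig
                ls[k] = new_ls
                sigma[k] = new_sig
                acc_s[k] += 1.0

        # --- warmup adaptation toward ~0.35 acceptance
        if it < n_warmup and (it + 1) % adapt_every == 0:
            for i in range(n_sub):
                s_z[i] *= np.exp((acc_z[i] / adapt_every - 0.35) * 0.5)
                acc_z[i] = 0.0
            for k in range(p):
                s_b[k] *= np.exp((acc_b[k] / adapt_every - 0.35) * 0.5)
                s_s[k] *= np.exp((acc_s[k] / adapt_every - 0.35) * 0.5)
                acc_b[k] = 0.0
                acc_s[k] = 0.0

        if it >= n_warmup:
            j = it - n_warmup
            for k in range(p):
                draws[j, k] = beta[k]
                draws[j, p + k] = sigma[k]
    return draws


def _design(sf: pd.DataFrame, coding: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if coding == "effects":
        rew = np.where(sf.prev_reward.to_numpy() == 1, 1.0, -1.0)
        trn = np.where(sf.prev_transition.to_numpy() == "common", 1.0, -1.0)
    elif coding == "dummy":
        rew = (sf.prev_reward.to_numpy() == 1).astype(float)
        trn = (sf.prev_transition.to_numpy() == "common").astype(float)
    else:
        raise ValidationError(f"coding must be 'effects' or 'dummy', got {coding!r}")
    X = np.column_stack([np.ones(len(sf)), rew, trn, rew * trn])
    y = sf.stay.to_numpy(float)
    codes, _ = pd.factorize(sf.subject_id, sort=False)
    order = np.argsort(codes, kind="stable")
    return X[order], y[order], codes[order], order


def fit_stay_glmm(
    logs: pd.DataFrame,
    coding: str = "effects",
    exclude_block_starts: bool = False,
    n_chains: int = 4,
    n_warmup: int = 1500,
    n_draws: int = 1500,
    seed: int | None = 0,
) -> GlmmResult:
    """Fit stay ~ reward * transition + (1 + reward * transition | subject).

    Bayesian hierarchical logistic regression with independent
    subject-level random intercept and slopes; fixed-effect estimates
    are posterior means on the conditional (subject-specific) scale,
    standard errors are posterior SDs.  Weakly informative priors
    (Normal(0, 5) on fixed effects, half-normal(1) on random-effect
    SDs) regularise degenerate or separated data instead of failing.

    ``coding='effects'`` codes rewarded/common as +1 and
    unrewarded/rare as -1; ``'dummy'`` uses 0/1 indicators.
    """
    if logs["subject_id"].nunique() < 2:
        raise ValidationError("need >= 2 subjects for the hierarchical regression")
    sf = stay_frame(logs, exclude_block_starts=exclude_block_starts)
    X, y, subj, _ = _design(sf, coding)
    n_sub = int(subj.max()) + 1
    start = np.searchsorted(subj, np.arange(n_sub)).astype(np.int64)
    stop = np.searchsorted(subj, np.arange(n_sub), side="right").astype(np.int64)

    base = np.random.SeedSequence(seed).generate_state(n_chains) % 2**31
    chains = np.stack(
        [
            _glmm_mwg(X, y, start, stop, n_warmup, n_draws, int(s))
            for s in base
        ]
    )  # (n_chains, n_draws, 8)

    import arviz as az

    ds = az.convert_to_dataset(chains[:, :, :4])
    rhat = az.rhat(ds)["x"].to_numpy()

    flat = chains.reshape(-1, 8)
    est = flat[:, :4].mean(axis=0)
    se = flat[:, :4].std(axis=0, ddof=1)
    zval = est / se
    pval = 2.0 * norm.sf(np.abs(zval))
    fixed = pd.DataFrame(
        {"estimate": est, "se": se, "z": zval, "p": pval}, index=list(FIXED_TERMS)
    )
    re_sd = {term: float(flat[:, 4 + k].mean()) for k, term in enumerate(FIXED_TERMS)}
    return GlmmResult(
        fixed=fixed,
        re_sd=re_sd,
        n_subjects=n_sub,
        n_observations=len(y),
        coding=coding,
        rhat=rhat,
        converged=bool(np.all(rhat < 1.05)),
    )


# ---------------------------------------------------------------------------
# Response-quality flagger


@dataclass(frozen=True)
class QCThresholds:
    """Run-length thresholds for the online response-quality warnings.

    Defaults are calibrated so that a typical engaged learner (hybrid
    agent at mid-range parameters) triggers a warning in well under 5%
    of sessions, while mechanical responding (key mashing, strict
    alternation, never switching location, frequent misses) is caught
    within a block.
    """

    consecutive_keys: int = 13
    alternating_keys: int = 13
    same_location: int = 25
    missed_count: int = 5
    missed_window: int = 20


@dataclass(frozen=True)
class SubjectQC:
    subject_id: str
    longest_consecutive_keys: int
    longest_alternating_keys: int
    longest_same_location: int
    max_missed_in_window: int
    flags: dict[str, bool]
    warning_count: int
    aborted: bool


@dataclass(frozen=True)
class QCReport:
    subjects: list[SubjectQC]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "longest_consecutive_keys": s.longest_consecutive_keys,
                    "longest_alternating_keys": s.longest_alternating_keys,
                    "longest_same_location": s.longest_same_location,
                    "max_missed_in_window": s.max_missed_in_window,
                    "warning_count": s.warning_count,
                    "aborted": s.aborted,
                    **{f"flag_{k}": v for k, v in s.flags.items()},
                }
                for s in self.subjects
            ]
        )

    def any_flagged(self) -> bool:
        return any(s.warning_count > 0 for s in self.subjects)


def _longest_run(vals: np.ndarray) -> int:
    best = run = 0
    prev = None
    for v in vals:
        if v < 0:  # missed response breaks every run
            run, prev = 0, None
            continue
        run = run + 1 if v == prev else 1
        prev = v
        best = max(best, run)
    return best


def _longest_alternation(vals: np.ndarray) -> int:
    best = run = 0
    prev = None
    for v in vals:
        if v < 0:
            run, prev = 0, None
            continue
        run = run + 1 if (prev is not None and v == 1 - prev) else 1
        prev = v
        best = max(best, run)
    return best


def _max_missed(vals: np.ndarray, window: int) -> int:
    miss = (vals < 0).astype(int)
    if len(miss) <= window:
        return int(miss.sum())
    c = np.convolve(miss, np.ones(window, dtype=int), mode="valid")
    return int(c.max())


def qc_flags(log: pd.DataFrame, thresholds: QCThresholds | None = None) -> QCReport:
    """Scan trial logs for the online task's disengagement patterns.

    Uses the raw ``key`` column when present (pressed side; -1 = missed
    response) for the key-press patterns and ``choice`` for location
    streaks; without a key column, choices stand in for keys.  A flag is
    raised when a run reaches its threshold; two or more flagged
    patterns mark the session as aborted (warn once, then stop).
    """
    if len(log) == 0:
        raise ValidationError("trial log is empty")
    th = thresholds or QCThresholds()
    if "subject_id" not in log.columns:
        log = log.assign(subject_id="s0")
    subjects = []
    for sid, g in log.groupby("subject_id", sort=False):
        g = g.sort_values("trial")
        choices = g["choice"].to_numpy(np.int64)
        keys = g["key"].to_numpy(np.int64) if "key" in g.columns else choices
        runs = {
            "consecutive_keys": _longest_run(keys),
            "alternating_keys": _longest_alternation(keys),
            "same_location": _longest_run(choices),
        }
        missed = max(_max_missed(keys, th.missed_window), _max_missed(choices, th.missed_window))
        flags = {
            "consecutive_keys": runs["consecutive_keys"] >= th.consecutive_keys,
            "alternating_keys": runs["alternating_keys"] >= th.alternating_keys,
            "same_location": runs["same_location"] >= th.same_location,
            "missed": missed >= th.missed_count,
        }
        n_warn = sum(flags.values())
        subjects.append(
            SubjectQC(
                subject_id=str(sid),
                longest_consecutive_keys=runs["consecutive_keys"],
                longest_alternating_keys=runs["alternating_keys"],
                longest_same_location=runs["same_location"],
                max_missed_in_window=missed,
                flags=flags,
                warning_count=n_warn,
                aborted=n_warn >= 2,
            )
        )
    return QCReport(subjects)
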