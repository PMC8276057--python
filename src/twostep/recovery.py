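"""Simulation -> fit -> compare parameter-recovery harness.

Validates the whole pipeline: sample a cohort of agents with known
parameters, simulate a session per agent, re-estimate each agent's
parameters from its simulated choices, and tabulate generating versus
recovered means per parameter.  Also produces the four-bar stay
probability signature data that distinguishes model-free, model-based
and hybrid cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .agents import AgentParams, PopulationSpec, sample_population, simulate_agent
from .behavior import stay_table
from .exceptions import EstimationError
from .fitting import PosteriorSummary, PriorSpec, fit_map, fit_mcmc
from .task import TaskConfig
from .transforms import PARAM_NAMES

__all__ = [
    "VALIDATION_COHORTS",
    "RecoveryReport",
    "oracle_fitter",
    "run_recovery",
    "signature_data",
    "plot_signatures",
]

# Canonical validation cohorts: natural-scale parameter means
# (alpha, beta, w, lam, persev).  "hybrid_daw" uses the empirical means
# of the original two-step study's hybrid fits; the pure and balanced
# cohorts pin w at its extremes / midpoint.
VALIDATION_COHORTS: dict[str, AgentParams] = {
    "hybrid_daw": AgentParams(0.54, 5.24, 0.39, 0.57, 0.12),
    "pure_model_based": AgentParams(0.55, 5.18, 1.0, 0.49, 0.0),
    "pure_model_free": AgentParams(0.49, 5.16, 0.0, 0.49, 0.0),
    "hybrid_balanced": AgentParams(0.51, 5.12, 0.51, 0.50, 0.01),
}


@dataclass(frozen=True)
class RecoveryReport:
    """Cohort-level recovery table plus per-agent paired records.

    ``summary`` has one row per (cohort, parameter): the target input
    mean, the realised mean of the sampled generating parameters, the
    mean recovered estimate, and the absolute input-vs-recovered
    difference.  ``agents`` pairs each agent's generating and recovered
    values for scatter / correlation plots.
    """

    summary: pd.DataFrame
    agents: pd.DataFrame

    def cohort_mean(self, cohort: str, parameter: str, column: str = "estimated_mean") -> float:
        row = self.summary[
            (self.summary.cohort == cohort) & (self.summary.parameter == parameter)
        ]
        return float(row[column].iloc[0])

    def correlation(self, cohort: str, parameter: str) -> float:
        sel = self.agents[
            (self.agents.cohort == cohort) & (self.agents.parameter == parameter)
        ]
        return float(np.corrcoef(sel.generated, sel.recovered)[0, 1])


def oracle_fitter(log, prior, config, seed, true_params: AgentParams) -> AgentParams:
    """Identity fitter: returns the generating parameters unchanged.

    Used to verify the harness bookkeeping (all differences must be 0).
    """
    return true_params


def _mcmc_fitter(log, prior, config, seed, true_params=None, **kw) -> AgentParams:
    summary: PosteriorSummary = fit_mcmc(log, prior, config, seed=seed, **kw)
    return summary.median


def _map_fitter(log, prior, config, seed, true_params=None, **kw) -> AgentParams:
    return fit_map(log, prior, config, seed=seed, **kw)


def run_recovery(
    cohorts: Mapping[str, PopulationSpec],
    config: TaskConfig | None = None,
    prior: PriorSpec | None = None,
    seed: int = 0,
    fitter: str | Callable = "mcmc",
    fit_kwargs: dict | None = None,
) -> RecoveryReport:
    """Full simulation -> fit -> compare run over one or more cohorts.

    Per-cohort and per-agent seeds are derived deterministically from
    ``seed``, so identical inputs give byte-identical reports.  A fit
    that raises :class:`EstimationError` is recorded and excluded from
    the cohort means rather than aborting the run.
    """
    if not cohorts:
        raise ValueError("cohorts must be non-empty")
    config = config or TaskConfig()
    prior = prior or PriorSpec()
    fit_kwargs = fit_kwargs or {}
    if callable(fitter):
        fit = fitter
    elif fitter == "mcmc":
        fit = lambda *a, **k: _mcmc_fitter(*a, **k, **fit_kwargs)  # noqa: E731
    elif fitter == "map":
        fit = lambda *a, **k: _map_fitter(*a, **k, **fit_kwargs)  # noqa: E731
    else:
        raise ValueError(f"unknown fitter {fitter!r}")

    summary_rows = []
    agent_rows = []
    for c_idx, (label, spec) in enumerate(cohorts.items()):
        cohort_seed = (seed + 10_000 * (c_idx + 1)) % 2**31
        if spec.seed is None:
            spec = replace(spec, seed=cohort_seed)
        params_list = sample_population(spec)
        recovered, failed = [], 0
        for a_idx, true_params in enumerate(params_list):
            agent_seed = (cohort_seed + 1 + a_idx) % 2**31
            log = simulate_agent(true_params, config, seed=agent_seed, subject_id=f"{label}-{a_idx:03d}")
            try:
                est = fit(log, prior, config, agent_seed, true_params)
            except EstimationError:
                failed += 1
                continue
            est_arr = est.to_array() if isinstance(est, AgentParams) else np.asarray(est, float)
            gen_arr = true_params.to_array()
            recovered.append(est_arr)
            for k, name in enumerate(PARAM_NAMES):
                agent_rows.append(
                    {
                        "cohort": label,
                        "agent": a_idx,
                        "parameter": name,
                        "generated": gen_arr[k],
                        "recovered": est_arr[k],
                    }
                )
        rec = np.array(recovered) if recovered else np.full((0, 5), np.nan)
        gen = np.array([p.to_array() for p in params_list])
        mu = spec.mu_natural.to_array()
        for k, name in enumerate(PARAM_NAMES):
            est_mean = float(rec[:, k].mean()) if len(rec) else np.nan
            summary_rows.append(
                {
                    "cohort": label,
                    "parameter": name,
                    "input_mean": mu[k],
                    "sampled_input_mean": float(gen[:, k].mean()),
                    "estimated_mean": est_mean,
                    "abs_difference": abs(mu[k] - est_mean) if len(rec) else np.nan,
                    "n_fitted": len(rec),
                    "n_failed": failed,
                }
            )
    return RecoveryReport(
        summary=pd.DataFrame(summary_rows), agents=pd.DataFrame(agent_rows)
    )


def signature_data(logs_by_cohort: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Four-bar stay-probability data per cohort (mean +/- between-agent SEM).

    Expects each cohort's concatenated multi-agent trial log; returns a
    tidy frame with one row per (cohort, transition, reward) and the
    across-agent mean stay proportion, its standard error and agent
    count.
    """
    rows = []
    for label, logs in logs_by_cohort.items():
        per_agent: dict[tuple[str, str], list[float]] = {}
        for _, g in logs.groupby("subject_id", sort=False):
            tab = stay_table(g)
            for key, (stays, n) in tab.cells.items():
                if n > 0:
                    per_agent.setdefault(key, []).append(stays / n)
        for (trans, rew), props in sorted(per_agent.items()):
            arr = np.array(props)
            rows.append(
                {
                    "cohort": label,
                    "transition": trans,
                    "reward": rew,
                    "mean_stay": float(arr.mean()),
                    "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan,
                    "n_agents": len(arr),
                }
            )
    return pd.DataFrame(rows)


def plot_signatures(data: pd.DataFrame, path: str | None = None):
    """Bar plot of the stay-probability signatures, one panel per cohort."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cohorts = list(dict.fromkeys(data.cohort))
    fig, axes = plt.subplots(1, len(cohorts), figsize=(4 * len(cohorts), 3.5), sharey=True)
    axes = np.atleast_1d(axes)
    width = 0.35
    for ax, label in zip(axes, cohorts):
        sub = data[data.cohort == label]
        for j, rew in enumerate(("rewarded", "unrewarded")):
            means = [
                float(sub[(sub.transition == t) & (sub.reward == rew)].mean_stay.iloc[0])
                for t in ("common", "rare")
            ]
            sems = [
                float(sub.loc[(sub.transition == t) & (sub.reward == rew), "sem"].iloc[0])
                for t in ("common", "rare")
            ]
            x = np.arange(2) + (j - 0.5) * width
            ax.bar(x, means, width, yerr=sems, label=rew, capsize=3)
        ax.set_xticks([0, 1], ["common", "rare"])
        ax.set_ylim(0, 1)
        ax.set_title(label)
        ax.set_ylabel("P(stay)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
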