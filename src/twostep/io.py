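"""Trial-log CSV round-tripping, config files and reproducibility headers.

The interchange format for trial logs is a plain UTF-8 CSV with header
``subject_id,trial,block,choice,transition,state2,reward`` (an optional
``key`` column carries raw pressed sides for the QC flagger).  Codes:
choice/state2 in {0, 1}, transition in {common, rare}, reward in
{0, 1}; trial indices are 0-based and contiguous within each subject.
Output files written by this module carry ``# key=value`` comment lines
(package version, config hash, base seed) that readers skip.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .agents import AgentParams, PopulationSpec
from .exceptions import ValidationError
from .task import TaskConfig

__all__ = [
    "REQUIRED_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "validate_trial_log",
    "load_task_config",
    "save_task_config",
    "load_population_spec",
    "config_hash",
]

REQUIRED_COLUMNS = ("subject_id", "trial", "block", "choice", "transition", "state2", "reward")
_CODES = {
    "choice": {0, 1},
    "state2": {0, 1},
    "reward": {0, 1},
    "transition": {"common", "rare"},
}


def validate_trial_log(log: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a trial log; raises naming the offending row/column."""
    for col in REQUIRED_COLUMNS:
        if col not in log.columns:
            raise ValidationError(f"missing required column {col!r}")
    for col, allowed in _CODES.items():
        bad = ~log[col].isin(allowed)
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"row {row}, column {col!r}: invalid value {log[col].loc[row]!r} "
                f"(allowed: {sorted(map(str, allowed))})"
            )
    for sid, g in log.groupby("subject_id", sort=False):
        t = g["trial"].to_numpy()
        expected = range(len(t))
        if list(t) != list(expected):
            raise ValidationError(
                f"subject {sid!r}: trial indices must be 0-based and contiguous"
            )
    return log


def _package_version() -> str:
    from . import __version__

    return __version__


def write_trial_log(
    log: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write a validated trial log as CSV with a reproducibility header."""
    validate_trial_log(log)
    path = Path(path)
    header = {"twostep_version": _package_version(), **(meta or {})}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        log.to_csv(fh, index=False)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV (``#`` header lines are skipped)."""
    df = pd.read_csv(path, comment="#")
    return validate_trial_log(df)


def config_hash(config) -> str:
    """Short stable digest of a config dataclass, for output headers."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def save_task_config(config: TaskConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_task_config(path: str | Path) -> TaskConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "walk_bounds" in raw and raw["walk_bounds"] is not None:
        raw["walk_bounds"] = tuple(raw["walk_bounds"])
    if isinstance(raw.get("walk_init"), list):
        raw["walk_init"] = tuple(raw["walk_init"])
    return TaskConfig(**raw)


def load_population_spec(path: str | Path) -> dict[str, PopulationSpec]:
    """Load one or more cohorts from YAML.

    Layout: mapping of cohort label -> {mu: {alpha, beta, w, lam, persev},
    sd_unconstrained, n_agents, seed}.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    cohorts = {}
    for label, spec in raw.items():
        mu = AgentParams(**spec["mu"])
        cohorts[label] = PopulationSpec(
            mu_natural=mu,
            sd_unconstrained=spec.get("sd_unconstrained", 0.2),
            n_agents=spec.get("n_agents", 100),
            seed=spec.get("seed"),
        )
    return cohorts
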