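"""Small end-to-end parameter-recovery run.

Samples two cohorts (pure model-free and balanced hybrid) of 8 agents,
simulates a session per agent, refits every agent by MCMC, and prints
the generating-vs-recovered table.  The full validation (100 agents x
4 cohorts) is what scripts/acceptance.py runs.
"""

from twostep import PopulationSpec, TaskConfig, run_recovery
from twostep.recovery import VALIDATION_COHORTS

config = TaskConfig()
cohorts = {
    label: PopulationSpec(VALIDATION_COHORTS[label], n_agents=8)
    for label in ("pure_model_free", "hybrid_balanced")
}

report = run_recovery(cohorts, config, seed=2, fitter="mcmc")
print(report.summary.to_string(index=False))
# estimated_mean tracks input_mean for alpha/lam everywhere; the
# model-based weight w separates the cohorts (recovered means keep
# pure-MF below hybrid), with shrinkage toward mid-range at the w=0
# boundary because a 201-trial session only weakly identifies w there.
print("\nw correlation (generated vs recovered), hybrid cohort:",
      round(report.correlation("hybrid_balanced", "w"), 3))
# at 8 agents this correlation is extremely noisy; it stabilises in
# the 100-agent validation runs where the generating spread of w
# (~0.05 natural-scale) is comparable to per-agent recovery noise

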