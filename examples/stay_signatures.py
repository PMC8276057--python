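"""Stay/switch signatures that dissociate model-free from model-based control.

Simulates small pure model-free and pure model-based cohorts and prints
the four-bar stay-probability pattern for each, then fits the
hierarchical stay ~ reward * transition regression to the model-based
cohort (reduced chain lengths to keep the demo quick).
"""

from twostep import PopulationSpec, TaskConfig, fit_stay_glmm, signature_data, simulate_cohort
from twostep.recovery import VALIDATION_COHORTS

config = TaskConfig()
logs = {}
for label in ("pure_model_free", "pure_model_based"):
    spec = PopulationSpec(VALIDATION_COHORTS[label], n_agents=30, seed=1)
    logs[label], _ = simulate_cohort(spec, config)

print(signature_data(logs).to_string(index=False))
# Model-free: rewarded bars sit above unrewarded bars under BOTH
# transitions (reinforcement history only).  Model-based: crossover —
# staying after rewarded-common and unrewarded-rare outcomes.

res = fit_stay_glmm(
    logs["pure_model_based"], coding="effects",
    n_chains=2, n_warmup=600, n_draws=600, seed=0,
)
print("\nModel-based cohort, stay ~ reward * transition (+1/-1 coding):")
print(res.fixed.to_string())
# The reward x transition interaction is the model-based signature; its
# z-statistic dwarfs the reward main effect for this cohort.
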