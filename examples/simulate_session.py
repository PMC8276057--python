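"""Simulate one session of the simplified two-stage task and inspect it.

Builds the default 201-trial task (70/30 transitions, reflected
Gaussian reward walks), runs a hybrid agent through it, and prints the
stay table and response-quality report.
"""

from twostep import AgentParams, TaskConfig, qc_flags, simulate_agent, stay_table

config = TaskConfig()  # 201 trials, 3 blocks of 67, p_common = 0.7
agent = AgentParams(alpha=0.51, beta=5.12, w=0.51, lam=0.50, persev=0.01)

log = simulate_agent(agent, config, seed=42, subject_id="demo")
print(f"simulated {len(log)} trials; rewards earned: {log.reward.sum()} "
      f"({config.reward_value * log.reward.sum()} cents)")

print("\nStay table (stay probability by previous transition x reward):")
print(stay_table(log).to_frame().to_string(index=False))
# A hybrid agent stays most after rewarded-common outcomes; rewards
# reached through rare transitions produce noticeably less staying.

print("\nResponse-quality report (run lengths vs warning thresholds):")
print(qc_flags(log).to_frame().to_string(index=False))
# warning_count 0 means no disengagement pattern (key mashing,
# alternation, location streaks, missed responses) reached threshold.
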