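import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from twostep import (
    AgentParams,
    PopulationSpec,
    QCThresholds,
    TaskConfig,
    ValidationError,
    fit_stay_glmm,
    qc_flags,
    simulate_agent,
    simulate_cohort,
    stay_table,
)
from twostep.behavior import stay_frame
from twostep.recovery import VALIDATION_COHORTS
from conftest import make_log


class TestStayTable:
    def test_always_staying_gives_unit_proportions(self):
        log = make_log([1] * 6, ["common"] * 6, [1] * 6, [1, 0, 1, 0, 1, 0])
        tab = stay_table(log)
        for key, (stays, n) in tab.cells.items():
            if n > 0:
                assert stays == n

    def test_hand_counted_toy_log(self):
        # choices 0,0,1,1,0 ; prev outcomes: (c,1) (c,0) (r,1) (c,1)
        # stays:                               1     0     1     0
        log = make_log(
            [0, 0, 1, 1, 0],
            ["common", "common", "rare", "common", "common"],
            [0, 0, 0, 1, 0],
            [1, 0, 1, 1, 0],
        )
        tab = stay_table(log)
        assert tab.proportion("common", "rewarded") == pytest.approx(0.5)
        assert tab.proportion("common", "unrewarded") == 0.0
        assert tab.proportion("rare", "rewarded") == 1.0
        assert math.isnan(tab.proportion("rare", "unrewarded"))

    def test_opportunities_conserved(self, hybrid_log):
        tab = stay_table(hybrid_log)
        assert tab.n_opportunities == len(hybrid_log) - 1

    def test_excluding_block_starts_drops_two_opportunities(self, hybrid_log):
        tab = stay_table(hybrid_log, exclude_block_starts=True)
        assert tab.n_opportunities == len(hybrid_log) - 3

    def test_single_trial_rejected(self):
        with pytest.raises(ValidationError):
            stay_table(make_log([0], ["common"], [0], [1]))

    def test_model_based_cohort_shows_transition_dependence(self, config):
        spec = PopulationSpec(VALIDATION_COHORTS["pure_model_based"], n_agents=100, seed=5)
        logs, _ = simulate_cohort(spec, config)
        tab = stay_table(logs)
        assert tab.proportion("common", "rewarded") > tab.proportion("rare", "rewarded")


class TestStayGlmm:
    def test_null_data_yields_null_effects(self, config):
        # coin-flip choices carry no history information: every
        # non-intercept fixed effect should sit within 3 SE of zero
        rng = np.random.default_rng(8)
        logs = []
        for s in range(30):
            n = 100
            choices = rng.integers(2, size=n)
            states2 = rng.integers(2, size=n)
            transitions = ["common" if c == x else "rare" for c, x in zip(choices, states2)]
            log = make_log(choices, transitions, states2, rng.integers(2, size=n), subject_id=f"s{s}")
            logs.append(log)
        res = fit_stay_glmm(
            pd.concat(logs, ignore_index=True),
            n_chains=2, n_warmup=600, n_draws=600, seed=0,
        )
        for term in ("reward", "transition", "reward:transition"):
            assert abs(res.fixed.loc[term, "z"]) < 3.0

    def test_agrees_with_lme4_reference(self, tmp_path):
        # independent cross-check: the same random-slope logistic data
        # fitted by lme4's glmer (Laplace ML) and by this module's MCMC
        rng = np.random.default_rng(3)
        true = np.array([0.3, 0.8, 0.0, 1.0])
        rows = []
        for s in range(30):
            b = true + rng.normal(0, 0.3, 4)
            rew = rng.choice([-1.0, 1.0], 150)
            trn = rng.choice([-1.0, 1.0], 150)
            eta = b[0] + b[1] * rew + b[2] * trn + b[3] * rew * trn
            stay = (rng.random(150) < 1 / (1 + np.exp(-eta))).astype(int)
            rows.append(
                pd.DataFrame(
                    dict(subject_id=f"s{s}", stay=stay, reward=rew, transition=trn)
                )
            )
        df = pd.concat(rows, ignore_index=True)

        # route A: this package (fed through its trial-log interface)
        logs = []
        for sid, g in df.groupby("subject_id"):
            n = len(g) + 1
            choices = np.zeros(n, dtype=int)
            choices[1:][g.stay.to_numpy() == 0] = 1
            choices = np.cumsum(np.r_[0, (g.stay.to_numpy() == 0)]) % 2
            rewards = np.r_[(g.reward.to_numpy() == 1).astype(int), 0]
            trans = np.r_[
                np.where(g.transition.to_numpy() == 1, "common", "rare"), ["common"]
            ]
            states2 = [c if t == "common" else 1 - c for c, t in zip(choices, trans)]
            logs.append(make_log(choices, trans, states2, rewards, subject_id=sid))
        ours = fit_stay_glmm(
            pd.concat(logs, ignore_index=True),
            n_chains=2, n_warmup=800, n_draws=800, seed=1,
        )

        # route B: lme4
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- glmer(stay ~ reward*transition + (1 + reward*transition | subject_id),
                   data=d, family=binomial, control=glmerControl(optimizer='bobyqa'))
        co <- summary(m)$coefficients
        write.csv(co, '{tmp_path / "glmer.csv"}')
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "glmer.csv", index_col=0)
        for ours_term, ref_term in [
            ("intercept", "(Intercept)"),
            ("reward", "reward"),
            ("transition", "transition"),
            ("reward:transition", "reward:transition"),
        ]:
            est = ours.fixed.loc[ours_term, "estimate"]
            ref_est = ref.loc[ref_term, "Estimate"]
            ref_se = ref.loc[ref_term, "Std. Error"]
            assert abs(est - ref_est) < max(0.1, 2 * ref_se), (ours_term, est, ref_est)

    def test_requires_multiple_subjects(self, hybrid_log):
        with pytest.raises(ValidationError):
            fit_stay_glmm(hybrid_log)

    def test_dummy_coding_changes_scale_not_signs(self):
        rng = np.random.default_rng(4)
        rows = []
        for s in range(20):
            rew = rng.choice([-1.0, 1.0], 100)
            trn = rng.choice([-1.0, 1.0], 100)
            eta = 0.2 + 0.8 * rew + 1.0 * rew * trn + rng.normal(0, 0.2)
            stay = (rng.random(100) < 1 / (1 + np.exp(-eta))).astype(int)
            choices = np.cumsum(np.r_[0, (stay == 0)]) % 2
            trans = np.r_[np.where(trn == 1, "common", "rare"), ["common"]]
            states2 = [c if t == "common" else 1 - c for c, t in zip(choices, trans)]
            rows.append(
                make_log(choices, trans, states2, np.r_[(rew == 1).astype(int), 0], subject_id=f"s{s}")
            )
        logs = pd.concat(rows, ignore_index=True)
        eff = fit_stay_glmm(logs, coding="effects", n_chains=2, n_warmup=400, n_draws=400, seed=0)
        dum = fit_stay_glmm(logs, coding="dummy", n_chains=2, n_warmup=400, n_draws=400, seed=0)
        assert eff.coding == "effects" and dum.coding == "dummy"
        assert eff.coef("reward") > 0
        # re-expressing the generating model (eta = 0.2 + 0.8 rew + 1.0
        # rew*trn on the +/-1 scale) in 0/1 coordinates gives interaction
        # 4x the effects-coded one and a negative dummy reward slope
        assert dum.coef("reward:transition") == pytest.approx(
            4 * eff.coef("reward:transition"), rel=0.35
        )
        assert dum.coef("reward") < 0


class TestQcFlags:
    def test_consecutive_press_run_flagged(self):
        log = make_log([0] * 12 + [1, 0] * 5, ["common"] * 22, [0] * 22, [0] * 22)
        log["key"] = log["choice"]
        report = qc_flags(log, QCThresholds(consecutive_keys=10))
        s = report.subjects[0]
        assert s.flags["consecutive_keys"]
        assert s.longest_consecutive_keys == 12

    def test_alternation_flagged(self):
        keys = [0, 1] * 6
        log = make_log(keys, ["common"] * 12, keys, [0] * 12)
        log["key"] = keys
        report = qc_flags(log, QCThresholds(alternating_keys=10, same_location=100))
        assert report.subjects[0].flags["alternating_keys"]
        assert report.subjects[0].longest_alternating_keys == 12

    def test_missed_responses_counted_in_window(self):
        keys = ([-1] * 5 + [0] * 15) + [0, 1] * 10
        choices = [max(k, 0) for k in keys]
        log = make_log(choices, ["common"] * 40, choices, [0] * 40)
        log["key"] = keys
        report = qc_flags(log, QCThresholds())
        assert report.subjects[0].flags["missed"]
        assert report.subjects[0].max_missed_in_window == 5

    def test_two_warnings_abort(self):
        keys = [0] * 15 + [0, 1] * 10
        log = make_log(keys, ["common"] * 35, keys, [0] * 35)
        log["key"] = keys
        report = qc_flags(
            log, QCThresholds(consecutive_keys=10, alternating_keys=10, same_location=100)
        )
        assert report.subjects[0].warning_count == 2
        assert report.subjects[0].aborted

    def test_clean_prefix_cannot_create_flags(self):
        rng = np.random.default_rng(0)
        keys = list(rng.integers(2, size=60))
        log = make_log(keys, ["common"] * 60, keys, [0] * 60)
        log["key"] = keys
        base = qc_flags(log).subjects[0]
        prefix_keys = [0, 1, 1, 0, 1, 0, 0, 1] + keys
        log2 = make_log(prefix_keys, ["common"] * 68, prefix_keys, [0] * 68)
        log2["key"] = prefix_keys
        extended = qc_flags(log2).subjects[0]
        assert base.warning_count == 0
        assert extended.warning_count == 0

    def test_engaged_hybrid_agents_rarely_flagged(self, config):
        mu = VALIDATION_COHORTS["hybrid_balanced"]
        flagged = 0
        for seed in range(100):
            log = simulate_agent(mu, config, seed=seed)
            if qc_flags(log).subjects[0].warning_count > 0:
                flagged += 1
        assert flagged <= 5
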