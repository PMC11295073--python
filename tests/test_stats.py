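"""Regressor preparation, mixed-model inference, permutation tests,
interaction probes, previous-reward splits, and the stimulation GLM."""

import numpy as np
import pandas as pd
import pytest

from effortdm.config import GroundTruth, TaskConfig
from effortdm.simulate import (build_offer_schedule, simulate_choices,
                               simulate_rts, simulate_stim_sessions,
                               stim_task_config)
from effortdm.stats import (ModelSpec, REWARD_EFFORT_EFFECTS,
                            compare_value_models, fit_mixed,
                            fit_stimulation_glm, interaction_probe,
                            permutation_test, prepare_regressors,
                            sliding_window_models, split_by_previous_reward)
from conftest import augment_with_fits


@pytest.fixture(scope="module")
def study_table():
    """Four simulated participants, behavioral fits, synthetic power columns.

    The power columns carry known effects: BG beta declines with the current
    effort cost, PFC theta rises with the previous reward.
    """
    cfg = TaskConfig(seed=21)
    truth = GroundTruth()
    frames = []
    for i, pid in enumerate(["P01", "P02", "P03", "P04"]):
        sch = build_offer_schedule(cfg.replace(seed=cfg.seed + i), participant=pid)
        tr = simulate_choices(sch, truth, seed=100 + i)
        tr = simulate_rts(tr, truth, seed=100 + i)
        frames.append(tr)
    trials = pd.concat(frames, ignore_index=True)
    aug = augment_with_fits(trials)
    rng = np.random.default_rng(0)
    z = lambda v: (v - v.mean()) / v.std(ddof=0)
    cost = aug["reward"] - aug["sv"]
    prev_r = aug.groupby(["participant", "session", "block"])["reward"].shift(1)
    prev_r = prev_r.fillna(aug["reward"])
    aug["pow_BG_beta"] = -0.6 * z(cost) + rng.standard_normal(len(aug))
    aug["pow_PFC_theta"] = 0.6 * z(prev_r) + rng.standard_normal(len(aug))
    return aug


class TestPrepare:
    def test_lagged_regressors_missing_at_block_start_only(self, study_table):
        prep = prepare_regressors(study_table)
        t = prep.table
        assert t.loc[t.first_in_block, "reward_tm1"].isna().all()
        assert t.loc[~t.first_in_block, "reward_tm1"].notna().all()

    def test_zscoring_within_participant(self, study_table):
        prep = prepare_regressors(study_table)
        for _, sub in prep.table.groupby("participant"):
            assert sub["reward_t"].mean() == pytest.approx(0.0, abs=1e-9)
            assert sub["reward_t"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_predictor_errors_with_names(self, study_table):
        bad = study_table.copy()
        bad.loc[bad.participant == "P02", "reward"] = 7
        bad.loc[bad.participant == "P02", "sv"] = 7 - (
            bad.loc[bad.participant == "P02", "reward"]
            - bad.loc[bad.participant == "P02", "sv"])
        bad.loc[bad.participant == "P02", "reward"] = 7
        with pytest.raises(ValueError, match="P02"):
            prepare_regressors(bad)

    def test_artifact_and_response_filters_counted(self, study_table):
        t = study_table.copy()
        t.loc[t.index[:3], "choice"] = np.nan
        t.loc[t.index[5], "rt"] = 7.5
        prep = prepare_regressors(t, artifact_ids=[("P01", 10), ("P03", 20)])
        assert prep.base_counts["invalid_or_missing_response"] == 3
        assert prep.base_counts["rt_over_deadline"] == 1
        assert prep.base_counts["artifact"] == 2
        assert len(prep.table) == len(t) - 6

    def test_outlier_rule_catches_constructed_outlier(self, study_table):
        t = study_table.copy()
        mu, sd = t["pow_BG_beta"].mean(), t["pow_BG_beta"].std(ddof=0)
        idx = t.index[t.trial_in_block > 1][0]
        t.loc[idx, "pow_BG_beta"] = mu + 5 * sd
        prep = prepare_regressors(t)
        spec = ModelSpec("pow_BG_beta", "gaussian", tuple(REWARD_EFFORT_EFFECTS))
        res = fit_mixed(spec, prep)
        assert res.filter_report.counts["outlier_3sd"] >= 1

    def test_filter_accounting_exact(self, study_table):
        prep = prepare_regressors(study_table)
        spec = ModelSpec("choice", "binomial", tuple(REWARD_EFFORT_EFFECTS))
        res = fit_mixed(spec, prep)
        rep = res.filter_report
        assert rep.n_analyzed == res.n_observations
        assert rep.n_input == rep.n_analyzed + sum(rep.counts.values())

    def test_requires_augmented_table(self, study_table):
        with pytest.raises(ValueError, match="sv"):
            prepare_regressors(study_table.drop(columns=["sv"]))


class TestFitMixed:
    def test_recovers_known_neural_effects(self, study_table):
        prep = prepare_regressors(study_table)
        beta = fit_mixed(ModelSpec("pow_BG_beta", "gaussian",
                                   tuple(REWARD_EFFORT_EFFECTS)), prep)
        theta = fit_mixed(ModelSpec("pow_PFC_theta", "gaussian",
                                    tuple(REWARD_EFFORT_EFFECTS)), prep)
        assert beta.estimate("effort_t") < 0
        assert beta.lrt_p("effort_t") < 1e-4
        assert theta.estimate("reward_tm1") > 0
        assert theta.lrt_p("reward_tm1") < 1e-4

    def test_choice_model_reward_positive_effort_negative(self, study_table):
        prep = prepare_regressors(study_table)
        res = fit_mixed(ModelSpec("choice", "binomial",
                                  tuple(REWARD_EFFORT_EFFECTS)), prep)
        assert res.estimate("reward_t") > 0
        assert res.estimate("effort_t") < 0
        assert res.lrt_p("reward_t") < 1e-6

    def test_rt_model_difficulty_effects(self, study_table):
        prep = prepare_regressors(study_table)
        res = fit_mixed(ModelSpec("log_rt", "gaussian",
                                  ("ease_t", "ease_tm1")), prep)
        # generated with rt_ease_coef=-0.040, rt_prev_ease_coef=+0.027
        assert res.estimate("ease_t") < 0
        assert res.estimate("ease_tm1") > 0

    def test_missing_column_errors(self, study_table):
        prep = prepare_regressors(study_table)
        with pytest.raises(ValueError, match="missing columns"):
            fit_mixed(ModelSpec("nope", "gaussian", ("reward_t",)), prep)


class TestPermutation:
    def _null_table(self, seed, G=4, n=40):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "participant": np.repeat([f"P{g}" for g in range(G)], n),
            "x": rng.standard_normal(G * n),
            "y": rng.standard_normal(G * n)})

    def test_deterministic_given_seed(self):
        spec = ModelSpec("y", "gaussian", ("x",))
        t = self._null_table(0)
        a = permutation_test(spec, t, "x", n_perms=100, seed=5)
        b = permutation_test(spec, t, "x", n_perms=100, seed=5)
        assert a["perm_p"] == b["perm_p"]

    def test_strong_effect_gives_zero_under_proportion_rule(self):
        rng = np.random.default_rng(99)
        t = self._null_table(1)
        t["y"] = 2.0 * t["x"] + 0.1 * rng.standard_normal(len(t))
        spec = ModelSpec("y", "gaussian", ("x",))
        res = permutation_test(spec, t, "x", n_perms=200, seed=0)
        assert res["perm_p"] == 0.0
        res1 = permutation_test(spec, t, "x", n_perms=200, seed=0,
                                rule="add_one")
        assert res1["perm_p"] == pytest.approx(1 / 201)

    def test_small_n_perms_warns_and_absent_effect_errors(self):
        spec = ModelSpec("y", "gaussian", ("x",))
        t = self._null_table(2)
        with pytest.warns(UserWarning):
            permutation_test(spec, t, "x", n_perms=50, seed=0)
        with pytest.raises(ValueError):
            permutation_test(spec, t, "z", n_perms=100, seed=0)

    def test_null_rejection_rate_near_nominal(self):
        import warnings as _w
        spec = ModelSpec("y", "gaussian", ("x",))
        with _w.catch_warnings():
            _w.simplefilter("ignore", UserWarning)
            rej = sum(permutation_test(spec, self._null_table(100 + i), "x",
                                       n_perms=99, seed=i)["perm_p"] <= 0.05
                      for i in range(40))
        assert rej <= 8  # liberal bound; the calibrated check runs at scale


class TestModelComparison:
    def test_shared_rows_and_dissociation(self, study_table):
        prep = prepare_regressors(study_table)
        cmp = compare_value_models(prep, "pow_BG_beta")
        assert (cmp["sv_model"].n_observations
                == cmp["reward_effort_model"].n_observations)
        # effort-only generator: effort term detected, integrated SV is a
        # diluted proxy and should not beat it
        re_p = cmp["reward_effort_model"].lrt_p("effort_t")
        assert re_p < 1e-4

    def test_interaction_probe_detects_injected_crossterm(self):
        # choices whose log-odds carry a previous x current reward product
        rng = np.random.default_rng(3)
        cfg = TaskConfig(seed=31)
        truth = GroundTruth()
        frames = []
        for i, pid in enumerate(["P01", "P02", "P03", "P04"]):
            sch = build_offer_schedule(cfg.replace(seed=cfg.seed + i),
                                       participant=pid)
            tr = simulate_choices(sch, truth, seed=200 + i)
            tr = simulate_rts(tr, truth, seed=200 + i)
            frames.append(tr)
        aug = augment_with_fits(pd.concat(frames, ignore_index=True))
        z = lambda v: (v - v.mean()) / v.std(ddof=0)
        prev_r = aug.groupby(["participant", "session", "block"])["reward"].shift(1)
        zint = z(z(aug["reward"]) * z(prev_r.fillna(aug["reward"])))
        from scipy.special import expit
        p = expit(np.log(np.clip(aug["p_accept"], 1e-6, 1 - 1e-6)
                         / np.clip(1 - aug["p_accept"], 1e-6, 1 - 1e-6))
                  - 1.2 * zint)
        aug["choice"] = (rng.random(len(aug)) < p).astype(float)
        prep = prepare_regressors(aug)
        probe = interaction_probe(prep)
        probe = probe.set_index("interaction")
        assert probe.loc["reward_tm1:reward_t", "lrt_p"] < 0.01
        assert probe.loc["reward_tm1:reward_t", "estimate"] < 0

    def test_split_excludes_middle_previous_reward(self, study_table):
        prep = prepare_regressors(study_table)
        spec = ModelSpec("choice", "binomial", tuple(REWARD_EFFORT_EFFECTS))
        from effortdm.stats import _model_frame
        frame, _ = _model_frame(spec, prep, extra_cols=("reward_level_tm1",))
        splits = split_by_previous_reward(prep)
        n_low = (frame["reward_level_tm1"].isin([1, 4])).sum()
        n_high = (frame["reward_level_tm1"].isin([10, 13])).sum()
        assert splits["low"].n_observations == n_low
        assert splits["high"].n_observations == n_high
        n_mid = (frame["reward_level_tm1"] == 7).sum()
        assert n_low + n_high + n_mid == len(frame)
        assert n_mid > 0


class TestSlidingModels:
    def test_one_row_per_window_and_effect_localization(self, study_table):
        prep = prepare_regressors(study_table)
        # synthetic sliding table: effect on effort only inside 0.5-1.5 s
        rng = np.random.default_rng(4)
        base = prep.table[["participant", "trial_global", "effort_t"]].dropna()
        rows = []
        for w in range(73):
            t0 = w * 0.025
            slope = -0.8 if 0.5 <= t0 + 0.1 <= 1.5 else 0.0
            rows.append(pd.DataFrame({
                "participant": base["participant"],
                "trial_global": base["trial_global"],
                "power": slope * base["effort_t"]
                + rng.standard_normal(len(base)),
                "window": w, "t_start": t0}))
        sliding = pd.concat(rows, ignore_index=True)
        spec = ModelSpec("pow_win", "gaussian", ("effort_t",))
        out = sliding_window_models(spec, sliding, prep)
        assert out["window"].nunique() == 73
        est = out.set_index("t_start")["estimate"]
        inside = est[(est.index >= 0.5) & (est.index <= 1.3)].abs().mean()
        outside = est[(est.index < 0.4) | (est.index > 1.6)].abs().mean()
        assert inside > 3 * outside


class TestStimGLM:
    def test_positive_stim_effect_recovered(self, truth):
        cfg = stim_task_config(seed=41)
        stim_truth = truth.replace(sv_offset=2.0)  # indifference-point shift
        signs = []
        for seed in (0, 1, 2):
            tr = simulate_stim_sessions(cfg, stim_truth, truth, seed=seed)
            res = fit_stimulation_glm(tr)
            terms = res["terms"].set_index("term")
            signs.append(terms.loc["stim", "estimate"] > 0)
            assert res["n_observations"] == 200
        assert all(signs)

    def test_null_stim_effect_not_flagged_significant(self, truth):
        cfg = stim_task_config(seed=42)
        tr = simulate_stim_sessions(cfg, truth, truth, seed=7)
        res = fit_stimulation_glm(tr)
        terms = res["terms"].set_index("term")
        assert terms.loc["stim", "lrt_p"] > 0.01

    def test_separation_flagged_with_fallback(self, truth):
        cfg = stim_task_config(seed=43)
        tr = simulate_stim_sessions(cfg, truth, truth, seed=8)
        tr["choice"] = (tr["reward"] > 7).astype(float)  # perfectly separable
        res = fit_stimulation_glm(tr, fit_behavior=False)
        assert res["separation"]
        assert "fallback" in res

    def test_condition_specific_behavior_fits_returned(self, truth):
        cfg = stim_task_config(seed=44)
        lenient = truth.replace(k=truth.k * 0.5)
        tr = simulate_stim_sessions(cfg, lenient, truth, seed=9)
        res = fit_stimulation_glm(tr)
        fits = res["behavior_fits"]
        assert fits["on"] is not None and fits["off"] is not None
        assert fits["on"].k < fits["off"].k
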