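"""Shared fixtures and the end-to-end sign-recovery harness."""

import pandas as pd
import pytest

from effortdm import (GroundTruth, TaskConfig, build_offer_schedule,
                      simulate_choices, simulate_rts, simulate_study)
from effortdm.stats import (ModelSpec, REWARD_EFFORT_EFFECTS, fit_mixed,
                            prepare_regressors)
from effortdm.workflow import augment_with_behavior, decision_band_power

# re-exported for tests that build augmented tables by hand
augment_with_fits = augment_with_behavior


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def one_participant_trials(default_config, truth):
    """150 trials with model-driven choices and RTs for one participant."""
    sch = build_offer_schedule(default_config, participant="P01")
    tr = simulate_choices(sch, truth, seed=11)
    return simulate_rts(tr, truth, seed=11)


def run_sign_recovery(seed, n_participants=4):
    """Full synthetic pipeline at paper scale for one seed.

    Returns the fitted fixed effects (current effort on BG low-beta power,
    previous reward on PFC theta power) from the reward/effort mixed model.
    """
    cfg = TaskConfig(seed=seed)
    truth = GroundTruth()
    trials, epochs = simulate_study(
        cfg, truth, participants=[f"P{i+1:02d}" for i in range(n_participants)],
        seed=seed)
    aug = augment_with_behavior(trials)
    power, artifact_ids = decision_band_power(epochs)
    aug = aug.merge(power, on=["participant", "trial_global"], how="left")
    prepared = prepare_regressors(aug, artifact_ids=artifact_ids)
    res_beta = fit_mixed(ModelSpec("pow_BG_beta", "gaussian",
                                   tuple(REWARD_EFFORT_EFFECTS)), prepared)
    res_theta = fit_mixed(ModelSpec("pow_PFC_theta", "gaussian",
                                    tuple(REWARD_EFFORT_EFFECTS)), prepared)
    return {
        "effort_on_bg_beta": res_beta.estimate("effort_t"),
        "prev_reward_on_pfc_theta": res_theta.estimate("reward_tm1"),
    }
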