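"""Simulate the effort-based decision task for one participant.

Builds the default design (5 reward x 5 effort offers, 3 blocks x 25 trials
x 2 sessions), draws choices from the ground-truth subjective-value model
(SV = R - k*E^2 through a softmax with temperature beta), and prints the
acceptance rates across the offer grid.
"""

from effortdm import GroundTruth, TaskConfig, build_offer_schedule, \
    simulate_choices, simulate_rts

cfg = TaskConfig(seed=0)
truth = GroundTruth()  # k = 15, beta = 1

schedule = build_offer_schedule(cfg, participant="P01")
trials = simulate_choices(schedule, truth, seed=0)
trials = simulate_rts(trials, truth, seed=0)

print(f"trials: {len(trials)}  (blocks x trials x sessions = "
      f"{cfg.blocks_per_session} x {cfg.trials_per_block} x {cfg.sessions})")
print(f"overall acceptance: {trials.choice.mean():.2f}   "
      f"mean RT: {trials.rt.mean():.2f} s")
print("\nacceptance rate by offer (rows: effort fraction, cols: reward points):")
grid = trials.pivot_table(index="effort", columns="reward", values="choice")
print(grid.round(2).to_string())
print("\nHigher rewards are accepted more, higher efforts less — the "
      "reward-effort trade-off the task is built to elicit.")
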