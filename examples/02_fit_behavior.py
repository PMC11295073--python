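"""Fit the subjective-value model to one participant's choices.

Simulates 150 choices from known parameters, then recovers the effort
weight k and softmax temperature beta by maximum likelihood (bounded
multi-start), and evaluates each offer's SV, p(Accept) and decision ease.
"""

from effortdm import GroundTruth, TaskConfig, build_offer_schedule, \
    evaluate_offers, fit_participant, simulate_choices

truth = GroundTruth(k=15.0, beta=1.0)
schedule = build_offer_schedule(TaskConfig(seed=1), participant="P01")
trials = simulate_choices(schedule, truth, seed=1)

fit = fit_participant(trials, participant_id="P01")
print(f"true   k = {truth.k:6.2f}   beta = {truth.beta:5.2f}")
print(f"fitted k = {fit.k:6.2f}   beta = {fit.beta:5.2f}   "
      f"(NLL = {fit.objective_value:.2f}, converged = {fit.converged})")

ev = evaluate_offers(trials, fit)
hard = ev.loc[ev.ease.idxmin()]
print(f"\nhardest offer: reward {hard.reward:g}, effort {hard.effort:.2f} -> "
      f"SV = {hard.sv:.2f}, p(Accept) = {hard.p_accept:.2f}, "
      f"ease = {hard.ease:.3f}")
print("Ease is |p(Accept) - 0.5|: offers near the indifference point are "
      "the hardest decisions.")
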