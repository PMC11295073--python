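"""Extract decision-window band power from simulated LFP epochs.

Generates two-channel epochs (-2 to 9 s at 422 Hz) whose PFC theta burst
scales with the previous offer's reward and whose BG low-beta burst scales
negatively with the current effort cost, then runs the spectral chain:
artifact rejection, 4-cycle Hanning-taper TFR, median/MAD baseline
correction, participant-specific beta-peak detection, and band averaging
over the 0.5-1.5 s decision window.
"""

import numpy as np

from effortdm import GroundTruth, TaskConfig, build_offer_schedule, \
    simulate_choices, simulate_lfp
from effortdm.spectral import (BandSpec, THETA_BAND, baseline_correct,
                               compute_tfr, detect_beta_peak,
                               extract_band_power, reject_artifact_trials)

truth = GroundTruth()
trials = simulate_choices(build_offer_schedule(TaskConfig(seed=2)), truth, seed=2)
epochs = simulate_lfp(trials, truth, seed=2)

clean, report = reject_artifact_trials(epochs)
print(f"artifact rejection: {report.n_rejected}/{report.n_input} trials "
      f"removed ({report.rule} rule)")

tfr_bg = baseline_correct(compute_tfr(clean, "BG"))
beta = detect_beta_peak(tfr_bg)
print(f"BG low-beta peak: {beta.peak_hz:g} Hz -> band "
      f"[{beta.lo:g}, {beta.hi:g}] Hz")

beta_pow = extract_band_power(tfr_bg, beta)
tfr_pfc = baseline_correct(compute_tfr(clean, "PFC"))
theta_pow = extract_band_power(tfr_pfc, BandSpec("theta", *THETA_BAND))
print(f"decision-window power (median across trials, MAD units above "
      f"baseline): BG beta {np.nanmedian(beta_pow.power):.2f}, "
      f"PFC theta {np.nanmedian(theta_pow.power):.2f}")

merged = trials.merge(beta_pow, on="trial_global")
r = np.corrcoef(merged["effort"] ** 2, merged["power"])[0, 1]
print(f"correlation of BG beta power with squared effort: {r:.2f} "
      "(negative: beta desynchronizes for costlier offers)")
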