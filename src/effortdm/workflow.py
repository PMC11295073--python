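"""High-level analysis helpers that chain the per-module operations.

These wrap the common study-level workflow — fit every participant's
behavioral model, then reduce epoch sets to decision-window band power —
without the file I/O of the full pipeline stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import evaluate_offers, fit_participant
from .spectral import (BandSpec, THETA_BAND, baseline_correct, compute_tfr,
                       detect_beta_peak, extract_band_power,
                       reject_artifact_trials)

__all__ = ["augment_with_behavior", "decision_band_power"]


def augment_with_behavior(trials: pd.DataFrame, **fit_kw) -> pd.DataFrame:
    """Fit each participant's (k, beta) and populate sv/p_accept/ease."""
    frames = []
    for pid, sub in trials.groupby("participant", sort=False):
        fit = fit_participant(sub, participant_id=pid, **fit_kw)
        frames.append(evaluate_offers(sub, fit, allow_unconverged=True))
    return pd.concat(frames, ignore_index=True)


def decision_band_power(epoch_sets: dict, artifact_rule="cross_trial"):
    """Decision-window PFC theta and BG peak-beta power per trial.

    Computes the TFR only at the frequencies the two bands need (theta
    4-7 Hz on PFC; 10-22 Hz on BG so a boundary beta peak keeps its full
    4 Hz band).  Returns (wide per-trial table with ``pow_PFC_theta`` and
    ``pow_BG_beta`` columns, list of rejected (participant, trial) pairs).
    """
    rows, artifact_ids = [], []
    for pid, epochs in epoch_sets.items():
        clean, report = reject_artifact_trials(epochs, rule=artifact_rule)
        artifact_ids += [(pid, t) for t in report.rejected]
        tfr_pfc = baseline_correct(
            compute_tfr(clean, "PFC", freqs=np.arange(4.0, 8.0)))
        theta = BandSpec("theta", *THETA_BAND)
        df = extract_band_power(tfr_pfc, theta)
        df = df.rename(columns={"power": "pow_PFC_theta"})
        tfr_bg = baseline_correct(
            compute_tfr(clean, "BG", freqs=np.arange(10.0, 23.0)))
        beta = detect_beta_peak(tfr_bg)
        df["pow_BG_beta"] = extract_band_power(tfr_bg, beta)["power"].to_numpy()
        rows.append(df[["participant", "trial_global",
                        "pow_PFC_theta", "pow_BG_beta"]])
    return pd.concat(rows, ignore_index=True), artifact_ids
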