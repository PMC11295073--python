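# Data dictionary

All tables are UTF-8 CSV, fixed column order, floats formatted `%.10g`,
missing values as empty fields.

## trials.csv / trials_augmented.csv (one row per offer)

| column | meaning |
|---|---|
| participant | participant id (string) |
| session | session number, 1-based |
| block | block within session, 1-based |
| trial_in_block | trial within block, 1-based |
| trial_global | 0-based trial index within participant (joins epochs and power) |
| reward | offered reward, points (1, 4, 7, 10, 13 by default) |
| effort | required force as fraction of maximum (0.16–0.80 by default) |
| stim_on | stimulation ON flag for the trial's block |
| choice | 1 accept, 0 reject, empty missing |
| rt | reaction time, seconds (empty if missing) |
| iti | inter-trial interval, seconds |
| first_in_block | True on the first trial of each block (previous-trial regressors undefined) |
| sv_true, p_accept_true, ease_true | generator ground truth (synthetic data only) |
| sv, p_accept, ease | fitted-model evaluations (augmented table only) |

## band_power.csv (one row per trial × channel × band)

| column | meaning |
|---|---|
| participant, trial_global | join keys |
| channel | PFC or BG |
| band | theta or beta |
| power | decision-window (0.5–1.5 s) mean baseline-corrected power, MAD units |
| n_missing_cells | TFR cells excluded from the mean |

## results.csv (one row per model × effect)

| column | meaning |
|---|---|
| dependent | choice, log_rt, or pow_<channel>_<band> |
| model | sv_model or reward_effort_model |
| effect | fixed-effect name (sv_t, sv_tm1, reward_t, effort_t, reward_tm1, effort_tm1, …) |
| estimate | fixed-effect estimate (predictors z-scored within participant) |
| se | standard error |
| lrt_stat, lrt_p | likelihood-ratio test vs the model without the effect |
| n_observations | rows analyzed after all filters |
| estimator | ML engine used (profiled-ML / gauss-hermite) |

## JSON sidecars

- `epochs_<pid>.json`: fs (Hz), t0 (s, first sample re offer onset),
  channels, regions, participant, meta (seed, ground truth).
- `ground_truth.json`: generator parameters per participant.
- `artifact_report.json`: rule, rejected trial ids, per-channel counts.
- `bands.json`: per participant/channel theta and detected beta bands (Hz).
- `filter_reports.json`: per model, trials dropped by each rule in order.
- `stim_results.json`: GLM terms, separation flag, per-condition (k, β).
- `manifest.json`: config hash, per-stage seeds, package version, artifact
  paths, stage durations.
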