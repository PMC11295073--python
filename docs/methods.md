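# Methods

This note documents the models implemented in `effortdm`, the assumptions
behind them, the synthetic-data generator used to validate the pipeline,
and the numerical choices that matter.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Behavioral model

**Subjective value.** An offer of reward *R* (points; levels 1, 4, 7, 10,
13) at effort *E* (fraction of maximal voluntary contraction; levels
0.16–0.80) is valued as SV = R − k·E², with k ≥ 0 the participant's effort
weight.  Effort is stored as a fraction rather than percent so that k·E²
spans 0–k on the points scale and k stays of order 1–100 rather than 10⁻³;
`effort_percent_to_fraction`/`effort_fraction_to_percent` convert.
Throughout the statistics, "effort" means this individualized quadratic
cost k·E² (recovered from an augmented table as R − SV), not the raw force
level; a raw-E regressor can be built from the trial table if wanted.

**Decision policy.** The default softmax is implemented verbatim in the
form p(Accept) = e^{β·SV} / (e^β + e^{β·SV}).  Algebraically this is a
logistic in β·(SV − 1), i.e. its indifference point sits at SV = 1 rather
than 0.  Whether that denominator is a typographical variant of the
canonical logistic cannot be decided from the source description, so both
forms are exposed (`form="as_printed" | "canonical"`), the as-printed form
is the default, and every `BehavioralFit` records the form used.  Both are
evaluated through `scipy.special.expit`, so they are overflow-safe.

**Fitting.** The default objective is the Bernoulli negative log-likelihood
("minimizing the difference between p(Accept) and choices" is ambiguous;
NLL is the proper scoring rule), with summed squared error retained as a
config option for fidelity checks.  Probabilities are clipped to
[10⁻⁹, 1 − 10⁻⁹] inside the likelihood.  Optimization is L-BFGS-B over the
box k ∈ [0, 100], β ∈ [10⁻³, 50] from a 5×5 log-spaced start grid (k from
0.5 to 80, β from 0.01 to 20), which covers every behaviorally
distinguishable regime for rewards ≤ 13; the best start's optimum is
returned.  Fitting is deterministic and order-invariant.  Degenerate data
(all-accept/all-reject, or separable choices that push β to its bound)
yield a flagged, unconverged fit rather than a silent success;
`evaluate_offers` refuses such fits unless explicitly overridden.

## Synthetic-data generator

The generator exists so that every downstream stage can be tested by
recovery against known truth.  Defaults reproduce the study design it
emulates: 5×5 reward/effort grid, 3 blocks × 25 trials × 2 sessions
(150 choice trials per participant), ITI ~ U(1.6, 1.8) s, response mappings
revealed 1.5 s post-offer, 6 s response deadline, and a stimulation
protocol of 4 ON + 4 OFF blocks of 25 trials (100/100 trials).  The source
design ran its 8 stimulation blocks over three sessions, necessarily
unevenly; the generator uses 2 sessions × 4 blocks so that per-session
counterbalancing is exact while preserving the trial totals.

**Offers.** How the original task balanced offers over the grid is not
documented; offers here are drawn by repeated shuffled passes over the
25-cell grid (exact balance for multiples of 25) with leftovers drawn
without replacement from a final shuffled pass.  Schedules are a pure
function of (config, seed).

**Choices and RTs.** Choices are Bernoulli draws from the as-printed
softmax on SV (defaults k = 15, β = 1, which give graded acceptance across
the grid and ~60% overall acceptance).  An optional `sv_offset` shifts net
SV additively — the mechanism used to emulate a stimulation-induced
indifference-point shift.  Log RTs are linear in the z-scored decision ease
of the current and previous offer, log rt = 1.05 − 0.040·z(ease_t) +
0.027·z(ease_{t−1}) + N(0, 0.25); the base gives a ~2.86 s mean RT and the
two slopes are the reported behavioral effect sizes for this task family.
RTs are clipped to the deadline (logged).

**LFP epochs.** Per trial and channel, epochs spanning −2 to 9 s at 422 Hz
(500 Hz configurable) contain 1/f-shaped Gaussian background noise
(spectral shaping of white noise by f^(−exponent/2), default exponent 1.0,
unit SD) plus amplitude-modulated sinusoidal bursts confined to the 0.5–1.5
s decision window with 0.25 s raised-cosine ramps — the simplest generator
whose band power is analytically predictable while avoiding spectral
splatter.  The PFC channel carries a theta burst (5.5 Hz) with amplitude
osc_amp·(1 + 0.3·z(R_{t−1})); the BG channel a low-beta burst (16 Hz) with
amplitude osc_amp·(1 − 0.3·z(k·E²)).  Amplitudes are floored at zero, with
a warning when more than 10% of trials hit the floor.  Whether neural
effort sensitivity should follow raw E, E², or k·E² is undetermined; the
default uses the model's k·E² cost, matching how "effort" is defined in the
behavioral model.  Previous-trial regressors are undefined at block starts;
the first trial of each block reuses its own offer and is flagged, and the
statistics drop flagged trials.  The default burst amplitude (osc_amp =
0.5) puts decision-window band power at roughly 4–5 MAD units above
baseline — a realistic magnitude for task-evoked intracranial power — and a
30% amplitude modulation per SD of the driving regressor is a moderate
physiological effect size.  What the generator does **not** emulate: real
1/f knees and spectral peaks outside the injected bands, burst-like
(non-sinusoidal) oscillation dynamics, autocorrelated behavioral and neural
drift, stimulation artifacts, and movement/EMG contamination.  Passing
recovery tests therefore demonstrates correctness of the pipeline, not that
effects of this size are detectable in arbitrary real recordings.

## Spectral chain

**Artifact rejection.** The literal reading of the amplitude rule — reject
a trial whose maximum absolute value exceeds two SDs of that trial's own
samples — rejects essentially every realistic trial (the max of ~4,600
samples always exceeds 2 within-trial SDs), which is incompatible with the
low rejection counts such studies report.  The default rule therefore
compares each trial's max-|amplitude| statistic *across trials* (reject if
above mean + 2 SD of that distribution, per channel); the literal
within-trial rule remains selectable (`rule="within_trial"`), and neither
is asserted to be the original.  A zero-spread distribution rejects
nothing.

**TFR.** Convolution with Hanning-tapered complex sinusoids, taper length 4
cycles of the center frequency (2 s at 2 Hz), power = |coefficient|²;
default grid 2–40 Hz × (−1 to 2 s in 4 ms steps), evaluated at the nearest
epoch sample, taper centered on the output point.  Epochs are generated
long (−2 to 9 s) precisely so the 2 Hz taper fits the whole analysis span;
cells whose taper would leave the epoch are NaN and counted, never
zero-padded.  A 4-cycle window places the analysis frequency exactly at DFT
bin 4 of the tapered segment, which is what makes the independent
windowed-DFT oracle in the tests exact rather than approximate.

**Baseline.** Per trial × frequency: (power − median)/MAD over the
[−0.8, 0) s window, MAD unscaled (no 1.4826 consistency factor).  Median
and MAD are computed per trial, not pooled.  Zero-MAD series are excluded
and counted.  This robust normalization tolerates heavy-tailed power and
occasional residual artifacts better than mean/SD z-scoring.

**Bands.** Theta is fixed at 4–7 Hz (inclusive on the 1 Hz grid).  Low beta
is participant/channel-specific: the argmax of trial-averaged corrected
power over 12–20 Hz within the 0.5–1.5 s decision window (whether the
original peak detection used only the decision window is unstated; it is
used here), ±2 Hz.  Ties resolve to the lowest frequency (logged); a
boundary peak keeps its full 4 Hz band even if it extends past 12 or 20 Hz,
since clipping would bias bandwidth.  Band power is the mean over band
frequencies × window times, with missing cells excluded and counted.
Sliding windows are 0.2 s stepped by 0.025 s from 0 s (73 windows over
0–2 s), for visualization only.

## Statistics

**Regressors.** Previous-trial variables are lagged within block; all
fixed-effect predictors are z-scored within participant *before* any
exclusion (the alternative ordering is not determinable from the source
description); RTs are log-transformed.  A constant within-participant
predictor raises an error naming participant and predictor.  Filters apply
in a fixed order — invalid/missing response, RT over deadline, neural
artifact, 3 SD group-level outlier on the dependent, first trial of each
block — and the `FilterReport` accounting is exact (input = analyzed +
dropped).  The outlier rule runs per dependent, so models may analyze
slightly different row sets, except inside `compare_value_models`, where
the two candidate models share identical rows.

**Mixed models.** Random intercepts by participant, fit by maximum
likelihood (not REML) so that likelihood-ratio tests on fixed effects are
valid.  The gaussian engine profiles the variance ratio analytically
(per-group rank-one downdates of the OLS cross-products), making each fit
sub-millisecond — which is what keeps the permutation machinery (hundreds
of refits per test) and its calibration battery tractable; it matches
statsmodels `MixedLM(reml=False)` to optimizer tolerance.  The binomial
engine maximizes an adaptive Gauss–Hermite marginal likelihood (25 nodes,
recentered on each group's conditional mode), agreeing with `lme4::glmer`
(adaptive quadrature) to ~3 decimal places; the estimator is recorded in
every result's metadata.  LRT statistics are floored at zero.

**Permutation tests.** The predictor of interest is shuffled within each
participant (other columns fixed); the permutation p is the proportion of
null LRT p-values ≤ the observed one, so the minimum attainable p is 0.
An add-one smoothed option ((1+count)/(n+1), minimum 1/(n+1)) is available.
Permutation seeds are required inputs, never wall-clock derived.  The
reduced model does not involve the permuted column, so it is fit once per
test, not per permutation.

**Follow-ups.** Interaction probes add one product of z-scored components
at a time to the reward/effort choice model and LRT it.  Previous-reward
splits refit the choice model on trials following low (1, 4) vs high
(10, 13) raw previous reward, excluding the middle level rather than
bisecting it.  The stimulation analysis is a single-participant binomial
GLM (statsmodels IRLS) with reward, effort, stimulation and the two
stimulation interactions; complete separation is flagged and a
ridge-penalized fallback reported without LRTs; per-condition (k, β) fits
accompany the GLM.  No multiple-comparison correction is applied anywhere,
and results metadata says so.

## Problem sizes used in validation

Parameter recovery uses 20 seeded replicates at 150 and 1,000 trials;
permutation calibration uses 500 null datasets of 4 participants × 40
trials with 200 permutations each; end-to-end sign recovery uses 20 seeded
studies of 4 participants × 150 trials with the generator defaults.  These
sizes were chosen as the smallest at which the corresponding statistical
statements are meaningful (binomial CIs around nominal error rates, median
recovery error at the study's own scale).

## Known limitations

- Only random intercepts (no random slopes) and a single grouping factor.
- The binomial engine's Wald SEs come from the BFGS inverse-Hessian
  approximation; inference should rely on the LRT/permutation p-values.
- The generator's oscillations are stationary sinusoidal bursts; analyses
  of burst dynamics or cross-frequency structure are out of scope.
- The external-study adapter validates schema and units but cannot verify
  scientific comparability (electrode placement, referencing, gain).
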