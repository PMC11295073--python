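"""Mixed-model and permutation inference for choices, RTs and band power.

The analysis contrasts two candidate models of each trial-level dependent
variable (choice, log RT, or decision-window band power):

    DV ~ SV_t + SV_{t-1} + (1 | participant)
    DV ~ Reward_t + Effort_t + Reward_{t-1} + Effort_{t-1} + (1 | participant)

where Effort is the individualized quadratic cost k*E^2 from the behavioral
model and all predictors are z-scored within participant.  Fixed effects are
assessed with likelihood-ratio tests of nested maximum-likelihood fits and,
where the dependent is non-normal, with within-subject permutation tests:
the predictor of interest is shuffled within each participant and the
permutation p is the proportion of null LRT p-values at or below the
observed one.

Filtering follows the preprocessing rules of the task: trials with invalid
or missing responses, RTs beyond the 6 s deadline, or neural artifacts are
removed first; then, per model, trials whose dependent value exceeds 3 SD
from the group-level mean, and the first trial of each block (previous-trial
regressors are undefined after a rest break).  No multiple-comparison
correction is applied anywhere; reports say so.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .behavior import fit_participant
from .lmm import MixedFit, fit_glmm_binomial, fit_lmm_gaussian, lrt_pvalue

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "MixedModelResult",
    "FilterReport",
    "PreparedData",
    "prepare_regressors",
    "fit_mixed",
    "permutation_test",
    "compare_value_models",
    "interaction_probe",
    "split_by_previous_reward",
    "sliding_window_models",
    "fit_stimulation_glm",
    "SV_MODEL_EFFECTS",
    "REWARD_EFFORT_EFFECTS",
]

SV_MODEL_EFFECTS = ["sv_t", "sv_tm1"]
REWARD_EFFORT_EFFECTS = ["reward_t", "effort_t", "reward_tm1", "effort_tm1"]

FILTER_ORDER = [
    "invalid_or_missing_response",
    "rt_over_deadline",
    "artifact",
    "outlier_3sd",
    "first_trial_of_block",
]


@dataclass(frozen=True)
class ModelSpec:
    dependent: str
    family: str  # "gaussian" | "binomial"
    fixed_effects: tuple
    grouping: str = "participant"
    name: str = ""

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.fixed_effects:
            raise ValueError("need at least one fixed effect")


@dataclass
class FilterReport:
    counts: dict
    n_input: int
    n_analyzed: int

    def __post_init__(self):
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative filter count")
        total = self.n_analyzed + sum(self.counts.values())
        if total != self.n_input:
            raise ValueError(
                f"filter accounting broken: {self.n_analyzed} analyzed + "
                f"{sum(self.counts.values())} dropped != {self.n_input} input")

    def to_dict(self):
        return {"counts": {k: int(v) for k, v in self.counts.items()},
                "n_input": int(self.n_input), "n_analyzed": int(self.n_analyzed)}


@dataclass
class MixedModelResult:
    spec: ModelSpec
    effects: pd.DataFrame  # effect, estimate, se, lrt_stat, lrt_p [, perm_p]
    n_observations: int
    filter_report: FilterReport | None
    fit: MixedFit
    converged: bool
    metadata: dict = field(default_factory=dict)

    def estimate(self, effect):
        row = self.effects.set_index("effect").loc[effect]
        return float(row["estimate"])

    def lrt_p(self, effect):
        row = self.effects.set_index("effect").loc[effect]
        return float(row["lrt_p"])


@dataclass
class PreparedData:
    """Clean analysis table plus the accounting that produced it.

    ``table`` holds one row per clean trial (invalid/missing, late-RT and
    artifact trials already removed) with within-participant z-scored
    predictors, raw helper columns, and every available dependent.  The
    per-model filters (3 SD outliers on the dependent, first trial of each
    block) are applied inside :func:`fit_mixed` so each model's
    FilterReport is complete.
    """

    table: pd.DataFrame
    base_counts: dict
    n_input: int


def _zscore_within(df, col, by="participant"):
    out = np.full(len(df), np.nan)
    for pid, idx in df.groupby(by, sort=False).groups.items():
        vals = df.loc[idx, col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() == 0:
            continue
        sd = vals[ok].std(ddof=0)
        if sd == 0:
            raise ValueError(
                f"predictor {col!r} is constant within participant {pid!r}; "
                "cannot z-score")
        z = np.full_like(vals, np.nan)
        z[ok] = (vals[ok] - vals[ok].mean()) / sd
        out[np.asarray(df.index.get_indexer(idx))] = z
    return out


def _lag_within_block(df, col):
    return df.groupby(["participant", "session", "block"], sort=False)[col].shift(1)


def prepare_regressors(trials: pd.DataFrame, artifact_ids=None,
                       deadline=6.0) -> PreparedData:
    """Build the analysis table from an augmented trial table.

    ``trials`` must carry sv/p_accept/ease columns (from the behavioral
    fits) and may carry band-power columns named ``pow_*``.  The effort
    regressor is the individualized cost k*E^2, recovered as reward - sv.
    Previous-trial regressors are lagged within block (NaN on block-first
    trials, which later drop); all predictors are z-scored within
    participant before any exclusion.  ``artifact_ids`` is an iterable of
    (participant, trial_global) pairs to drop as neural artifacts.
    """
    df = trials.reset_index(drop=True).copy()
    for col in ("sv", "p_accept", "ease"):
        if col not in df:
            raise ValueError(f"augmented trial table lacks {col!r}; run "
                             "behavior.evaluate_offers first")
    df["effort_cost"] = df["reward"].astype(float) - df["sv"].astype(float)
    # raw previous-trial values (within block)
    df["reward_level_tm1"] = _lag_within_block(df, "reward")
    for raw, base in (("reward", "reward"), ("effort_cost", "effort"),
                      ("sv", "sv"), ("ease", "ease")):
        df[f"_{base}_t_raw"] = df[raw].astype(float)
        df[f"_{base}_tm1_raw"] = _lag_within_block(df, raw)
    for base in ("reward", "effort", "sv", "ease"):
        df[f"{base}_t"] = _zscore_within(df, f"_{base}_t_raw")
        df[f"{base}_tm1"] = _zscore_within(df, f"_{base}_tm1_raw")
    df = df.drop(columns=[c for c in df.columns if c.startswith("_")])
    if "rt" in df:
        with np.errstate(divide="ignore", invalid="ignore"):
            df["log_rt"] = np.log(df["rt"].astype(float))
    if "stim_on" in df:
        df["stim"] = df["stim_on"].astype(float)

    n_input = len(df)
    counts = dict.fromkeys(FILTER_ORDER[:3], 0)
    bad_resp = df["choice"].isna()
    counts["invalid_or_missing_response"] = int(bad_resp.sum())
    df = df[~bad_resp]
    late = df["rt"].astype(float) > deadline if "rt" in df else pd.Series(False, index=df.index)
    counts["rt_over_deadline"] = int(late.sum())
    df = df[~late]
    if artifact_ids:
        pairs = {(str(p), int(t)) for p, t in artifact_ids}
        is_art = df.apply(
            lambda r: (str(r["participant"]), int(r["trial_global"])) in pairs,
            axis=1)
        counts["artifact"] = int(is_art.sum())
        df = df[~is_art]
    return PreparedData(table=df.reset_index(drop=True),
                        base_counts=counts, n_input=n_input)


def _model_frame(spec: ModelSpec, data, extra_cols=()):
    """Apply per-model filters and return (frame, FilterReport|None)."""
    if isinstance(data, PreparedData):
        df = data.table
        counts = dict(data.base_counts)
        n_input = data.n_input
        track = True
    else:
        df = data
        counts, n_input, track = {}, len(data), False

    dep = spec.dependent
    need = [dep, spec.grouping, *spec.fixed_effects, *extra_cols]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"model {spec.name or dep}: missing columns {missing}")

    keep = df[dep].notna()
    vals = df.loc[keep, dep].astype(float)
    mu, sd = vals.mean(), vals.std(ddof=0)
    out_mask = keep & (np.abs(df[dep].astype(float) - mu) > 3 * sd) if sd > 0 \
        else pd.Series(False, index=df.index)
    counts["outlier_3sd"] = int(out_mask.sum())
    df2 = df[keep & ~out_mask]
    if "first_in_block" in df2:
        fb = df2["first_in_block"].astype(bool)
        counts["first_trial_of_block"] = int(fb.sum())
        df2 = df2[~fb]
    frame = df2.dropna(subset=[c for c in need if c in df2.columns])
    n_lagged_na = len(df2) - len(frame)
    if n_lagged_na:
        counts["missing_regressor"] = counts.get("missing_regressor", 0) + n_lagged_na
    n_dep_na = int((~keep).sum())
    if n_dep_na:
        counts["missing_dependent"] = counts.get("missing_dependent", 0) + n_dep_na
    report = FilterReport(counts=counts, n_input=n_input,
                          n_analyzed=len(frame)) if track else None
    return frame.reset_index(drop=True), report


def _fit_family(spec, y, X, groups, names):
    if spec.family == "gaussian":
        return fit_lmm_gaussian(y, X, groups, names=names)
    return fit_glmm_binomial(y, X, groups, names=names)


def fit_mixed(spec: ModelSpec, data, drop_effects_lrt=True) -> MixedModelResult:
    """Random-intercept mixed model with per-effect likelihood-ratio tests.

    Fits by maximum likelihood and, for each fixed effect, refits the
    reduced model without it; the LRT p is chi-square(1).  Estimates are on
    the scale of the (within-participant standardized) predictors.
    """
    frame, report = _model_frame(spec, data)
    if frame[spec.grouping].nunique() < 2:
        raise ValueError("mixed model needs >= 2 grouping levels")
    y = frame[spec.dependent].to_numpy(dtype=float)
    names = ["intercept", *spec.fixed_effects]
    X = np.column_stack([np.ones(len(frame))]
                        + [frame[c].to_numpy(dtype=float) for c in spec.fixed_effects])
    groups = frame[spec.grouping].to_numpy()
    full = _fit_family(spec, y, X, groups, names)

    rows = []
    for j, eff in enumerate(spec.fixed_effects, start=1):
        rec = {"effect": eff,
               "estimate": float(full.beta[j]),
               "se": float(full.se[j]) if full.se is not None else np.nan}
        if drop_effects_lrt:
            Xr = np.delete(X, j, axis=1)
            red = _fit_family(spec, y, Xr, groups,
                              [n for i, n in enumerate(names) if i != j])
            stat, p = lrt_pvalue(full.loglik, red.loglik)
            rec["lrt_stat"], rec["lrt_p"] = stat, p
        rows.append(rec)
    return MixedModelResult(
        spec=spec, effects=pd.DataFrame(rows),
        n_observations=len(frame), filter_report=report,
        fit=full, converged=full.converged,
        metadata={"estimator": full.method,
                  "multiple_comparison_correction": "none"},
    )


def permutation_test(spec: ModelSpec, data, effect, n_perms=1000, seed=0,
                     rule="proportion"):
    """Within-subject permutation test of one fixed effect.

    The effect's column is shuffled within each participant ``n_perms``
    times (all other columns fixed) and the full model refit; the returned
    p is the proportion of null LRT p-values <= the observed LRT p
    (``rule="proportion"``, minimum attainable 0) or the add-one smoothed
    (1 + count) / (n_perms + 1) (``rule="add_one"``, minimum 1/(n+1)).
    """
    if effect not in spec.fixed_effects:
        raise ValueError(f"effect {effect!r} not in model {spec.fixed_effects}")
    if n_perms < 100:
        warnings.warn(f"n_perms={n_perms} is small; permutation p is coarse")
    if rule not in ("proportion", "add_one"):
        raise ValueError(f"unknown permutation rule {rule!r}")
    frame, _ = _model_frame(spec, data)
    y = frame[spec.dependent].to_numpy(dtype=float)
    names = ["intercept", *spec.fixed_effects]
    X = np.column_stack([np.ones(len(frame))]
                        + [frame[c].to_numpy(dtype=float) for c in spec.fixed_effects])
    groups = frame[spec.grouping].to_numpy()
    j = 1 + list(spec.fixed_effects).index(effect)

    full = _fit_family(spec, y, X, groups, names)
    Xr = np.delete(X, j, axis=1)
    red = _fit_family(spec, y, Xr, groups, None)
    _, obs_p = lrt_pvalue(full.loglik, red.loglik)

    rng = np.random.default_rng(seed)
    codes = pd.factorize(pd.Series(groups))[0]
    group_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    col = X[:, j].copy()
    null_ps = np.empty(n_perms)
    Xp = X.copy()
    for b in range(n_perms):
        perm_col = col.copy()
        for idx in group_idx:
            perm_col[idx] = col[idx][rng.permutation(len(idx))]
        Xp[:, j] = perm_col
        fullp = _fit_family(spec, y, Xp, groups, names)
        # reduced model is unchanged by permuting the dropped column
        _, null_ps[b] = lrt_pvalue(fullp.loglik, red.loglik)
    count = int((null_ps <= obs_p).sum())
    if rule == "proportion":
        perm_p = count / n_perms
    else:
        perm_p = (1 + count) / (n_perms + 1)
    return {"effect": effect, "perm_p": float(perm_p), "obs_lrt_p": float(obs_p),
            "n_perms": int(n_perms), "seed": int(seed), "rule": rule,
            "null_lrt_p": null_ps}


def compare_value_models(data, dependent, family=None) -> dict:
    """Fit the SV model and the reward/effort model on identical rows.

    Both candidate models are fit to the same filtered row set (union of
    regressor requirements), so their likelihood surfaces describe the same
    data; the comparison is significance-pattern based.
    """
    if family is None:
        family = "binomial" if dependent == "choice" else "gaussian"
    all_effects = tuple(dict.fromkeys(SV_MODEL_EFFECTS + REWARD_EFFORT_EFFECTS))
    probe = ModelSpec(dependent=dependent, family=family,
                      fixed_effects=all_effects, name="shared-rows probe")
    frame, report = _model_frame(probe, data)
    sv_spec = ModelSpec(dependent=dependent, family=family,
                        fixed_effects=tuple(SV_MODEL_EFFECTS), name="sv_model")
    re_spec = ModelSpec(dependent=dependent, family=family,
                        fixed_effects=tuple(REWARD_EFFORT_EFFECTS),
                        name="reward_effort_model")
    res_sv = fit_mixed(sv_spec, frame)
    res_re = fit_mixed(re_spec, frame)
    if res_sv.n_observations != res_re.n_observations:
        raise RuntimeError("row sets diverged between candidate models")
    res_sv.filter_report = report
    res_re.filter_report = report
    return {"sv_model": res_sv, "reward_effort_model": res_re,
            "n_observations": res_sv.n_observations}


def interaction_probe(data, dependent="choice", family="binomial",
                      interactions=(("reward_tm1", "reward_t"),
                                    ("reward_tm1", "effort_t"),
                                    ("reward_tm1", "effort_tm1"))) -> pd.DataFrame:
    """LRT of previous-reward interaction terms added one at a time.

    Each interaction (product of the z-scored components) is appended to
    the reward/effort model and tested against it.
    """
    rows = []
    for a, b in interactions:
        name = f"{a}:{b}"
        spec = ModelSpec(dependent=dependent, family=family,
                         fixed_effects=tuple(REWARD_EFFORT_EFFECTS),
                         name=f"base+{name}")
        frame, _ = _model_frame(spec, data, extra_cols=())
        frame = frame.copy()
        frame[name] = frame[a] * frame[b]
        full_spec = ModelSpec(dependent=dependent, family=family,
                              fixed_effects=tuple(REWARD_EFFORT_EFFECTS) + (name,),
                              name=f"base+{name}")
        res = fit_mixed(full_spec, frame)
        rec = res.effects.set_index("effect").loc[name]
        rows.append({"interaction": name, "estimate": float(rec["estimate"]),
                     "lrt_stat": float(rec["lrt_stat"]),
                     "lrt_p": float(rec["lrt_p"]),
                     "n_observations": res.n_observations})
    return pd.DataFrame(rows)


def split_by_previous_reward(data, low=(1, 4), high=(10, 13),
                             dependent="choice", family="binomial") -> dict:
    """Refit the reward/effort choice model after low vs high previous reward.

    Splits use the raw previous reward level (middle level excluded, so no
    trial is artificially divided by a median split).
    """
    spec = ModelSpec(dependent=dependent, family=family,
                     fixed_effects=tuple(REWARD_EFFORT_EFFECTS))
    frame, _ = _model_frame(spec, data, extra_cols=("reward_level_tm1",))
    out = {}
    for label, levels in (("low", low), ("high", high)):
        sub = frame[frame["reward_level_tm1"].isin(levels)]
        if len(sub) < 30:
            warnings.warn(f"previous-reward {label} split has only {len(sub)} "
                          "trials; estimates will be unstable")
        out[label] = fit_mixed(spec, sub.reset_index(drop=True))
    return out


def sliding_window_models(spec: ModelSpec, sliding_table: pd.DataFrame,
                          data) -> pd.DataFrame:
    """Per-window mixed models over a sliding band-power table.

    For each window, the window's per-trial power becomes the dependent and
    the model in ``spec`` is refit.  Output is one row per window x effect,
    labelled visualization-only: no multiplicity correction is applied.
    """
    base = data.table if isinstance(data, PreparedData) else data
    rows = []
    for w, wdf in sliding_table.groupby("window", sort=True):
        merged = base.merge(
            wdf[["participant", "trial_global", "power"]],
            on=["participant", "trial_global"], how="inner")
        merged[spec.dependent] = merged.pop("power")
        res = fit_mixed(spec, merged)
        for _, r in res.effects.iterrows():
            rows.append({"window": int(w),
                         "t_start": float(wdf["t_start"].iloc[0]),
                         "effect": r["effect"], "estimate": r["estimate"],
                         "lrt_p": r["lrt_p"],
                         "n_observations": res.n_observations})
    out = pd.DataFrame(rows)
    out.attrs["note"] = "visualization only; no multiplicity correction"
    return out


def fit_stimulation_glm(stim_table: pd.DataFrame, fit_behavior=True) -> dict:
    """Single-participant binomial GLM of choice under PFC stimulation.

    choice ~ z(reward) + z(effort cost) + stim + reward:stim + effort:stim,
    no random effects; each term is assessed with an LRT against the
    reduced GLM without it.  Complete separation is flagged and a ridge-
    penalized fallback reported (without LRTs).  Per-condition behavioral
    fits (k, beta ON vs OFF) are also returned.
    """
    df = stim_table.dropna(subset=["choice"]).copy()
    if "sv" in df:
        effort_cost = df["reward"].astype(float) - df["sv"].astype(float)
    elif "sv_true" in df:
        effort_cost = df["reward"].astype(float) - df["sv_true"].astype(float)
    else:
        effort_cost = df["effort"].astype(float) ** 2
    z = lambda v: (v - v.mean()) / v.std(ddof=0)
    zr = z(df["reward"].astype(float)).to_numpy()
    ze = z(pd.Series(effort_cost)).to_numpy()
    stim = df["stim_on"].astype(float).to_numpy()
    y = df["choice"].astype(float).to_numpy()
    names = ["intercept", "reward", "effort", "stim", "reward:stim", "effort:stim"]
    X = np.column_stack([np.ones(len(df)), zr, ze, stim, zr * stim, ze * stim])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    separated = bool(np.abs(res.params).max() > 15) or not np.all(
        np.isfinite(res.bse))
    out = {"terms": None, "separation": separated,
           "estimator": "statsmodels GLM binomial (IRLS)",
           "n_observations": int(len(df))}
    if separated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pen = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
        out["fallback"] = {
            "note": "complete separation; ridge-penalized estimates, no LRTs",
            "params": dict(zip(names, map(float, pen.params)))}
    rows = []
    for j, name in enumerate(names):
        if j == 0:
            continue
        rec = {"term": name, "estimate": float(res.params[j]),
               "se": float(res.bse[j])}
        if not separated:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                red = sm.GLM(y, np.delete(X, j, axis=1),
                             family=sm.families.Binomial()).fit(maxiter=200)
            stat, p = lrt_pvalue(res.llf, red.llf)
            rec["lrt_stat"], rec["lrt_p"] = stat, p
        rows.append(rec)
    out["terms"] = pd.DataFrame(rows)

    if fit_behavior:
        fits = {}
        for label, mask in (("on", stim == 1), ("off", stim == 0)):
            sub = df[mask]
            try:
                fits[label] = fit_participant(
                    sub, participant_id=f"{sub['participant'].iloc[0]}_{label}")
            except Exception as exc:  # noqa: BLE001 - reported, not raised
                fits[label] = None
                log.warning("behavioral fit (%s) failed: %s", label, exc)
        out["behavior_fits"] = fits
    return out
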