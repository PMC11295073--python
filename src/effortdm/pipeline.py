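"""Pipeline orchestration: simulate -> fit-behavior -> spectra -> stats -> stim.

Each stage reads only the serialized artifacts of upstream stages, writes
its outputs with provenance metadata, and records itself in a RunManifest.
Re-running with identical config and master seed reproduces byte-identical
CSV outputs.  Per-stage random seeds are derived from the master seed by a
documented counter scheme: ``default_rng([master_seed, stage_index])``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import evaluate_offers, fit_participant
from .config import ConfigError, GroundTruth, TaskConfig, load_config
from .io import (read_epochs, read_fits, read_trials, write_epochs, write_fits,
                 write_json, write_trials, FLOAT_FMT)
from .simulate import (simulate_participant, simulate_stim_sessions,
                       stim_task_config)
from .spectral import (THETA_BAND, BandSpec, baseline_correct, compute_tfr,
                       detect_beta_peak, extract_band_power,
                       reject_artifact_trials)
from .stats import (compare_value_models, fit_stimulation_glm,
                    prepare_regressors)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_external_study", "RunManifest", "STAGES",
            "StageError"]

STAGES = ["simulate", "fit_behavior", "spectra", "stats", "stim"]


class StageError(RuntimeError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    outdir: str
    stage_seeds: dict = field(default_factory=dict)
    completed: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def save(self, path):
        write_json(dataclasses.asdict(self), path)


def _stage_seed(master, stage):
    idx = STAGES.index(stage)
    # documented: independent stream per stage from (master, index)
    return int(np.random.default_rng([int(master) & 0x7FFFFFFF, idx])
               .integers(0, 2**31 - 1))


def _hash_config(cfg: dict) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)
    return hashlib.sha256(
        json.dumps(cfg, default=enc, sort_keys=True).encode()).hexdigest()[:16]


def _require(path: Path, produced_by: str):
    if not path.exists():
        raise StageError(f"missing upstream artifact {path.name}; "
                        f"run the '{produced_by}' stage first")
    return path


def run_pipeline(config, outdir, stages=None, master_seed=0) -> RunManifest:
    """Execute the requested stages in order.

    ``config`` is a path to a YAML/JSON config or the dict returned by
    :func:`effortdm.config.load_config`.  Stage dependencies are enforced
    through the presence of upstream artifacts; failures abort with a
    stage-local error.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    task: TaskConfig = config["task"]
    truth = config["truth"]
    participants = config["participants"]
    analysis = config.get("analysis", {})
    truths = truth if isinstance(truth, list) else [truth] * len(participants)
    if len(truths) != len(participants):
        raise ConfigError("need one ground truth per participant")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")

    manifest = RunManifest(
        config_hash=_hash_config(config), master_seed=int(master_seed),
        version=__version__, outdir=str(outdir),
    )

    for stage in STAGES:
        if stage not in stages:
            continue
        seed = _stage_seed(master_seed, stage)
        manifest.stage_seeds[stage] = seed
        t0 = time.time()
        try:
            arts = _STAGE_FUNCS[stage](task, truths, participants, analysis,
                                       outdir, seed)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.completed[stage] = True
        manifest.artifacts[stage] = [str(a) for a in arts]
        manifest.timestamps[stage] = round(time.time() - t0, 3)
        manifest.save(outdir / "manifest.json")
    return manifest


def _stage_simulate(task, truths, participants, analysis, outdir, seed):
    arts = []
    frames = []
    with_lfp = bool(analysis.get("with_lfp", True))
    for i, (pid, truth) in enumerate(zip(participants, truths)):
        cfg = task.replace(seed=task.seed + i)
        trials, epochs = simulate_participant(
            cfg, truth, participant=pid, seed=seed + i, with_lfp=with_lfp)
        frames.append(trials)
        if epochs is not None:
            arts.append(write_epochs(epochs, outdir / f"epochs_{pid}.h5"))
    all_trials = pd.concat(frames, ignore_index=True)
    arts.append(write_trials(all_trials, outdir / "trials.csv"))
    arts.append(write_json({pid: t.to_dict() for pid, t
                            in zip(participants, truths)},
                           outdir / "ground_truth.json"))
    return arts


def _stage_fit_behavior(task, truths, participants, analysis, outdir, seed):
    trials = read_trials(_require(outdir / "trials.csv", "simulate"))
    fits, frames = {}, []
    for pid, sub in trials.groupby("participant", sort=False):
        fit = fit_participant(sub, participant_id=pid,
                              form=analysis.get("softmax_form", "as_printed"),
                              objective=analysis.get("objective", "nll"))
        fits[pid] = fit
        frames.append(evaluate_offers(sub, fit, allow_unconverged=True))
    augmented = pd.concat(frames, ignore_index=True)
    return [write_fits(fits, outdir / "fits.json"),
            write_trials(augmented, outdir / "trials_augmented.csv")]


def _stage_spectra(task, truths, participants, analysis, outdir, seed):
    _require(outdir / "trials.csv", "simulate")
    rule = analysis.get("artifact_rule", "cross_trial")
    rows, reports, bands = [], {}, {}
    for pid in participants:
        epochs = read_epochs(_require(outdir / f"epochs_{pid}.h5", "simulate"))
        clean, report = reject_artifact_trials(epochs, rule=rule)
        reports[pid] = report.to_dict()
        for channel in clean.channels:
            tfr = baseline_correct(compute_tfr(clean, channel))
            theta = BandSpec(name=f"theta_{channel}", lo=THETA_BAND[0],
                             hi=THETA_BAND[1])
            beta = detect_beta_peak(tfr)
            bands.setdefault(pid, {})[channel] = {
                "theta": [theta.lo, theta.hi],
                "beta": [beta.lo, beta.hi],
                "beta_peak_hz": beta.peak_hz,
            }
            for label, band in (("theta", theta), ("beta", beta)):
                df = extract_band_power(tfr, band)
                df["band"] = label
                rows.append(df)
    power = pd.concat(rows, ignore_index=True)
    return [
        write_trials(power, outdir / "band_power.csv"),
        write_json(reports, outdir / "artifact_report.json"),
        write_json(bands, outdir / "bands.json"),
    ]


def _power_wide(power: pd.DataFrame) -> pd.DataFrame:
    wide = power.pivot_table(index=["participant", "trial_global"],
                             columns=["channel", "band"], values="power")
    wide.columns = [f"pow_{ch}_{bd}" for ch, bd in wide.columns]
    return wide.reset_index()


def _stage_stats(task, truths, participants, analysis, outdir, seed):
    augmented = read_trials(_require(outdir / "trials_augmented.csv",
                                     "fit_behavior"))
    behavioral_only = bool(analysis.get("behavioral_only", False))
    artifact_ids = []
    if not behavioral_only:
        power = read_trials(_require(outdir / "band_power.csv", "spectra"))
        augmented = augmented.merge(_power_wide(power),
                                    on=["participant", "trial_global"],
                                    how="left")
        art = json.loads((outdir / "artifact_report.json").read_text())
        for pid, rep in art.items():
            artifact_ids += [(pid, t) for t in rep["rejected_trial_ids"]]
    prepared = prepare_regressors(augmented, artifact_ids=artifact_ids,
                                  deadline=task.response_deadline)

    dependents = [("choice", "binomial"), ("log_rt", "gaussian")]
    if not behavioral_only:
        dependents += [(c, "gaussian") for c in augmented.columns
                       if c.startswith("pow_")]
    rows, filter_reports = [], {}
    for dep, family in dependents:
        cmp_res = compare_value_models(prepared, dep, family=family)
        for model_name in ("sv_model", "reward_effort_model"):
            res = cmp_res[model_name]
            filter_reports[f"{dep}:{model_name}"] = res.filter_report.to_dict()
            for _, r in res.effects.iterrows():
                rows.append({
                    "dependent": dep, "model": model_name,
                    "effect": r["effect"], "estimate": r["estimate"],
                    "se": r["se"], "lrt_stat": r["lrt_stat"],
                    "lrt_p": r["lrt_p"],
                    "n_observations": res.n_observations,
                    "estimator": res.metadata["estimator"],
                })
    results = pd.DataFrame(rows)
    return [
        write_trials(results, outdir / "results.csv"),
        write_json(filter_reports, outdir / "filter_reports.json"),
    ]


def _stage_stim(task, truths, participants, analysis, outdir, seed):
    stim_cfg = stim_task_config(seed=task.seed)
    truth_off = truths[-1]
    # stimulation emulated as a net-SV (indifference point) shift plus
    # reduced effort discounting: more offers accepted, weaker effort effect
    k_scale = float(analysis.get("stim_k_scale", 0.6))
    sv_shift = float(analysis.get("stim_sv_offset", 2.0))
    truth_on = truth_off.replace(k=truth_off.k * k_scale, sv_offset=sv_shift)
    stim_trials = simulate_stim_sessions(
        stim_cfg, truth_on, truth_off, participant="P_stim", seed=seed)
    res = fit_stimulation_glm(stim_trials)
    arts = [write_trials(stim_trials, outdir / "stim_trials.csv")]
    payload = {
        "separation": res["separation"],
        "estimator": res["estimator"],
        "n_observations": res["n_observations"],
        "terms": res["terms"].to_dict(orient="records"),
        "behavior_fits": {k: (v.to_dict() if v is not None else None)
                          for k, v in res.get("behavior_fits", {}).items()},
    }
    if "fallback" in res:
        payload["fallback"] = res["fallback"]
    arts.append(write_json(payload, outdir / "stim_results.json"))
    return arts


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit_behavior": _stage_fit_behavior,
    "spectra": _stage_spectra,
    "stats": _stage_stats,
    "stim": _stage_stim,
}


REQUIRED_TRIAL_COLUMNS = [
    "participant", "session", "block", "trial_in_block", "trial_global",
    "reward", "effort", "choice", "rt",
]


def load_external_study(path, descriptor):
    """Load a user-supplied study into the internal representation.

    ``descriptor`` maps the external layout onto the internal schema::

        {"trials_file": "behavior.csv",
         "columns": {"participant": "subj", ...},   # internal -> external
         "choice_coding": {"accept": "yes", "reject": "no"},  # optional
         "effort_units": "percent" | "fraction",
         "epoch_files": {"P01": "p01_epochs.h5", ...}}        # optional

    Validation is all-or-nothing: every schema problem is collected into an
    itemized report and raised together; nothing is partially loaded.
    """
    path = Path(path)
    problems = []
    trials_file = path / descriptor.get("trials_file", "trials.csv")
    if not trials_file.exists():
        raise FileNotFoundError(f"trial table not found: {trials_file}")
    raw = pd.read_csv(trials_file)
    colmap = descriptor.get("columns", {})
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    for col in REQUIRED_TRIAL_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise ConfigError("external study failed validation:\n  - "
                          + "\n  - ".join(problems))

    coding = descriptor.get("choice_coding")
    if coding:
        mapping = {coding["accept"]: 1.0, coding["reject"]: 0.0}
        bad = set(df["choice"].dropna()) - set(mapping)
        if bad:
            problems.append(f"choice values outside coding {coding}: {sorted(map(str, bad))}")
        else:
            df["choice"] = df["choice"].map(mapping)
    else:
        bad = set(df["choice"].dropna()) - {0, 1, 0.0, 1.0}
        if bad:
            problems.append(f"choice values not 0/1: {sorted(map(str, bad))}")
    if descriptor.get("effort_units", "fraction") == "percent":
        df["effort"] = df["effort"].astype(float) / 100.0
    eff = df["effort"].dropna().astype(float)
    if len(eff) and (eff.min() <= 0 or eff.max() > 1.0):
        problems.append("effort values outside (0, 1] after unit conversion")
    rt = df["rt"].dropna().astype(float)
    if len(rt) and rt.min() < 0:
        problems.append("negative RTs")
    if "first_in_block" not in df.columns:
        df["first_in_block"] = df["trial_in_block"] == df["trial_in_block"].min()
    if "stim_on" not in df.columns:
        df["stim_on"] = False

    epochs = {}
    for pid, fname in descriptor.get("epoch_files", {}).items():
        f = path / fname
        if not f.exists():
            problems.append(f"epoch file for {pid} not found: {fname}")
            continue
        eset = read_epochs(f)
        if eset.fs <= 0:
            problems.append(f"{pid}: nonpositive sampling rate")
        dt = np.diff(eset.times)
        if not np.allclose(dt, dt[0]):
            problems.append(f"{pid}: nonuniform time axis")
        epochs[pid] = eset
    if problems:
        raise ConfigError("external study failed validation:\n  - "
                          + "\n  - ".join(problems))
    return df, epochs
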