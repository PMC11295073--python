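"""Synthetic study generator for the effort-based decision task.

Produces task schedules, model-driven choices and reaction times, and
structured two-channel LFP epochs with known ground truth, so that every
downstream stage (behavioral fitting, spectral extraction, mixed-model
inference) can be validated by parameter and effect recovery.

The generator emulates the study design: 5 reward x 5 effort offers over
3 blocks x 25 trials x 2 sessions per participant; choices drawn from the
parabolic-SV/softmax model; log reaction times linear in current and
previous decision ease; epochs from -2 to 9 s at 422 Hz containing
1/f-shaped background noise plus a PFC theta burst whose amplitude scales
with the previous offer's reward and a BG low-beta burst whose amplitude
scales negatively with the current effort cost k*E^2; and an optional
block-wise stimulation protocol (4 ON / 4 OFF blocks of 25 trials).
"""

from __future__ import annotations

import logging
import zlib

import numpy as np
import pandas as pd

from .behavior import compute_sv, decision_ease, p_accept
from .config import ConfigError, GroundTruth, StimDesign, TaskConfig
from .spectral import LFPEpochSet

log = logging.getLogger(__name__)

__all__ = [
    "build_offer_schedule",
    "simulate_choices",
    "simulate_rts",
    "simulate_lfp",
    "simulate_stim_sessions",
    "simulate_participant",
    "simulate_study",
    "stim_task_config",
    "zscore",
]

SCHEDULE_COLUMNS = [
    "participant", "session", "block", "trial_in_block", "trial_global",
    "reward", "effort", "stim_on", "choice", "rt", "iti", "first_in_block",
]


def zscore(x):
    """Plain z-score; raises on zero variance (degenerate regressor)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


def _rng(seed, *key):
    # documented derivation: independent streams from (seed, *key)
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *map(int, key)])


def _draw_offers(n, rewards, efforts, rng):
    """Repeated shuffled passes over the reward x effort grid.

    Full passes guarantee exact balance; leftover slots are drawn without
    replacement from one final shuffled pass.
    """
    grid = [(r, e) for r in rewards for e in efforts]
    cells = []
    n_full, rem = divmod(n, len(grid))
    for _ in range(n_full):
        idx = rng.permutation(len(grid))
        cells.extend(grid[i] for i in idx)
    if rem:
        idx = rng.permutation(len(grid))[:rem]
        cells.extend(grid[i] for i in idx)
    return cells


def build_offer_schedule(config: TaskConfig, participant="P01",
                         require_exact_balance=False) -> pd.DataFrame:
    """Build the ordered offer schedule for one participant.

    Deterministic given ``config.seed``.  Offers cover the reward x effort
    grid as evenly as the trial count allows; ITIs are uniform over
    ``config.iti_range``.  With ``require_exact_balance`` the trial count
    must be a multiple of the grid size.
    """
    n = config.n_trials
    if require_exact_balance and n % config.grid_size:
        raise ConfigError(
            f"{n} trials cannot cover the {config.grid_size}-cell grid evenly "
            f"({n} % {config.grid_size} = {n % config.grid_size})")
    # stable participant hash: schedules must reproduce across processes
    rng = _rng(config.seed, zlib.crc32(str(participant).encode()) & 0xFFFF, 0)
    offers = _draw_offers(n, config.reward_levels, config.effort_levels, rng)
    itis = rng.uniform(*config.iti_range, size=n)

    rows = []
    t = 0
    for s in range(1, config.sessions + 1):
        for b in range(1, config.blocks_per_session + 1):
            for ti in range(1, config.trials_per_block + 1):
                r, e = offers[t]
                rows.append({
                    "participant": participant, "session": s, "block": b,
                    "trial_in_block": ti, "trial_global": t,
                    "reward": r, "effort": e, "stim_on": False,
                    "choice": np.nan, "rt": np.nan, "iti": itis[t],
                    "first_in_block": ti == 1,
                })
                t += 1
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def simulate_choices(schedule: pd.DataFrame, truth: GroundTruth,
                     seed=0) -> pd.DataFrame:
    """Draw accept/reject choices from the ground-truth SV/softmax model.

    Adds ``sv_true``, ``p_accept_true``, ``ease_true`` and fills ``choice``
    (1 accept / 0 reject).  Deterministic given ``seed``.
    """
    out = schedule.copy()
    sv = compute_sv(out["reward"].to_numpy(float),
                    out["effort"].to_numpy(float), truth.k)
    p = p_accept(sv + truth.sv_offset, truth.beta, form="as_printed")
    rng = _rng(seed, 1)
    out["sv_true"] = sv
    out["p_accept_true"] = p
    out["ease_true"] = decision_ease(p)
    out["choice"] = (rng.random(len(out)) < p).astype(float)
    return out


def _lag_within_block(df, col):
    """Previous-trial value lagged within block; the first trial of each
    block uses its own (the block's first) offer and is flagged upstream."""
    lagged = df.groupby(["participant", "session", "block"], sort=False)[col].shift(1)
    return lagged.fillna(df[col])


def simulate_rts(schedule: pd.DataFrame, truth: GroundTruth,
                 seed=0, deadline=6.0) -> pd.DataFrame:
    """Simulate log-normal reaction times with difficulty effects.

    log(rt) = rt_base + rt_ease_coef * z(ease_t)
            + rt_prev_ease_coef * z(ease_{t-1}) + N(0, rt_noise_sd).
    RTs are clipped to (0, deadline]; clipping is logged.
    """
    out = schedule.copy()
    if "ease_true" not in out:
        raise ValueError("simulate_rts requires ease_true (run simulate_choices)")
    z_ease = zscore(out["ease_true"].to_numpy(float))
    out["_ze"] = z_ease
    prev = _lag_within_block(out, "_ze").to_numpy(float)
    rng = _rng(seed, 2)
    logrt = (truth.rt_base
             + truth.rt_ease_coef * z_ease
             + truth.rt_prev_ease_coef * prev
             + rng.normal(0.0, truth.rt_noise_sd, size=len(out)))
    rt = np.exp(logrt)
    n_clip = int((rt > deadline).sum())
    if n_clip:
        log.warning("clipped %d simulated RTs to the %.1f s deadline", n_clip, deadline)
    out["rt"] = np.minimum(rt, deadline)
    return out.drop(columns="_ze")


def _cosine_ramp_envelope(times, window=(0.5, 1.5), ramp=0.25):
    """Burst envelope: raised-cosine ramps inside the window edges."""
    env = np.zeros_like(times)
    lo, hi = window
    rise = (times >= lo) & (times < lo + ramp)
    flat = (times >= lo + ramp) & (times <= hi - ramp)
    fall = (times > hi - ramp) & (times <= hi)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (times[rise] - lo) / ramp))
    env[flat] = 1.0
    env[fall] = 0.5 * (1 + np.cos(np.pi * (times[fall] - (hi - ramp)) / ramp))
    return env


def _one_over_f_noise(rng, n_trials, n_samples, fs, exponent, sd):
    """Spectrally shaped Gaussian noise with target standard deviation."""
    white = rng.standard_normal((n_trials, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples, 1 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def simulate_lfp(schedule: pd.DataFrame, truth: GroundTruth,
                 seed=0) -> LFPEpochSet:
    """Generate two-channel (PFC, BG) epochs with known spectral effects.

    Each epoch is 1/f background noise plus amplitude-modulated bursts in
    the 0.5-1.5 s decision window: PFC theta amplitude
    ``osc_amp * (1 + theta_prevreward_gain * z(R_{t-1}))`` and BG low-beta
    amplitude ``osc_amp * (1 - beta_effort_gain * z(k*E_t^2))``; amplitudes
    are floored at 0 (warned when >10% of trials hit the floor), phase is
    uniform per trial.
    """
    n = len(schedule)
    fs = truth.fs
    t_lo, t_hi = truth.epoch_window
    n_samples = int(round((t_hi - t_lo) * fs))
    times = t_lo + np.arange(n_samples) / fs
    rng = _rng(seed, 3)

    prev_r = _lag_within_block(schedule, "reward").to_numpy(float)
    effort_cost = truth.k * schedule["effort"].to_numpy(float) ** 2
    z_prev_r = zscore(prev_r)
    z_cost = zscore(effort_cost)

    theta_amp = truth.osc_amp * (1 + truth.theta_prevreward_gain * z_prev_r)
    beta_amp = truth.osc_amp * (1 - truth.beta_effort_gain * z_cost)
    for name, amp in (("theta", theta_amp), ("beta", beta_amp)):
        n_floor = int((amp < 0).sum())
        if n_floor > 0.1 * n:
            log.warning("%s amplitude floored at 0 on %d/%d trials "
                        "(gain too large for the regressor spread)",
                        name, n_floor, n)
    theta_amp = np.maximum(theta_amp, 0.0)
    beta_amp = np.maximum(beta_amp, 0.0)

    env = _cosine_ramp_envelope(times)
    data = np.empty((n, 2, n_samples))
    for ci in range(2):
        data[:, ci, :] = _one_over_f_noise(
            rng, n, n_samples, fs, truth.aperiodic_exponent, truth.noise_sd)
    phases = rng.uniform(0, 2 * np.pi, size=(n, 2))
    f_theta = truth.theta_center_hz
    f_beta = truth.beta_center_hz["BG"]
    data[:, 0, :] += (theta_amp[:, None] * env[None, :]
                      * np.sin(2 * np.pi * f_theta * times[None, :]
                               + phases[:, 0:1]))
    data[:, 1, :] += (beta_amp[:, None] * env[None, :]
                      * np.sin(2 * np.pi * f_beta * times[None, :]
                               + phases[:, 1:2]))

    participant = str(schedule["participant"].iloc[0])
    return LFPEpochSet(
        data=data, fs=fs, t0=t_lo,
        channels=["PFC", "BG"], regions={"PFC": "PFC", "BG": "BG"},
        trial_ids=schedule["trial_global"].to_numpy(),
        participant=participant,
        meta={"seed": int(seed), "ground_truth": truth.to_dict()},
    )


def stim_task_config(seed=0) -> TaskConfig:
    """Default stimulation protocol: 4 ON + 4 OFF blocks of 25 trials
    (2 sessions x 4 blocks so per-session counterbalancing is exact),
    reproducing the study's 100 ON / 100 OFF trial totals."""
    return TaskConfig(blocks_per_session=4, sessions=2,
                      stim_design=StimDesign(), seed=seed)


def simulate_stim_sessions(config: TaskConfig, truth_on: GroundTruth,
                           truth_off: GroundTruth, participant="P05",
                           seed=0) -> pd.DataFrame:
    """Simulate block-wise stimulation sessions with condition-specific
    behavior.

    ON/OFF labels are assigned per block, randomized and (by default)
    counterbalanced within each session; choices and RTs are drawn from
    ``truth_on`` on ON blocks and ``truth_off`` on OFF blocks.
    """
    if config.stim_design is None:
        raise ConfigError("simulate_stim_sessions requires config.stim_design")
    design = config.stim_design
    total_blocks = config.blocks_per_session * config.sessions
    if design.blocks_on + design.blocks_off != total_blocks:
        raise ConfigError(
            f"stim design has {design.blocks_on}+{design.blocks_off} blocks but "
            f"the schedule has {total_blocks}")
    rng = _rng(seed, 4)
    if design.order == "counterbalanced":
        if config.blocks_per_session % 2:
            raise ConfigError("counterbalanced ON/OFF needs an even number of "
                              f"blocks per session, got {config.blocks_per_session}")
        labels = []
        half = config.blocks_per_session // 2
        for _ in range(config.sessions):
            sess = np.array([True] * half + [False] * half)
            labels.append(rng.permutation(sess))
        labels = np.concatenate(labels)
    else:
        labels = rng.permutation(
            np.array([True] * design.blocks_on + [False] * design.blocks_off))

    schedule = build_offer_schedule(config, participant=participant)
    block_key = (schedule["session"].astype(str) + "/"
                 + schedule["block"].astype(str))
    uniq = list(dict.fromkeys(block_key))
    on_map = dict(zip(uniq, labels))
    schedule["stim_on"] = block_key.map(on_map).astype(bool)

    on = simulate_choices(schedule, truth_on, seed=seed)
    off = simulate_choices(schedule, truth_off, seed=seed + 1)
    mask = schedule["stim_on"].to_numpy()
    merged = off.copy()
    for col in ("sv_true", "p_accept_true", "ease_true", "choice"):
        merged.loc[mask, col] = on.loc[mask, col]
    merged = simulate_rts(merged, truth_off, seed=seed + 2,
                          deadline=config.response_deadline)
    return merged


def simulate_participant(config: TaskConfig, truth: GroundTruth,
                         participant="P01", seed=0, with_lfp=True):
    """Full single-participant simulation: schedule, choices, RTs, epochs."""
    schedule = build_offer_schedule(config, participant=participant)
    trials = simulate_choices(schedule, truth, seed=seed)
    trials = simulate_rts(trials, truth, seed=seed,
                          deadline=config.response_deadline)
    epochs = simulate_lfp(trials, truth, seed=seed) if with_lfp else None
    return trials, epochs


def simulate_study(config: TaskConfig, truths, participants=None, seed=0,
                   with_lfp=True):
    """Simulate a multi-participant study.

    ``truths`` is one GroundTruth shared by all participants or a list with
    one per participant.  Returns (trials DataFrame over all participants,
    dict participant -> LFPEpochSet or None).
    """
    if participants is None:
        n = len(truths) if isinstance(truths, (list, tuple)) else 4
        participants = [f"P{i + 1:02d}" for i in range(n)]
    if not isinstance(truths, (list, tuple)):
        truths = [truths] * len(participants)
    if len(truths) != len(participants):
        raise ConfigError("need one GroundTruth per participant")
    frames, epoch_sets = [], {}
    for i, (pid, truth) in enumerate(zip(participants, truths)):
        cfg = config.replace(seed=config.seed + i)
        trials, epochs = simulate_participant(
            cfg, truth, participant=pid, seed=seed + 1000 + i, with_lfp=with_lfp)
        frames.append(trials)
        epoch_sets[pid] = epochs
    return pd.concat(frames, ignore_index=True), epoch_sets
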