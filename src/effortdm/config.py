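"""Task and ground-truth configuration for the effort-based decision task.

The defaults reproduce the apple-gathering paradigm used in the study this
package models: 5 reward levels (1, 4, 7, 10, 13 points) crossed with 5
effort levels (16–80% of maximal voluntary contraction), 3 blocks of 25
offers per session and 2 sessions per participant (150 choice trials), an
inter-trial interval drawn uniformly from 1.6–1.8 s, response mappings
revealed 1.5 s after offer onset, and a 6 s response deadline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "TaskConfig",
    "StimDesign",
    "GroundTruth",
    "ConfigError",
    "load_config",
    "effort_fraction_to_percent",
    "effort_percent_to_fraction",
]


class ConfigError(ValueError):
    """Raised when a task or analysis configuration violates its invariants."""


def effort_fraction_to_percent(e):
    """Convert effort as a fraction of max force (0–1] to percent (0–100]."""
    return e * 100.0


def effort_percent_to_fraction(e):
    """Convert effort in percent of max force to a fraction in (0, 1]."""
    return e / 100.0


@dataclass(frozen=True)
class StimDesign:
    """Block-wise stimulation protocol (ON/OFF across blocks, counterbalanced)."""

    blocks_on: int = 4
    blocks_off: int = 4
    order: str = "counterbalanced"  # or "random"

    def __post_init__(self):
        if self.blocks_on < 1 or self.blocks_off < 1:
            raise ConfigError("stim design needs at least one ON and one OFF block")
        if self.order not in ("counterbalanced", "random"):
            raise ConfigError(f"unknown stim order policy: {self.order!r}")


@dataclass(frozen=True)
class TaskConfig:
    reward_levels: tuple = (1, 4, 7, 10, 13)
    effort_levels: tuple = (0.16, 0.32, 0.48, 0.64, 0.80)
    trials_per_block: int = 25
    blocks_per_session: int = 3
    sessions: int = 2
    iti_range: tuple = (1.6, 1.8)
    mapping_delay: float = 1.5
    response_deadline: float = 6.0
    stim_design: StimDesign | None = None
    seed: int = 0

    def __post_init__(self):
        if len(set(self.reward_levels)) < 2:
            raise ConfigError("need >= 2 distinct reward levels")
        if len(set(self.effort_levels)) < 2:
            raise ConfigError("need >= 2 distinct effort levels")
        if not all(0.0 < e <= 1.0 for e in self.effort_levels):
            raise ConfigError("effort levels must be fractions of max force in (0, 1]")
        lo, hi = self.iti_range
        if not lo < hi:
            raise ConfigError("iti_range must satisfy lo < hi")
        if min(lo, self.mapping_delay, self.response_deadline) <= 0:
            raise ConfigError("all durations must be positive")
        if min(self.trials_per_block, self.blocks_per_session, self.sessions) < 1:
            raise ConfigError("counts must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.trials_per_block * self.blocks_per_session * self.sessions

    @property
    def grid_size(self) -> int:
        return len(self.reward_levels) * len(self.effort_levels)

    def replace(self, **kw) -> "TaskConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters for one simulated participant.

    Behavioral side: choices follow the parabolic subjective-value model
    SV = R - k*E^2 passed through the as-printed softmax with temperature
    ``beta``; log reaction times are linear in the z-scored decision ease of
    the current and previous offer.

    Neural side: each epoch is 1/f-shaped Gaussian background noise plus, on
    the PFC channel, a theta burst whose amplitude scales with the previous
    offer's reward, and on the BG channel a low-beta burst whose amplitude
    scales negatively with the current effort cost k*E^2.  Oscillation phase
    is randomized per trial; bursts occupy the 0.5–1.5 s decision window with
    0.25 s cosine ramps.
    """

    k: float = 15.0
    beta: float = 1.0
    sv_offset: float = 0.0  # additive shift of net SV (indifference-point shift)
    rt_base: float = 1.05  # log-seconds; exp(1.05) ~ 2.86 s
    rt_ease_coef: float = -0.040
    rt_prev_ease_coef: float = 0.027
    rt_noise_sd: float = 0.25
    theta_center_hz: float = 5.5
    theta_prevreward_gain: float = 0.3
    beta_center_hz: dict = field(default_factory=lambda: {"PFC": 16.0, "BG": 16.0})
    beta_effort_gain: float = 0.3
    osc_amp: float = 0.5  # burst amplitude, uV-like units; ~5 MAD units of band power
    aperiodic_exponent: float = 1.0
    noise_sd: float = 1.0
    fs: float = 422.0
    epoch_window: tuple = (-2.0, 9.0)

    def __post_init__(self):
        if self.k < 0:
            raise ConfigError("k must be >= 0")
        if self.beta <= 0:
            raise ConfigError("beta must be > 0")
        if not 4.0 <= self.theta_center_hz <= 7.0:
            raise ConfigError("theta_center_hz must lie in 4-7 Hz")
        for ch, f in self.beta_center_hz.items():
            if not 12.0 <= f <= 20.0:
                raise ConfigError(f"beta_center_hz[{ch!r}] must lie in 12-20 Hz")
        max_f = max([self.theta_center_hz, *self.beta_center_hz.values(), 40.0])
        if self.fs <= 2 * max_f:
            raise ConfigError("fs must exceed twice the highest analysis frequency")
        lo, hi = self.epoch_window
        if lo > -2.0 or hi < 9.0:
            raise ConfigError("epoch_window must cover at least (-2, 9) s")

    def replace(self, **kw) -> "GroundTruth":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_stim(d: dict | None) -> StimDesign | None:
    if d is None:
        return None
    return StimDesign(**d)


def load_config(path) -> dict:
    """Load a declarative YAML/JSON run configuration.

    Recognized top-level keys: ``task`` (TaskConfig fields, with
    ``stim_design`` as a nested mapping), ``truth`` (GroundTruth fields,
    either one mapping shared by all participants or a list of mappings),
    ``participants`` (count or list of ids), and free-form ``analysis``
    options passed through to the pipeline.  Unknown keys raise.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {"task", "truth", "participants", "analysis"}
    extra = set(raw) - known
    if extra:
        raise ConfigError(f"unknown config keys: {sorted(extra)}")

    task_kw = dict(raw.get("task", {}))
    if "stim_design" in task_kw:
        task_kw["stim_design"] = _build_stim(task_kw["stim_design"])
    for key in ("reward_levels", "effort_levels", "iti_range", "epoch_window"):
        if key in task_kw and isinstance(task_kw[key], Sequence):
            task_kw[key] = tuple(task_kw[key])
    task = TaskConfig(**task_kw)

    truth_raw = raw.get("truth", {})
    def _mk_truth(d):
        d = dict(d)
        if "epoch_window" in d:
            d["epoch_window"] = tuple(d["epoch_window"])
        return GroundTruth(**d)
    if isinstance(truth_raw, list):
        truth = [_mk_truth(d) for d in truth_raw]
    else:
        truth = _mk_truth(truth_raw)

    participants = raw.get("participants", 4)
    if isinstance(participants, int):
        participants = [f"P{i + 1:02d}" for i in range(participants)]
    return {
        "task": task,
        "truth": truth,
        "participants": list(participants),
        "analysis": dict(raw.get("analysis", {})),
    }
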