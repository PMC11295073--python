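"""Subjective-value model of effort-based choice.

The model discounts reward by a participant-specific parabolic effort cost,

    SV(t) = R(t) - k * E(t)**2,

with R the offered points, E the required force as a fraction of the
participant's maximum, and k >= 0 the effort weight.  Choices follow a
softmax decision policy.  Two algebraic forms of the policy are supported:

``as_printed``
    p(Accept) = exp(beta*SV) / (exp(beta) + exp(beta*SV)),
    the form written in the source literature for this task; it places the
    indifference point at SV = 1 and is identical to a logistic in
    beta*(SV - 1).
``canonical``
    p(Accept) = 1 / (1 + exp(-beta*SV)), indifference at SV = 0.

Decision ease is the distance from indifference, abs(p(Accept) - 0.5);
smaller values mean harder decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "compute_sv",
    "p_accept",
    "decision_ease",
    "choice_nll",
    "fit_participant",
    "evaluate_offers",
    "BehavioralFit",
    "FitError",
]

_P_CLIP = 1e-9  # probability clipping inside the likelihood
K_BOUNDS = (0.0, 100.0)
BETA_BOUNDS = (1e-3, 50.0)


class FitError(ValueError):
    pass


def compute_sv(R, E, k):
    """Subjective value R - k*E**2 (vectorized).

    E is a fraction of maximum force in [0, 1]; k must be nonnegative.
    """
    if np.any(np.asarray(k) < 0):
        raise ValueError("effort weight k must be >= 0")
    R = np.asarray(R, dtype=float)
    E = np.asarray(E, dtype=float)
    return R - np.asarray(k, dtype=float) * E**2


def p_accept(sv, beta, form="as_printed"):
    """Acceptance probability of an offer with subjective value ``sv``.

    Overflow-safe: both forms are evaluated through the logistic function.
    """
    sv = np.asarray(sv, dtype=float)
    if not np.all(np.isfinite(sv)):
        raise ValueError("sv must be finite")
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("softmax temperature beta must be > 0")
    if form == "as_printed":
        # exp(b*sv)/(exp(b)+exp(b*sv)) == logistic(b*(sv-1))
        return expit(beta * (sv - 1.0))
    if form == "canonical":
        return expit(beta * sv)
    raise ValueError(f"unknown softmax form: {form!r}")


def decision_ease(p):
    """Decision ease abs(p - 0.5); 0 at the indifference point, max 0.5."""
    return np.abs(np.asarray(p, dtype=float) - 0.5)


def choice_nll(params, R, E, choices, form="as_printed", objective="nll"):
    """Objective for (k, beta) given 0/1 choices.

    ``nll`` is the Bernoulli negative log-likelihood with probabilities
    clipped to [1e-9, 1 - 1e-9]; ``sse`` is the summed squared difference
    between p(Accept) and the observed choices.
    """
    k, beta = params
    p = p_accept(compute_sv(R, E, k), beta, form=form)
    if objective == "sse":
        return float(np.sum((p - choices) ** 2))
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-np.sum(choices * np.log(p) + (1 - choices) * np.log1p(-p)))


@dataclass
class BehavioralFit:
    participant_id: str
    k: float
    beta: float
    objective_value: float
    n_trials_fit: int
    converged: bool
    n_starts: int
    softmax_form: str
    objective: str = "nll"
    at_bound: tuple = ()
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "k": self.k,
            "beta": self.beta,
            "objective_value": self.objective_value,
            "n_trials_fit": self.n_trials_fit,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "softmax_form": self.softmax_form,
            "objective": self.objective,
            "at_bound": list(self.at_bound),
            "flags": list(self.flags),
        }


def _start_grid(n_k=5, n_beta=5):
    # log-spaced over the behaviorally distinguishable range for rewards <= 13
    ks = np.geomspace(0.5, 80.0, n_k)
    betas = np.geomspace(0.01, 20.0, n_beta)
    return [(k, b) for k in ks for b in betas]


def fit_participant(trials, participant_id=None, form="as_printed",
                    objective="nll", min_trials=20):
    """Fit (k, beta) to one participant's accept/reject choices.

    ``trials`` is a DataFrame with columns ``reward``, ``effort`` (fraction
    of max force) and ``choice`` (1 accept / 0 reject; NaN rows are dropped).
    The objective is minimized over a bounded box (k in [0, 100], beta in
    [1e-3, 50]) from a 5x5 log-spaced multi-start grid; the best start's
    optimum is returned.  Deterministic: refitting identical data reproduces
    identical estimates.

    Degenerate inputs (all-accept or all-reject) return a flagged boundary
    fit rather than failing silently.
    """
    df = trials.dropna(subset=["choice"])
    df = df[df["choice"].isin((0, 1, 0.0, 1.0))]
    if participant_id is None:
        participant_id = str(df["participant"].iloc[0]) if "participant" in df else "?"
    n = len(df)
    if n < min_trials:
        raise FitError(f"participant {participant_id}: only {n} valid choice "
                       f"trials (< {min_trials})")
    R = df["reward"].to_numpy(dtype=float)
    E = df["effort"].to_numpy(dtype=float)
    c = df["choice"].to_numpy(dtype=float)

    flags = []
    one_sided = c.min() == c.max()
    if one_sided:
        flags.append("all_accept" if c[0] == 1 else "all_reject")

    starts = _start_grid()
    best = None
    for x0 in starts:
        res = minimize(
            choice_nll, x0=np.array(x0), args=(R, E, c, form, objective),
            method="L-BFGS-B", bounds=[K_BOUNDS, BETA_BOUNDS],
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    k_hat, beta_hat = float(best.x[0]), float(best.x[1])

    at_bound = []
    tol = 1e-6
    if k_hat <= K_BOUNDS[0] + tol or k_hat >= K_BOUNDS[1] - tol:
        at_bound.append("k")
    if beta_hat <= BETA_BOUNDS[0] + tol or beta_hat >= BETA_BOUNDS[1] * (1 - 1e-6):
        at_bound.append("beta")
    if at_bound:
        flags.append("at_bound:" + ",".join(at_bound))

    converged = bool(best.success) and not one_sided and not at_bound
    return BehavioralFit(
        participant_id=str(participant_id),
        k=k_hat, beta=beta_hat,
        objective_value=float(best.fun),
        n_trials_fit=n,
        converged=converged,
        n_starts=len(starts),
        softmax_form=form,
        objective=objective,
        at_bound=tuple(at_bound),
        flags=flags,
    )


def evaluate_offers(trials: pd.DataFrame, fit: BehavioralFit,
                    allow_unconverged=False) -> pd.DataFrame:
    """Populate sv, p_accept and ease columns from a behavioral fit.

    Refuses unconverged fits unless ``allow_unconverged`` (the caller then
    owns the interpretation of boundary estimates).
    """
    if not fit.converged and not allow_unconverged:
        raise FitError(
            f"fit for {fit.participant_id} not converged "
            f"(flags={fit.flags}); pass allow_unconverged=True to override")
    out = trials.copy()
    sv = compute_sv(out["reward"].to_numpy(float), out["effort"].to_numpy(float), fit.k)
    p = p_accept(sv, fit.beta, form=fit.softmax_form)
    out["sv"] = sv
    out["p_accept"] = p
    out["ease"] = decision_ease(p)
    return out
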