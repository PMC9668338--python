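"""Reconstructed-tree birth-death likelihood with time- and environment-
dependent rates and incomplete uniform species sampling.

Model
-----
Speciation and extinction rates follow the exponential forms

    lambda(t) = lambda0 * exp(alpha * t)        (time dependence)
    lambda(t) = lambda0 * exp(alpha * E(t))     (environmental dependence)

with t in Myr before present, so alpha > 0 (beta > 0) means higher speciation
(extinction) in the past, i.e. rates decreasing toward the present.  For
environmental forms, lambda0 is the rate at curve value 0 (e.g. 0 degC).

Likelihood
----------
Writing r(t) = lambda(t) - mu(t), R(t) = int_0^t r and

    Lam(t) = rho * lambda(t) * exp(R(t)),   J(t) = 1 + int_0^t Lam(s) ds,

the probability that a lineage of age t leaves at least one sampled
descendant is P(t) = Lam(t) / (lambda(t) * J(t)), and the density of a
singly-sampled pendant lineage is p1(t) = P(t) / J(t).  For a crown tree
with branching times t1 > t2 >= ... >= t_{n-1}, conditioned on the crown age
and on both crown lineages surviving to be sampled, the log-likelihood
collapses to

    log L = sum_{i>=2} [ log Lam(t_i) - 2 log J(t_i) ] - 2 log J(t1).

The data therefore enter only through Lam(t), i.e. through the pulled
diversification rate r_p(t) = d/dt log Lam(t) and the product rho*lambda0 =
Lam(0): the likelihood is constant on a birth-death congruence class, which
the pulled-rate module exploits directly.

Integrals are accumulated with composite Simpson quadrature on a uniform age
grid (default 4001 points per crown span) and interpolated at the branching
times; R(t) is cheap enough to re-evaluate per call, so no cross-call state
is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_simpson

from .env import SmoothEnv, env_value
from .trees import BranchingTimes

__all__ = [
    "RateSpec",
    "BDModel",
    "LikelihoodNumericsError",
    "rate_at",
    "net_rate",
    "log_likelihood",
    "loglik_from_logLam",
]

RATE_FORMS = ("constant", "exp_time", "exp_env")
DEFAULT_GRID = 4001


class LikelihoodNumericsError(ArithmeticError):
    """Raised when the likelihood integrals are not finite."""


@dataclass(frozen=True)
class RateSpec:
    """One parametric rate function (speciation or extinction)."""

    role: str  # "speciation" | "extinction"
    form: str  # "constant" | "exp_time" | "exp_env"
    baseline: float
    dependence: float = 0.0
    env: SmoothEnv | None = None

    def __post_init__(self):
        if self.role not in ("speciation", "extinction"):
            raise ValueError(f"bad role {self.role!r}")
        if self.form not in RATE_FORMS:
            raise ValueError(f"bad form {self.form!r}")
        if self.baseline < 0:
            raise ValueError("baseline rate must be >= 0")
        if self.form == "exp_env" and self.env is None:
            raise ValueError("exp_env rate needs an environmental curve")

    @property
    def n_free(self) -> int:
        return 1 if self.form == "constant" else 2

    def with_params(self, baseline: float, dependence: float = 0.0) -> "RateSpec":
        return replace(self, baseline=baseline, dependence=dependence)


def rate_at(spec: RateSpec, t):
    """Evaluate the rate at age(s) ``t`` (Myr before present)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative age")
    if spec.form == "constant":
        out = np.full_like(t_arr, spec.baseline, dtype=float)
    elif spec.form == "exp_time":
        out = spec.baseline * np.exp(spec.dependence * t_arr)
    else:
        out = spec.baseline * np.exp(spec.dependence * np.asarray(env_value(spec.env, t_arr)))
    return float(out) if t_arr.ndim == 0 else out


@dataclass(frozen=True)
class BDModel:
    """A speciation/extinction rate pair with a name and parameter count."""

    name: str
    lambda_spec: RateSpec
    mu_spec: RateSpec

    def __post_init__(self):
        if self.lambda_spec.role != "speciation" or self.mu_spec.role != "extinction":
            raise ValueError("lambda_spec/mu_spec roles are swapped")

    @property
    def k(self) -> int:
        """Free parameters: 2 baselines + 1 per exponential dependence."""
        return self.lambda_spec.n_free + self.mu_spec.n_free

    def speciation(self, t):
        return rate_at(self.lambda_spec, t)

    def extinction(self, t):
        return rate_at(self.mu_spec, t)


def net_rate(model: BDModel, t):
    """Net diversification r(t) = lambda(t) - mu(t); may be negative."""
    lam, mu = model.speciation(t), model.extinction(t)
    return lam - mu


def loglik_from_logLam(
    ts: np.ndarray,
    logLam: np.ndarray,
    event_ages: np.ndarray,
    t_max: float,
    n_stems: int,
    *,
    _logJ_at=None,
) -> float:
    """Log-likelihood of branching events given log Lam(t) on a uniform grid.

    ``event_ages`` are the branching times strictly inside [0, t_max);
    ``n_stems`` is the number of lineages alive at ``t_max`` (2 for a crown
    tree at its crown age), each conditioned on leaving sampled descendants.
    Shared by the canonical and the pulled likelihoods.
    """
    with np.errstate(over="ignore"):
        Lam = np.exp(logLam)
    if not np.all(np.isfinite(Lam)):
        raise LikelihoodNumericsError("Lam(t) overflowed; rates too large")
    Jint = cumulative_simpson(Lam, x=ts, initial=0.0)
    logJ = np.log1p(Jint)
    if not np.all(np.isfinite(logJ)):
        raise LikelihoodNumericsError("non-finite cumulative integral")
    logLam_ev = np.interp(event_ages, ts, logLam)
    logJ_ev = np.interp(event_ages, ts, logJ)
    logJ_top = np.interp(t_max, ts, logJ)
    out = float(np.sum(logLam_ev - 2.0 * logJ_ev) - n_stems * logJ_top)
    if _logJ_at is not None:
        _logJ_at.append(logJ_top)
    return out


def _grid(t_max: float, grid_points: int) -> np.ndarray:
    n = max(int(grid_points), 5)
    if n % 2 == 0:
        n += 1
    return np.linspace(0.0, t_max, n)


def log_likelihood(
    bt: BranchingTimes,
    model: BDModel,
    rho: float,
    conditioning: str = "crown_survival",
    grid_points: int = DEFAULT_GRID,
) -> float:
    """Log-likelihood of the branching times under ``model`` with uniform
    species-sampling fraction ``rho``.

    ``conditioning``:
      * ``"crown_survival"`` (default) — condition on the crown age and on
        both crown lineages leaving sampled descendants;
      * ``"crown"`` — condition on the crown age only.

    Returns ``-inf`` when a branching event has zero speciation rate; raises
    :class:`LikelihoodNumericsError` on non-finite integrals.
    """
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    if conditioning not in ("crown_survival", "crown"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    t1 = bt.crown_age
    events = bt.ages[1:]
    ts = _grid(t1, grid_points)
    lam = model.speciation(ts)
    mu = model.extinction(ts)
    if np.any(lam < 0):
        raise LikelihoodNumericsError("negative speciation rate")
    if np.all(lam == 0):
        return -np.inf
    R = cumulative_simpson(lam - mu, x=ts, initial=0.0)
    with np.errstate(divide="ignore"):
        logLam = np.log(rho) + np.log(lam) + R
    if np.any(np.isneginf(logLam)) and events.size:
        return -np.inf
    ll = loglik_from_logLam(ts, logLam, events, t1, 2)
    if conditioning == "crown":
        # add back the two survival probabilities: 2 * log P(t1),
        # log P = log Lam - log lambda - log J  (per crown lineage)
        Lam = np.exp(logLam)
        Jint = cumulative_simpson(Lam, x=ts, initial=0.0)
        logJ1 = float(np.log1p(Jint[-1]))
        logP1 = float(logLam[-1] - np.log(lam[-1]) - logJ1)
        ll += 2.0 * logP1
    if not np.isfinite(ll):
        raise LikelihoodNumericsError("non-finite log-likelihood")
    return ll
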