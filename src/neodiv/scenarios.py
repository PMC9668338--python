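"""Mapping fitted diversification models onto diversity-trajectory scenarios.

Four clade-level trajectories of species richness:

* Sc1 (gradual increase)      — constant net diversification;
* Sc2 (exponential increase)  — net diversification rising toward the present;
* Sc3 (saturated increase)    — net diversification falling toward the
                                present but still non-negative today;
* Sc4 (waxing and waning)     — falling net diversification that crosses
                                below zero, so diversity is being lost.

The trend of a non-constant winner is read from its realized r(t) = λ(t) − μ(t)
trajectory over the clade's own time span: the sign of the least-squares slope
of r against age (age is past-positive, so a positive slope means rates were
higher in the past, i.e. decreasing toward the present).  This grid rule
agrees with the sign of the exponential dependence for single-exponential
models and extends to environment-composed, non-monotone trajectories.

A parallel, deliberately weaker classification applies to pulled fits: a
time-variable pulled model with negative present-day pulled extinction
μ_p(0) < 0 diagnoses decreasing speciation; a positive μ_p(0) is compatible
with several canonical histories and is labelled "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .battery import FitResult
from .bd import net_rate, rate_at

__all__ = [
    "ScenarioCall",
    "PulledTrendCall",
    "classify_scenario",
    "classify_speciation_trend",
    "classify_pulled_trend",
    "SCENARIOS",
]

SCENARIOS = ("Sc1_gradual", "Sc2_exponential", "Sc3_saturated", "Sc4_waxing_waning")
TRENDS = ("constant", "increasing", "decreasing")

#: flatness threshold for the grid slope, relative to the mean |r|
FLAT_EPS_REL = 1e-4


@dataclass(frozen=True)
class ScenarioCall:
    scenario: str
    speciation_trend: str
    r_present: float
    basis: str = "time_only_comparison"
    reliable: bool = True

    def __post_init__(self):
        assert self.scenario in SCENARIOS
        assert self.speciation_trend in TRENDS


@dataclass(frozen=True)
class PulledTrendCall:
    trend: str  # "constant" | "decreasing_speciation" | "unknown"
    mu_p_present: float


def _grid_trend(values: np.ndarray, ts: np.ndarray) -> str:
    """'decreasing'/'increasing'/'constant' toward the present from a
    least-squares slope of the trajectory against age."""
    slope = np.polyfit(ts, values, 1)[0]
    eps = FLAT_EPS_REL * max(float(np.mean(np.abs(values))), 1e-12)
    if abs(slope) < eps:
        return "constant"
    # positive slope: larger in the past => decreasing toward present
    return "decreasing" if slope > 0 else "increasing"


def classify_scenario(
    best: FitResult,
    crown_age: float | None = None,
    basis: str = "time_only_comparison",
    n_grid: int = 100,
) -> ScenarioCall:
    """Classify the best-fitting model into Sc1–Sc4.

    A constant-rate winner is Sc1 by definition.  Otherwise r(t) is evaluated
    on a grid over [0, crown_age]; a flat trajectory is Sc1, an increasing one
    (toward the present) Sc2, a decreasing one Sc3 when r(0) >= 0 and Sc4 when
    r(0) < 0.  Non-converged winners are still classified but flagged.
    """
    crown_age = crown_age if crown_age is not None else best.crown_age
    model = best.model
    trend_l = classify_speciation_trend(best)
    r0 = float(net_rate(model, 0.0))
    reliable = bool(best.converged)
    if model.lambda_spec.form == "constant" and model.mu_spec.form == "constant":
        return ScenarioCall("Sc1_gradual", "constant", r0, basis, reliable)
    ts = np.linspace(0.0, crown_age, n_grid)
    r = np.asarray(net_rate(model, ts), dtype=float)
    trend = _grid_trend(r, ts)
    if trend == "constant":
        scen = "Sc1_gradual"
    elif trend == "increasing":
        scen = "Sc2_exponential"
    elif r0 >= 0:
        scen = "Sc3_saturated"
    else:
        scen = "Sc4_waxing_waning"
    return ScenarioCall(scen, trend_l, r0, basis, reliable)


def classify_speciation_trend(best: FitResult, n_grid: int = 100) -> str:
    """Trend of the speciation rate toward the present.

    Time-exponential λ: the sign of α decides (α > 0 means higher speciation
    in the past, hence decreasing).  Environment-composed λ: the grid-slope
    rule applied to the realized λ(t).  Constant λ (possibly with
    time-variable μ): "constant".
    """
    spec = best.model.lambda_spec
    if spec.form == "constant":
        return "constant"
    if spec.form == "exp_time":
        eps = FLAT_EPS_REL * max(abs(spec.baseline), 1e-12)
        if abs(spec.dependence) <= eps:
            return "constant"
        return "decreasing" if spec.dependence > 0 else "increasing"
    ts = np.linspace(0.0, best.crown_age, n_grid)
    return _grid_trend(np.asarray(rate_at(spec, ts), dtype=float), ts)


def classify_pulled_trend(pulled) -> PulledTrendCall:
    """Speciation-trend diagnosis from an AIC-selected pulled fit.

    Constant pulled winner → "constant".  Time-variable winner: μ_p(0) < 0 →
    "decreasing_speciation"; μ_p(0) >= 0 → "unknown" (compatible with both
    increasing and decreasing speciation).
    """
    mu_p0 = float(pulled.mu_p_knots[0])
    if pulled.n_intervals == 1:
        return PulledTrendCall("constant", mu_p0)
    if mu_p0 < 0:
        return PulledTrendCall("decreasing_speciation", mu_p0)
    return PulledTrendCall("unknown", mu_p0)
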