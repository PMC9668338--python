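"""Paleoenvironmental curves as smooth functions of age.

Curves (global mean temperature in °C, Andean paleo-elevation in m) arrive as
two-column (age, value) tables and are turned into continuous functions of
time before present with a cubic smoothing spline whose flexibility is set by
effective degrees of freedom.  Evaluation outside the sampled age range is
clamped to the boundary value: no trend is ever extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

logger = logging.getLogger(__name__)

__all__ = [
    "EnvCurve",
    "SmoothEnv",
    "load_env_table",
    "load_env_csv",
    "fit_smooth",
    "env_value",
    "make_synthetic_curve",
]


@dataclass(frozen=True)
class EnvCurve:
    """Sampled environmental series: strictly increasing ages (Myr), values."""

    ages: np.ndarray
    values: np.ndarray
    label: str = "env"
    units: str = ""

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ages.size < 2:
            raise ValueError("need at least 2 points")
        if np.any(~np.isfinite(ages)) or np.any(~np.isfinite(values)):
            raise ValueError("non-finite entries in curve")
        if np.any(ages < 0):
            raise ValueError("ages must be >= 0")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])


@dataclass(frozen=True)
class SmoothEnv:
    """Continuous age -> value mapping fitted to an :class:`EnvCurve`."""

    spline: object  # scipy BSpline (or a constant fallback)
    df: int
    source: EnvCurve

    def __call__(self, t):
        return env_value(self, t)


def load_env_table(rows, label: str = "env", units: str = "") -> EnvCurve:
    """Build a curve from (age, value) pairs.

    Rows are sorted by age; duplicate ages are collapsed by their mean value.
    """
    try:
        arr = np.asarray([[float(a), float(v)] for a, v in rows], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric row in environmental table: {exc}") from exc
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    df = pd.DataFrame(arr, columns=["age", "value"])
    collapsed = df.groupby("age", sort=True)["value"].mean().reset_index()
    return EnvCurve(
        ages=collapsed["age"].to_numpy(),
        values=collapsed["value"].to_numpy(),
        label=label,
        units=units,
    )


def load_env_csv(path, label: str | None = None, units: str = "") -> EnvCurve:
    """Read a two-column CSV (age_Myr, value) with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("environmental CSV needs two columns (age, value)")
    return load_env_table(
        df.iloc[:, :2].itertuples(index=False),
        label=label or str(df.columns[1]),
        units=units,
    )


def _hat_trace(x: np.ndarray, lam: float) -> float:
    """Trace of the smoothing-spline hat matrix (effective df) at penalty lam."""
    n = x.size
    tr = 0.0
    eye = np.eye(n)
    for j in range(n):
        spl = make_smoothing_spline(x, eye[j], lam=lam)
        tr += float(spl(x[j]))
    return tr


def fit_smooth(curve: EnvCurve, df: int | None = None) -> SmoothEnv:
    """Cubic smoothing spline with the penalty tuned to ``df`` effective
    degrees of freedom (trace of the hat matrix).

    ``df`` runs from 2 (a straight least-squares line) to the number of
    sampled points (exact interpolation).  Default: ``min(n_points, 50)``.
    """
    n = curve.ages.size
    if df is None:
        df = min(n, 50)
    if not (2 <= df <= n):
        raise ValueError(f"df must be in [2, {n}], got {df}")
    x, y = curve.ages, curve.values

    if df == 2:
        # the df -> 2 limit of the penalized spline is the least-squares line
        poly = np.polynomial.Polynomial.fit(x, y, deg=1)
        return SmoothEnv(spline=poly, df=df, source=curve)

    if n < 5:
        # too few points for the penalized spline: least-squares polynomial
        # of degree df-1 (df = n interpolates exactly)
        poly = np.polynomial.Polynomial.fit(x, y, deg=df - 1)
        return SmoothEnv(spline=poly, df=df, source=curve)

    if np.allclose(y, y[0]):
        # degenerate constant curve: any df gives the constant function
        spl = make_smoothing_spline(x, y, lam=0.0)
        return SmoothEnv(spline=spl, df=df, source=curve)

    if df >= n:
        return SmoothEnv(spline=make_smoothing_spline(x, y, lam=0.0), df=df, source=curve)

    # effective df is monotone decreasing in lam: bisect on log10(lam)
    span = x[-1] - x[0]
    lo, hi = -12.0, 12.0 + 3 * np.log10(max(span, 1e-6))
    target = float(df)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _hat_trace(x, 10.0**mid) > target:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** (0.5 * (lo + hi))
    return SmoothEnv(spline=make_smoothing_spline(x, y, lam=lam), df=df, source=curve)


def env_value(s: SmoothEnv, t):
    """Evaluate the smoothed curve at age(s) ``t`` (Myr before present).

    Ages beyond the sampled range are clamped to the nearest boundary value;
    negative ages are a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("negative age")
    lo, hi = s.source.ages[0], s.source.ages[-1]
    out = s.spline(np.clip(t_arr, lo, hi))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else np.asarray(out)


def make_synthetic_curve(kind: str, params: dict | None = None, seed: int = 0) -> EnvCurve:
    """Deterministic synthetic stand-ins for published paleo-curves.

    kinds
    -----
    cooling_ramp : monotone ramp from a warm past to a cool present
                   (params: max_age=65, present=12.0, past=28.0, n=131)
    step         : two-level curve with a jump at ``step_age``
                   (params: max_age=65, step_age=34, low=13.0, high=24.0)
    noisy_trend  : cooling ramp plus seeded Gaussian wiggles (sd=sigma)
    """
    p = dict(params or {})
    max_age = float(p.get("max_age", 65.0))
    n = int(p.get("n", 131))
    ages = np.linspace(0.0, max_age, n)
    if kind == "cooling_ramp":
        present, past = float(p.get("present", 12.0)), float(p.get("past", 28.0))
        vals = present + (past - present) * ages / max_age
    elif kind == "step":
        step_age = float(p.get("step_age", 34.0))
        low, high = float(p.get("low", 13.0)), float(p.get("high", 24.0))
        vals = np.where(ages < step_age, low, high)
    elif kind == "noisy_trend":
        present, past = float(p.get("present", 12.0)), float(p.get("past", 28.0))
        sigma = float(p.get("sigma", 1.0))
        rng = np.random.default_rng(seed)
        vals = present + (past - present) * ages / max_age + rng.normal(0, sigma, n)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return EnvCurve(ages=ages, values=vals, label=kind, units=str(p.get("units", "degC")))
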