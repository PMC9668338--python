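"""Maximum-likelihood fitting of the 10-model birth-death battery and
small-sample AIC model selection.

The battery per clade: constant rates; speciation and/or extinction
exponential in time; speciation and/or extinction exponential in global
temperature; speciation and/or extinction exponential in Andean paleo-
elevation.  Each model is fitted by L-BFGS-B from several Latin-hypercube
dispersed starting points (baselines searched in log space), and models are
ranked by AICc with Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.optimize import minimize
from scipy.stats import qmc

from .bd import BDModel, RateSpec, DEFAULT_GRID
from .env import SmoothEnv, env_value
from .trees import BranchingTimes

__all__ = [
    "FitSettings",
    "FitResult",
    "SelectionTable",
    "aicc",
    "akaike_weights",
    "fit_model",
    "run_battery",
    "battery_templates",
]

# lambda0 / mu0 bounds (events / lineage / Myr); time-dependence bounds 1/Myr.
BASELINE_BOUNDS = (1e-6, 10.0)
TIME_DEP_BOUNDS = (-0.5, 0.5)
#: an environmental dependence may change rates by at most e^±5 over the
#: observed curve range; bounds scale with that range.
ENV_DEP_SPAN = 5.0


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion.

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i ∝ exp(-ΔAICc_i / 2), normalized to sum 1."""
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    w = np.zeros_like(a)
    delta = a[finite] - np.min(a[finite])
    w_f = np.exp(-0.5 * delta)
    w[finite] = w_f / w_f.sum()
    return w


@dataclass(frozen=True)
class FitSettings:
    """Optimizer protocol: restarts, seed, quadrature grid, iteration caps."""

    n_restarts: int = 10
    seed: int = 0
    grid_points: int = 2001
    maxiter: int = 200
    bound_tol: float = 1e-6


@dataclass
class FitResult:
    model_name: str
    model: BDModel
    mle_params: dict[str, float]
    max_loglik: float
    k: int
    aicc: float
    converged: bool
    n_restarts_used: int
    best_restart_seed: int
    crown_age: float
    rho: float
    error: str | None = None


def _free_params(model: BDModel):
    """(name, lo, hi, is_log) for each free parameter of a template."""
    specs = []
    specs.append(("lambda0", np.log(BASELINE_BOUNDS[0]), np.log(BASELINE_BOUNDS[1]), True))
    specs.append(("mu0", np.log(BASELINE_BOUNDS[0]), np.log(BASELINE_BOUNDS[1]), True))
    for prefix, spec in (("alpha", model.lambda_spec), ("beta", model.mu_spec)):
        if spec.form == "exp_time":
            specs.append((prefix, TIME_DEP_BOUNDS[0], TIME_DEP_BOUNDS[1], False))
        elif spec.form == "exp_env":
            lo_v = float(np.min(spec.env.source.values))
            hi_v = float(np.max(spec.env.source.values))
            span = max(hi_v - lo_v, 1e-9)
            b = ENV_DEP_SPAN / span
            specs.append((prefix, -b, b, False))
    return specs


def _covariate(spec: RateSpec, ts: np.ndarray) -> np.ndarray:
    if spec.form == "constant":
        return np.zeros_like(ts)
    if spec.form == "exp_time":
        return ts
    return np.asarray(env_value(spec.env, ts))


def _make_objective(bt: BranchingTimes, model: BDModel, rho: float, grid_points: int):
    """Vectorized negative log-likelihood over the free-parameter vector.

    Precomputes the age grid, environmental covariates and interpolation
    abscissae once per (clade, template); each evaluation is then a handful
    of O(grid) array operations.
    """
    t1 = bt.crown_age
    events = bt.ages[1:]
    n = max(int(grid_points), 5)
    if n % 2 == 0:
        n += 1
    ts = np.linspace(0.0, t1, n)
    x_lam = _covariate(model.lambda_spec, ts)
    x_mu = _covariate(model.mu_spec, ts)
    x_lam_ev = _covariate(model.lambda_spec, events)
    lam_free = model.lambda_spec.form != "constant"
    mu_free = model.mu_spec.form != "constant"
    log_rho = np.log(rho)

    def unpack(x):
        log_l0, log_m0 = x[0], x[1]
        i = 2
        a = x[i] if lam_free else 0.0
        if lam_free:
            i += 1
        b = x[i] if mu_free else 0.0
        return log_l0, log_m0, a, b

    def loglik(x) -> float:
        log_l0, log_m0, a, b = unpack(x)
        with np.errstate(over="ignore", invalid="ignore"):
            lam = np.exp(log_l0 + a * x_lam)
            mu = np.exp(log_m0 + b * x_mu)
            R = cumulative_simpson(lam - mu, x=ts, initial=0.0)
            logLam = log_rho + (log_l0 + a * x_lam) + R
            Lam = np.exp(logLam)
            if not np.all(np.isfinite(Lam)):
                return -1e12  # finite penalty keeps numeric gradients usable
            Jint = cumulative_simpson(Lam, x=ts, initial=0.0)
            logJ = np.log1p(Jint)
            logLam_ev = log_rho + log_l0 + a * x_lam_ev + np.interp(events, ts, R)
            ll = float(
                np.sum(logLam_ev - 2.0 * np.interp(events, ts, logJ)) - 2.0 * logJ[-1]
            )
        return ll if np.isfinite(ll) else -1e12

    return loglik


def fit_model(
    bt: BranchingTimes,
    model_template: BDModel,
    rho: float,
    settings: FitSettings = FitSettings(),
    extra_starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one template, best of dispersed restarts.

    Deterministic for a fixed ``settings.seed``.  If no restart converges the
    best non-converged point is returned with ``converged=False`` — never an
    exception.
    """
    if len(bt.ages) < 3:
        import warnings

        warnings.warn("fewer than 3 branching events: fit will be weakly informed")
    params = _free_params(model_template)
    lo = np.array([p[1] for p in params])
    hi = np.array([p[2] for p in params])
    d = len(params)
    loglik = _make_objective(bt, model_template, rho, settings.grid_points)

    sampler = qmc.LatinHypercube(d=d, seed=settings.seed)
    unit = sampler.random(n=max(settings.n_restarts - 1, 1))
    # first start: a moment-based guess (Yule-like baseline, zero dependence)
    guess = np.zeros(d)
    lam_hat = max(np.log(max(bt.n_tips / (2.0 * rho), 1.1)) / bt.crown_age, 2e-6)
    guess[0] = np.log(min(max(lam_hat, BASELINE_BOUNDS[0] * 2), BASELINE_BOUNDS[1] / 2))
    guess[1] = guess[0] + np.log(0.3)
    starts = [guess] + [lo + u * (hi - lo) for u in unit[: settings.n_restarts - 1]]
    for xs in extra_starts or []:
        xs = np.clip(np.asarray(xs, dtype=float)[:d], lo, hi)
        if xs.size == d:
            starts.append(xs)

    best = None
    for idx, x0 in enumerate(starts):
        res = minimize(
            lambda x: -loglik(x),
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": settings.maxiter, "maxfun": 3 * settings.maxiter},
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res, idx)

    ll_best, res, idx = best
    x = res.x
    at_bound = np.any(
        (x - lo < settings.bound_tol * (hi - lo)) | (hi - x < settings.bound_tol * (hi - lo))
    )
    converged = bool(res.success) and np.isfinite(ll_best) and not at_bound

    log_l0, log_m0 = x[0], x[1]
    i = 2
    alpha = beta = 0.0
    if model_template.lambda_spec.form != "constant":
        alpha = float(x[i])
        i += 1
    if model_template.mu_spec.form != "constant":
        beta = float(x[i])
    fitted = BDModel(
        name=model_template.name,
        lambda_spec=model_template.lambda_spec.with_params(float(np.exp(log_l0)), alpha),
        mu_spec=model_template.mu_spec.with_params(float(np.exp(log_m0)), beta),
    )
    mle = {"lambda0": float(np.exp(log_l0)), "mu0": float(np.exp(log_m0))}
    if model_template.lambda_spec.form != "constant":
        mle["alpha"] = alpha
    if model_template.mu_spec.form != "constant":
        mle["beta"] = beta
    try:
        ic = aicc(ll_best, fitted.k, bt.n_tips)
    except ValueError as exc:
        ic = np.inf
        return FitResult(
            model_name=model_template.name,
            model=fitted,
            mle_params=mle,
            max_loglik=ll_best,
            k=fitted.k,
            aicc=ic,
            converged=False,
            n_restarts_used=len(starts),
            best_restart_seed=idx,
            crown_age=bt.crown_age,
            rho=rho,
            error=str(exc),
        )
    return FitResult(
        model_name=model_template.name,
        model=fitted,
        mle_params=mle,
        max_loglik=float(ll_best),
        k=fitted.k,
        aicc=float(ic),
        converged=converged,
        n_restarts_used=len(starts),
        best_restart_seed=idx,
        crown_age=bt.crown_age,
        rho=rho,
    )


def battery_templates(
    temperature: SmoothEnv | None = None,
    uplift: SmoothEnv | None = None,
    time_only: bool = False,
) -> list[BDModel]:
    """The model battery: constant, 3 time-dependent and, when curves are
    supplied, 3 temperature- and 3 uplift-dependent parameterizations."""

    def lam(form, env=None):
        return RateSpec("speciation", form, 0.1, 0.0, env)

    def mu(form, env=None):
        return RateSpec("extinction", form, 0.05, 0.0, env)

    models = [
        BDModel("constant", lam("constant"), mu("constant")),
        BDModel("time_lambda", lam("exp_time"), mu("constant")),
        BDModel("time_mu", lam("constant"), mu("exp_time")),
        BDModel("time_both", lam("exp_time"), mu("exp_time")),
    ]
    if not time_only:
        if temperature is not None:
            models += [
                BDModel("temp_lambda", lam("exp_env", temperature), mu("constant")),
                BDModel("temp_mu", lam("constant"), mu("exp_env", temperature)),
                BDModel("temp_both", lam("exp_env", temperature), mu("exp_env", temperature)),
            ]
        if uplift is not None:
            models += [
                BDModel("uplift_lambda", lam("exp_env", uplift), mu("constant")),
                BDModel("uplift_mu", lam("constant"), mu("exp_env", uplift)),
                BDModel("uplift_both", lam("exp_env", uplift), mu("exp_env", uplift)),
            ]
    return models


DRIVER_OF = {
    "constant": "constant",
    "time_lambda": "time",
    "time_mu": "time",
    "time_both": "time",
    "temp_lambda": "temperature",
    "temp_mu": "temperature",
    "temp_both": "temperature",
    "uplift_lambda": "uplift",
    "uplift_mu": "uplift",
    "uplift_both": "uplift",
}


@dataclass
class SelectionTable:
    """Fitted battery for one clade, ranked by AICc."""

    fits: dict[str, FitResult]
    delta_aicc: dict[str, float] = field(init=False)
    weights: dict[str, float] = field(init=False)
    best_model: str = field(init=False)
    second_best_model: str | None = field(init=False)

    def __post_init__(self):
        names = list(self.fits)
        a = np.array([self.fits[m].aicc for m in names])
        ks = np.array([self.fits[m].k for m in names])
        best_a = np.min(a[np.isfinite(a)])
        self.delta_aicc = {m: float(self.fits[m].aicc - best_a) for m in names}
        w = akaike_weights(a)
        self.weights = {m: float(wi) for m, wi in zip(names, w)}
        # strict min AICc; ties (< 1e-6) broken toward fewer parameters
        order = sorted(
            range(len(names)),
            key=lambda i: (round(a[i] / 1e-6) * 1e-6 if np.isfinite(a[i]) else np.inf, ks[i]),
        )
        self.best_model = names[order[0]]
        self.second_best_model = names[order[1]] if len(names) > 1 else None

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_model]

    @property
    def second_best(self) -> FitResult | None:
        return self.fits[self.second_best_model] if self.second_best_model else None

    def ranked(self) -> list[str]:
        return sorted(self.fits, key=lambda m: (self.fits[m].aicc, self.fits[m].k))

    def to_frame(self):
        import pandas as pd

        rows = []
        for m, f in self.fits.items():
            rows.append(
                {
                    "model": m,
                    "driver": DRIVER_OF.get(m, "other"),
                    "loglik": f.max_loglik,
                    "k": f.k,
                    "aicc": f.aicc,
                    "delta_aicc": self.delta_aicc[m],
                    "weight": self.weights[m],
                    "converged": f.converged,
                    **{f"param_{k}": v for k, v in f.mle_params.items()},
                }
            )
        return pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)


def run_battery(
    bt: BranchingTimes,
    rho: float,
    curves: dict[str, SmoothEnv] | None = None,
    settings: FitSettings = FitSettings(),
    time_only: bool = False,
) -> SelectionTable:
    """Fit the whole battery for one clade.  Per-model failures are captured
    in the table (infinite AICc) so the battery always completes."""
    curves = curves or {}
    templates = battery_templates(
        temperature=curves.get("temperature"), uplift=curves.get("uplift"),
        time_only=time_only,
    )
    fits: dict[str, FitResult] = {}
    nested_start: list[np.ndarray] = []
    for tm in templates:
        try:
            fits[tm.name] = fit_model(bt, tm, rho, settings, extra_starts=nested_start)
            if tm.name == "constant" and fits["constant"].mle_params:
                # seed every nested model at the constant optimum (alpha=beta=0)
                # so richer families can only improve on it
                p = fits["constant"].mle_params
                nested_start = [
                    np.array([np.log(p["lambda0"]), np.log(p["mu0"]), 0.0, 0.0])
                ]
        except Exception as exc:  # capture, never abort the battery
            fits[tm.name] = FitResult(
                model_name=tm.name,
                model=tm,
                mle_params={},
                max_loglik=-np.inf,
                k=tm.k,
                aicc=np.inf,
                converged=False,
                n_restarts_used=0,
                best_restart_seed=-1,
                crown_age=bt.crown_age,
                rho=rho,
                error=str(exc),
            )
    return SelectionTable(fits=fits)
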