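"""End-to-end drivers tying the stages together for one study.

Each function takes explicit inputs and returns plain DataFrames/objects so
the numbered analysis scripts, the CLI and the acceptance script all share
the same computation path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .battery import FitSettings, run_battery, DRIVER_OF
from .bioregions import AbundanceMatrix, assign_clades, cluster_regions
from .env import SmoothEnv
from .pulled import PulledSettings, fit_pulled, select_pulled_model
from .scenarios import classify_scenario
from .simulate import SimStudy
from .trees import branching_times

__all__ = ["fit_study_battery", "fit_study_pulled", "bioregionalize_study"]


def fit_study_battery(
    study: SimStudy,
    curves: dict[str, SmoothEnv] | None,
    settings: FitSettings = FitSettings(),
    time_only: bool = False,
) -> tuple[dict, pd.DataFrame]:
    """Fit the model battery for every clade; returns the per-clade
    SelectionTables and a tidy summary frame with the scenario calls."""
    tables, rows = {}, []
    basis = "time_only_comparison" if time_only or not curves else "environmental_comparison"
    for rec in study.records:
        bt = branching_times(study.trees[rec.clade_id])
        table = run_battery(bt, rec.sampling_fraction, curves, settings, time_only=time_only)
        tables[rec.clade_id] = table
        call = classify_scenario(table.best, basis=basis)
        const = table.fits.get("constant")
        rows.append(
            {
                "clade_id": rec.clade_id,
                "best_model": table.best_model,
                "driver": DRIVER_OF.get(table.best_model, "other"),
                "scenario": call.scenario,
                "speciation_trend": call.speciation_trend,
                "r_present": call.r_present,
                "lambda0_const": const.mle_params.get("lambda0", np.nan),
                "r_const": const.mle_params.get("lambda0", np.nan)
                - const.mle_params.get("mu0", np.nan),
                "aicc_best": table.best.aicc,
                "converged": table.best.converged,
            }
        )
    return tables, pd.DataFrame(rows).set_index("clade_id")


def fit_study_pulled(
    study: SimStudy,
    settings: PulledSettings = PulledSettings(),
) -> tuple[dict, pd.DataFrame]:
    """Constant vs 3-interval pulled fits per clade, AIC-selected."""
    fits, rows = {}, []
    for rec in study.records:
        bt = branching_times(study.trees[rec.clade_id])
        one = fit_pulled(bt, rec.sampling_fraction, 1, settings)
        three = (
            fit_pulled(bt, rec.sampling_fraction, 3, settings)
            if one.flag != "never_exceeds_min_lineages"
            else None
        )
        sel = select_pulled_model({1: one, 3: three})
        fits[rec.clade_id] = sel
        rows.append(
            {
                "clade_id": rec.clade_id,
                "n_intervals": sel.n_intervals,
                "trend": sel.trend.trend,
                "mu_p_present": sel.trend.mu_p_present,
                "rp_present": float(sel.model.rp(0.0)),
                "rho_lambda0": sel.model.rho_lambda0,
                "aic": sel.aic,
                "flag": sel.flag,
            }
        )
    return fits, pd.DataFrame(rows).set_index("clade_id")


def bioregionalize_study(
    study: SimStudy, seed: int = 0, n_init: int = 100
) -> tuple[object, dict]:
    """Cluster the study's abundance matrix and assign clades to clusters."""
    m: AbundanceMatrix = study.abundance
    clustering = cluster_regions(m, n_init=n_init, seed=seed)
    assignment = assign_clades(m, clustering)
    return clustering, assignment.cluster
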