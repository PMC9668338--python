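# neodiv

Clade-level analysis of Neotropical diversification: which trajectories of
species-richness accumulation — gradual expansion, exponential expansion,
saturation, or waxing-and-waning decline — explain today's diversity, what
drives them, and whether they are structured by geography or taxonomy.

The package is written for comparative macroevolution work in which the unit
of analysis is a time-calibrated clade (its reconstructed phylogeny, its
described richness and sampling fraction, its regional species counts), and
the questions are answered by fitting birth-death models with time- and
paleoenvironment-dependent rates, cross-checking trends with identifiable
pulled rates, clustering regions into macroevolutionary bioregions, and
comparing trajectories across groups with contingency, rank and
phylogenetic-signal statistics.  A forward birth-death simulator generates
whole synthetic studies with the structure of a continental compilation
(150 clades, five taxon groups, tree sizes 7–789), so the entire pipeline is
testable end to end without any external data.

## The models

With `t` in Myr before present, speciation and extinction follow
`λ(t) = λ₀e^{αt}` and `μ(t) = μ₀e^{βt}` (α, β > 0 ⇒ rates higher in the
past), or `λ(t) = λ₀e^{αE(t)}` for an environmental covariate `E` (global
temperature, Andean paleo-elevation).  For branching times
`t₁ > t₂ ≥ … ≥ t_{n−1}` and sampling fraction ρ, writing `r = λ − μ`,
`Λ(t) = ρλ(t)e^{∫₀ᵗ r}` and `J(t) = 1 + ∫₀ᵗ Λ`, the crown-conditioned
log-likelihood is

    log L = Σ_{i≥2} [log Λ(tᵢ) − 2 log J(tᵢ)] − 2 log J(t₁)

so the data constrain exactly the congruence class `(r_p, ρλ₀)` with
`r_p = d log Λ / dt` — which is what the pulled-rate module fits directly on
an age grid.  Ten models per clade are ranked by AICc; the winner's realized
`r(t)` trajectory maps the clade onto scenarios Sc1–Sc4; a negative
present-day pulled extinction rate `μ_p(0) = λ₀ − r_p(0) < 0` independently
diagnoses decreasing speciation.  Details, defaults and limitations:
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from neodiv.bd import RateSpec
from neodiv.simulate import simulate_tree
from neodiv.trees import branching_times
from neodiv.battery import run_battery, FitSettings
from neodiv.scenarios import classify_scenario

# a clade whose speciation decayed toward the present (a saturating regime)
tree = simulate_tree(
    RateSpec("speciation", "exp_time", 0.1, 0.08),
    RateSpec("extinction", "constant", 0.05),
    crown_age=20.0, rho=1.0, seed=300, size_window=(60, 400),
)
bt = branching_times(tree)
table = run_battery(bt, rho=1.0, curves=None,
                    settings=FitSettings(n_restarts=4, seed=1), time_only=True)
best = table.best
call = classify_scenario(best)
print(tree.n_tips, best.model_name, {k: round(v, 3) for k, v in best.mle_params.items()})
print(call.scenario, "r(0) =", round(call.r_present, 3))
```

prints

```
137 time_lambda {'lambda0': 0.092, 'mu0': 0.054, 'alpha': 0.094}
Sc3_saturated r(0) = 0.038
```

— the battery recovers the generating family (λ exponential in time, fitted
λ₀ ≈ 0.09 and α ≈ 0.09 against truths 0.10 and 0.08), and the positive
present-day net rate with rates higher in the past classifies the clade as a
saturated expansion (Sc3).

The numbered scripts under `analysis/` run the same machinery at study
scale: `01_simulate_study.py` draws the 150-clade synthetic study,
`02_fit_battery.py` fits the 10-model battery and scores scenario recovery,
`03_pulled_rates.py` adds the pulled cross-check, `04_bioregions.py`
clusters the 13 regions (the elbow finds the five planted blocks),
`05_comparative_tests.py` runs the Fisher / Kruskal-Wallis /
phylogenetic-signal battery, and `06_report.py` writes the summary tables
with their sensitivity filters.  Outputs land in `results/`.

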