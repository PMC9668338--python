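# Methods

`neodiv` implements a clade-level comparative analysis of diversification:
fit a battery of birth-death models to each time-calibrated phylogeny,
classify the implied diversity trajectory, cross-check the trend with
identifiable pulled rates, derive biogeographic units from clade-abundance
data, and compare trajectories across taxa, regions and elevations.  This
note records the models, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Time convention

Everywhere, `t` is measured in Myr before present: `t = 0` is today and `t`
increases into the past.  A positive time-dependence (`alpha > 0` for
speciation, `beta > 0` for extinction) therefore means rates were *higher in
the past*, i.e. decreasing toward the present.

## Birth-death likelihood

Rates take three parametric forms per role (speciation λ, extinction μ):
constant, exponential in time `λ(t) = λ0 e^{αt}`, and exponential in an
environmental covariate `λ(t) = λ0 e^{α E(t)}`, where `E` is a smoothed
paleoenvironmental curve (global temperature in °C or Andean paleo-elevation
in m) and `λ0` is the rate at covariate value 0 (0 °C, 0 m).  Units are
events · lineage⁻¹ · Myr⁻¹.

For a reconstructed crown tree with branching times `t1 > t2 ≥ … ≥ t_{n−1}`
and uniform species-sampling fraction ρ, write `r = λ − μ`,
`R(t) = ∫₀ᵗ r`, `Λ(t) = ρ λ(t) e^{R(t)}` and `J(t) = 1 + ∫₀ᵗ Λ`.
Conditioned on the crown age and on both crown lineages leaving sampled
descendants, the log-likelihood is

    log L = Σ_{i≥2} [ log Λ(t_i) − 2 log J(t_i) ] − 2 log J(t1).

Two useful consequences follow directly from this form:

* the data enter only through `Λ(t)` — equivalently through the pulled
  diversification rate `r_p(t) = d/dt log Λ(t)` and the product
  `ρλ0 = Λ(0)` — so the likelihood is constant on a birth-death congruence
  class, and the pulled-rate module can reuse the same code path;
* with constant rates it reduces to the classic closed form, and with
  `μ ≡ 0, ρ = 1` to the Yule likelihood.  Both reductions are enforced by
  tests against independently coded oracles (1e-8 / 1e-10), and the
  time-varying density is checked against a Monte-Carlo branching-time
  histogram from the forward simulator.

Conditioning is exposed as an enum (`crown_survival`, default, or `crown`
without the survival factor).  Integrals use composite Simpson accumulation
on a uniform grid over the crown span — 4001 points for direct likelihood
calls, 2001 inside optimizations — with values at branching times obtained
by interpolating the cumulative integrals; this reproduces closed forms to
~1e-12 and keeps one likelihood evaluation under a millisecond.  Parameter
regions that overflow `exp(R)` return −∞ to the optimizer rather than
raising.

## Model battery and selection

Ten models per clade: constant; λ and/or μ exponential in time; λ and/or μ
exponential in temperature; λ and/or μ exponential in paleo-elevation
(k = 2, 3, 3, 4, 3, 3, 4, 3, 3, 4 free parameters).  Fitting is L-BFGS-B on
(log λ0, log μ0, α, β) with bounds λ0, μ0 ∈ [1e-6, 10], time dependences
∈ [−0.5, 0.5] Myr⁻¹, and environmental dependences bounded so the rate can
change by at most e^±5 over the observed covariate range.  Each model starts
from a moment-based guess (Yule-like λ0, turnover 0.3) plus Latin-hypercube
dispersed restarts (default 10; the heavier simulation studies use 4, which
recovery tests show is sufficient at these tree sizes); after the constant
model is fitted, every richer model also starts from the constant optimum
with α = β = 0, which guarantees the nested-likelihood inequality in
practice.  A fit that ends on a bound or fails the optimizer's own test is
flagged `converged = False` but still reported.

Selection is by AICc with `n` = number of tips (the conventional
sample-size proxy; logged in results).  Ties below 1e-6 go to the model with
fewer parameters.  Akaike weights are reported alongside ΔAICc, and the
second-ranked model is kept for the driver-robustness tally.

## Scenario classification

A constant-rate winner is Sc1 (gradual expansion).  For any other winner the
realized net rate `r(t)` is evaluated on a 100-point grid over the clade's
crown span and summarized by the sign of its least-squares slope against age
(flatness threshold `1e-4 × mean |r|`): slope ≈ 0 → Sc1; rates rising toward
the present → Sc2 (exponential expansion); falling with `r(0) ≥ 0` → Sc3
(saturated expansion); falling with `r(0) < 0` → Sc4 (waxing and waning).
The grid-slope rule was chosen over endpoint comparison so that
environment-composed, possibly non-monotone trajectories receive a
principled overall trend; for single-exponential models it provably agrees
with the sign of α (or −β), which a 10,000-draw randomized test enforces.
Speciation trends (constant / increasing / decreasing) come from the fitted
λ-component alone under the same convention.

## Pulled rates

The pulled model is `r_p(t)` piecewise-linear between knots plus `ρλ0`,
fitted by maximum likelihood on the age window where the reconstructed tree
carries more than 10 lineages (gridded estimates near the root are noisy;
clades that never exceed 10 lineages are flagged and fitted with the
constant model on the full span).  Knots for the 3-interval grid sit at
fractions {0, 0.15, 0.40, 1} of the truncation age — denser near the
present, where the information is, with the exact fractions a fixed package
choice — and `r_p` is extrapolated as constant beyond the oldest knot.  The
constant (one-interval) model is a single free `r_p` value on the same
window, so the two AICs (plain AIC, `k` = free values + 1: 2 vs 5) compare
likelihoods of the same data; 20 independent restarts per fit.  From the
known ρ, `λ0 = ρλ0/ρ` and the pulled extinction `μ_p(t) = λ0 − r_p(t)`
follow.  Diagnosis: a constant winner indicates constant or slowly varying
rates; a time-variable winner with `μ_p(0) < 0` indicates decreasing
speciation; `μ_p(0) ≥ 0` is ambiguous and labelled "unknown".  No attempt is
made to recover canonical `λ(t), μ(t)` from pulled fits.

## Environmental curves

Curves arrive as (age, value) tables, are sorted with duplicate ages
averaged, and are smoothed by a cubic smoothing spline whose penalty is
bisected to a target effective degrees of freedom (trace of the hat matrix);
df = 2 is the least-squares line, df = n interpolates.  The default
df = min(n, 50) is logged with each run so curve-sensitivity reruns are
reproducible.  Evaluation outside the sampled age range is clamped to the
boundary value — no extrapolated trends — and clades older than a curve see
that boundary value, which is the conservative reading for deep-time tails.
Synthetic curve kinds (cooling ramp, step, seeded noisy trend) stand in for
published paleotemperature/uplift series in tests.

## Bioregionalization

Clade × region species counts over the 13 Neotropical operational areas are
Hellinger-transformed per clade row, Morisita-Horn dissimilarities are
computed between region columns, the dissimilarity matrix is embedded by
classical (Torgerson) MDS keeping positive-eigenvalue axes covering ≥95% of
positive variance, and K-means (seeded, 100 restarts by default) is run for
k = 1…12 with the elbow taken at the maximal second difference of the
within-cluster sum of squares (ties to the smaller k).  Whether the
dissimilarity should be computed on transformed or raw counts is genuinely
open; the transformed composition is the default and a flag switches to raw
counts.  Clades are assigned to a cluster only when strictly more than 60%
of their species fall in it (ties and exact 60% are "mixed").

## Comparative statistics

Fisher's exact test is exact (hypergeometric enumeration) for 2×2 tables and
margin-fixed Monte-Carlo (Patefield sampling, default 1e5 draws, seeded,
with the +1 correction) for larger tables — adequate at these table sizes
and fully reproducible.  Pairwise contingency comparisons use
Benjamini-Hochberg adjustment; post-hoc ANOVA contrasts use Holm.
Kruskal-Wallis is tie-corrected with a χ² reference.  Blomberg's K follows
the MSE-ratio definition with a tip-permutation significance test.  The
δ statistic for categorical traits aggregates node entropies of marginal
ancestral-state reconstructions under an ML-fitted equal-rates Markov model;
the original formulation samples these probabilities by MCMC, so this ML
variant is an approximation, but its randomization null (trait shuffled
across tips) is preserved and is what the p-value rests on.  The
phylogenetic ANOVA refers the ordinary F statistic to a null distribution of
F values from Brownian simulations on the tree with σ² estimated by
phylogenetic GLS.  Plain (non-phylogenetic) tests are used elsewhere, the
appropriate choice once traits show no phylogenetic signal.  Continuous rate
summaries entering group comparisons are taken from the constant-rate fit,
since time-varying curves are not summarized by one number.

## Synthetic studies

The default generator draws 150 clades in the five-group composition
66 plants / 12 mammals / 32 birds / 24 squamates / 16 amphibians, with
scenario mixture (0.507, 0.200, 0.207, 0.087) for Sc1–Sc4, crown ages
lognormal (median 26 Myr, σ = 0.8, clipped to 1–88.5), sampled tree sizes
lognormal (median 40, σ = 1, clipped to 7–789), and sampling fractions Beta
(mean 0.57).  Per scenario, `λ0` is solved from the net-rate integral
`R(T) = log(target richness / 2)` with turnover drawn uniform in
[0.1, 0.6]; Sc2 draws α ∈ [−0.1, −0.02], Sc3 α ∈ [0.03, 0.12], and Sc4
draws `μ0 > λ0` with αT ∈ [1.3, 2.5] so that diversity first waxes then
wanes with `r(0) < 0`.  Trees are simulated forward from the two crown
lineages by thinning against the rate envelope, pruned to sampled survivors
(each extant tip kept with probability ρ), and rejection-conditioned on both
crown lineages surviving — matching the likelihood's conditioning — and on
the realized size landing within a factor 3 of its target, which emulates a
curated compilation's size distribution and keeps study-level means stable.
Realized summary statistics land within a few percent of the emulation
targets (mean size ≈ 83, mean age ≈ 30 Myr, mean ρ ≈ 0.57).  Each clade uses
an RNG substream derived from (master seed, clade index), so studies are
byte-reproducible and individual clades can be regenerated.

What the generator does *not* emulate: among-lineage rate heterogeneity
within a clade, non-uniform (clumped) taxon sampling, divergence-time
estimation error, and abundance matrices beyond planted block structure.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated generating assumptions, not robustness to these real-data
complications.

## Problem sizes in the shipped tests

The test-suite and acceptance-script simulation sizes are fixed package
choices balancing statistical resolution against a single-CPU run: 32
constant-rate trees (100–300 tips) for parameter recovery and AICc family
ranking; 12,000 accepted 3-tip replicates for the Monte-Carlo density
oracle; 20 trees × 5 model pairs for congruence invariance (tolerance 1e-6);
12 large-tree (450–789 tip) replicates for the pulled decreasing-speciation
diagnosis — the present-day knot of a gridded pulled fit has a standard
error of several tenths on trees of a few hundred tips, so its sign is only
diagnostic in the large-clade regime; 100 seeded runs
for planted-bioregion recovery; 1,000 null replicates for test calibration.
Thresholds (15% recovery error, 70% family ranking, 90/100 block recovery,
3 binomial SE around the 5% level) are the acceptance contract and are not
adjusted per run.

## Known limitations

* Environmental dependences are exponential only; no linear or spline rate
  maps, no diversity-dependence, no fossil information.
* ρ is uniform per clade; clumped sampling biases branching-time densities
  in ways the likelihood cannot absorb.
* The δ statistic's ML shortcut can differ from the MCMC original when
  ancestral reconstructions are strongly multimodal.
* The elbow rule needs at least three candidate k and can be indecisive on
  WSS curves without curvature; the full curve is always reported so a
  caller can overrule.
* Monte-Carlo Fisher p-values have resolution 1/(n_draws + 1); raise
  `n_draws` for very small p.
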