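"""Forward birth-death simulation and whole synthetic "studies".

The generator emulates the statistical structure of a continental clade
compilation: 150 clades in five taxon groups (66 plants, 12 mammals,
32 birds, 24 squamates, 16 amphibians), crown ages of 0.5-88.5 Myr averaging
~30, tree sizes of 7-789 tips averaging ~83, sampling fractions averaging
~57%, and per-clade generating regimes drawn from the four diversity-
trajectory scenarios (constant rates; speciation rising toward the present;
speciation falling with non-negative present-day net rate; speciation
falling with negative present-day net rate).

Trees are simulated forward in time from the two crown lineages with an
inhomogeneous thinning algorithm, extinct lineages pruned, extant species
retained independently with probability rho, and the whole replicate
rejected unless both crown lineages leave at least one sampled descendant
(matching the likelihood's crown-survival conditioning).  Every clade's true
generating parameters are stored so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bd import BDModel, RateSpec, rate_at
from .trees import UltrametricTree, CladeRecord, parse_newick, REGIONS

__all__ = [
    "SimConfig",
    "SimStudy",
    "SimulationError",
    "simulate_tree",
    "simulate_study",
    "simulate_abundance",
    "score_recovery",
]

GROUP_COUNTS_150 = {"plant": 66, "mammal": 12, "bird": 32, "squamate": 24, "amphibian": 16}
SCENARIO_MIX = {  # mixture over generating regimes
    "Sc1_gradual": 76 / 150,
    "Sc2_exponential": 30 / 150,
    "Sc3_saturated": 31 / 150,
    "Sc4_waxing_waning": 13 / 150,
}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-level generating conditions (the defaults are the conditions)."""

    n_clades: int = 150
    group_counts: dict = field(default_factory=lambda: dict(GROUP_COUNTS_150))
    scenario_mix: dict = field(default_factory=lambda: dict(SCENARIO_MIX))
    # crown ages: lognormal, median 26 Myr, clipped to the observed span
    age_median: float = 26.0
    age_sigma: float = 0.8
    age_range: tuple = (1.0, 88.5)
    # sampled tree sizes: lognormal, median 40, clipped to the observed span
    size_median: float = 40.0
    size_sigma: float = 1.0
    size_range: tuple = (7, 789)
    # sampling fraction: Beta with mean 0.57
    rho_a: float = 2.85
    rho_b: float = 2.15
    rho_min: float = 0.08
    turnover_range: tuple = (0.1, 0.6)
    k_regions_true: int = 5
    abundance_mixing_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.scenario_mix.values()) - 1.0) > 1e-9:
            raise ValueError("scenario mixture must sum to 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class SimStudy:
    config: SimConfig
    records: list[CladeRecord]
    trees: dict[str, UltrametricTree]
    truths: pd.DataFrame  # per-clade generating scenario and parameters
    abundance: "object"  # AbundanceMatrix


class _Lineage:
    __slots__ = ("parent", "birth_age", "death_age", "children", "sampled")

    def __init__(self, parent, birth_age):
        self.parent = parent
        self.birth_age = birth_age  # Myr before present at which it appears
        self.death_age = None
        self.children = None
        self.sampled = False


def _simulate_once(model: BDModel, crown_age: float, rho: float, rng) -> list[_Lineage] | None:
    """One forward pass; returns the crown lineages or None if everything
    went extinct before the present."""
    ts = np.linspace(0.0, crown_age, 257)
    lam_max = float(np.max(model.speciation(ts)))
    mu_max = float(np.max(model.extinction(ts)))
    c = lam_max + mu_max
    if c <= 0:
        raise SimulationError("zero total rate everywhere")
    root_kids = [_Lineage(None, crown_age), _Lineage(None, crown_age)]
    alive = list(root_kids)
    t = crown_age  # sweep from the crown toward the present
    while alive and t > 0:
        total = c * len(alive)
        t -= rng.exponential(1.0 / total)
        if t <= 0:
            break
        lam_t = float(rate_at(model.lambda_spec, t))
        mu_t = float(rate_at(model.mu_spec, t))
        if rng.random() * c >= lam_t + mu_t:
            continue  # thinned proposal
        j = int(rng.integers(len(alive)))
        lineage = alive[j]
        alive[j] = alive[-1]
        alive.pop()
        lineage.death_age = t
        if rng.random() * (lam_t + mu_t) < lam_t:
            kids = [_Lineage(lineage, t), _Lineage(lineage, t)]
            lineage.children = kids
            alive.extend(kids)
    for ln in alive:
        ln.sampled = rng.random() < rho
    return root_kids


def _prune(ln: _Lineage):
    """Reconstructed subtree of a lineage: (list of tip placeholders, newick
    fragment, age of fragment root) or None if no sampled descendant."""
    if ln.children is None:
        return (1, None, 0.0) if ln.sampled else None
    left = _prune(ln.children[0])
    right = _prune(ln.children[1])
    split = ln.death_age
    if left and right:
        return (left[0] + right[0], (left, right, split), split)
    return left or right


_counter = [0]


def _to_newick(node, parent_age) -> str:
    n, inner, age = node
    if inner is None:
        _counter[0] += 1
        return f"t{_counter[0]}:{parent_age - 0.0:.10g}"
    left, right, split = inner
    return f"({_to_newick(left, split)},{_to_newick(right, split)}):{parent_age - split:.10g}"


def simulate_tree(
    lambda_spec: RateSpec,
    mu_spec: RateSpec,
    crown_age: float,
    rho: float = 1.0,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 100_000,
    size_window: tuple | None = None,
) -> UltrametricTree:
    """Simulate a reconstructed, rho-sampled crown tree of age ``crown_age``.

    Rejection-conditioned on both crown lineages leaving at least one sampled
    descendant; optionally also on the sampled tip count falling inside
    ``size_window``.  Deterministic for a fixed integer seed.
    """
    model = BDModel("sim", lambda_spec, mu_spec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_attempts):
        crown = _simulate_once(model, crown_age, rho, rng)
        left = _prune(crown[0])
        right = _prune(crown[1])
        if not (left and right):
            continue
        n_tips = left[0] + right[0]
        if size_window and not (size_window[0] <= n_tips <= size_window[1]):
            continue
        _counter[0] = 0
        nwk = f"({_to_newick(left, crown_age)},{_to_newick(right, crown_age)});"
        return parse_newick(nwk)
    raise SimulationError(
        f"no acceptable tree in {max_attempts} attempts; adjust parameters"
    )


def _scenario_params(scenario: str, crown_age: float, target_pre_sampling: float, rng):
    """Rate parameters realizing a scenario with expected pre-sampling
    richness ~ target: solve lambda0 from the net-rate integral
    R(T) = log(target / 2)."""
    R_target = np.log(max(target_pre_sampling, 3.0) / 2.0)
    T = crown_age
    eps = rng.uniform(0.1, 0.6)  # turnover mu0 / lambda0
    if scenario == "Sc1_gradual":
        alpha = 0.0
        lam0 = R_target / (T * (1 - eps))
        mu0 = eps * lam0
    elif scenario == "Sc2_exponential":
        alpha = rng.uniform(-0.1, -0.02)
        shape = np.expm1(alpha * T) / alpha
        eps = min(eps, 0.8 * shape / T)
        lam0 = R_target / (shape - eps * T)
        mu0 = eps * lam0
    elif scenario == "Sc3_saturated":
        alpha = rng.uniform(0.03, 0.12)
        shape = np.expm1(alpha * T) / alpha
        lam0 = R_target / (shape - eps * T)
        mu0 = eps * lam0
    elif scenario == "Sc4_waxing_waning":
        c = rng.uniform(1.05, 1.5)
        alpha = rng.uniform(1.3, 2.5) / T
        shape = np.expm1(alpha * T) / alpha
        if shape <= c * T:
            alpha = 2.8 / T
            shape = np.expm1(alpha * T) / alpha
        lam0 = R_target / (shape - c * T)
        mu0 = c * lam0
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    if lam0 <= 0:
        raise SimulationError(f"infeasible scenario parameters for {scenario}")
    return float(lam0), float(mu0), float(alpha)


def simulate_study(config: SimConfig = SimConfig()) -> SimStudy:
    """Generate a complete synthetic study (trees + metadata + truths +
    abundance matrix).  Byte-identical for a fixed config/seed: each clade
    draws from its own RNG substream (master seed + clade index)."""
    from .bioregions import AbundanceMatrix

    counts = {g: c for g, c in config.group_counts.items()}
    if sum(counts.values()) != config.n_clades:
        # scale group proportions to n_clades
        props = np.array(list(config.group_counts.values()), dtype=float)
        props /= props.sum()
        scaled = np.floor(props * config.n_clades).astype(int)
        while scaled.sum() < config.n_clades:
            scaled[int(np.argmax(props * config.n_clades - scaled))] += 1
        counts = dict(zip(config.group_counts, scaled))
    # interleave groups proportionally so any prefix of clades is a
    # representative cross-section of the study
    placed = [
        ((i + 0.5) / c, g) for g, c in counts.items() if c > 0 for i in range(c)
    ]
    groups = [g for _, g in sorted(placed, key=lambda x: x[0])]
    scen_names = list(config.scenario_mix)
    scen_p = np.array([config.scenario_mix[s] for s in scen_names])

    records, trees, rows = [], {}, []
    for i in range(config.n_clades):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(i,)))
        scenario = scen_names[rng.choice(len(scen_names), p=scen_p)]
        for attempt in range(60):
            T = float(np.clip(
                np.exp(np.log(config.age_median) + config.age_sigma * rng.standard_normal()),
                *config.age_range,
            ))
            n_target = float(np.clip(
                np.exp(np.log(config.size_median) + config.size_sigma * rng.standard_normal()),
                *config.size_range,
            ))
            rho = float(np.clip(rng.beta(config.rho_a, config.rho_b), config.rho_min, 1.0))
            try:
                lam0, mu0, alpha = _scenario_params(scenario, T, n_target / rho, rng)
                if lam0 > 8.0:  # implausibly fast: resample sizes
                    continue
                window = (max(7, int(n_target / 3)), min(max(int(n_target * 3), 21), 789))
                ut = simulate_tree(
                    RateSpec("speciation", "exp_time" if alpha else "constant", lam0, alpha),
                    RateSpec("extinction", "constant", mu0),
                    T, rho, seed=rng, max_attempts=400, size_window=window,
                )
                break
            except SimulationError:
                continue
        else:
            raise SimulationError(f"clade {i}: no feasible draw for {scenario}")
        clade_id = f"clade{i:03d}"
        n_sampled = ut.n_tips
        n_described = max(n_sampled, int(round(n_sampled / rho)))
        records.append(
            CladeRecord(
                clade_id=clade_id,
                taxon_group=groups[i],
                n_sampled=n_sampled,
                n_described=n_described,
                elevation_class=["lowland", "montane", "highland", "mixed"][
                    rng.choice(4, p=[0.28, 0.05, 0.04, 0.63])
                ],
            )
        )
        trees[clade_id] = ut
        rows.append(
            {
                "clade_id": clade_id,
                "scenario_true": scenario,
                "taxon_group": groups[i],
                "lambda0_true": lam0,
                "mu0_true": mu0,
                "alpha_true": alpha,
                "crown_age": ut.crown_age,
                "n_tips": n_sampled,
                "rho": rho,
            }
        )
    truths = pd.DataFrame(rows).set_index("clade_id")
    ab_rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(10_000,)))
    abundance = simulate_abundance(
        n_clades=config.n_clades,
        k_true=config.k_regions_true,
        mixing_noise=config.abundance_mixing_noise,
        seed=ab_rng,
        clade_ids=[r.clade_id for r in records],
        totals=[r.n_described for r in records],
    )
    for rec in records:
        rec.region_counts = abundance.counts.loc[rec.clade_id].to_dict()
    return SimStudy(config=config, records=records, trees=trees, truths=truths,
                    abundance=abundance)


def simulate_abundance(
    n_clades: int,
    n_regions: int = 13,
    k_true: int = 5,
    mixing_noise: float = 0.05,
    seed: int | np.random.Generator = 0,
    clade_ids: list[str] | None = None,
    totals: list[int] | None = None,
):
    """Clade x region counts with planted block structure: the regions are
    partitioned into ``k_true`` blocks and each clade concentrates
    ``1 - mixing_noise`` of its species in its home block."""
    from .bioregions import AbundanceMatrix

    if k_true > n_regions:
        raise ValueError("k_true must be <= n_regions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    regions = list(REGIONS)[:n_regions] if n_regions <= len(REGIONS) else [
        f"region{j}" for j in range(n_regions)
    ]
    blocks = np.array_split(np.arange(n_regions), k_true)
    clade_ids = clade_ids or [f"clade{i:03d}" for i in range(n_clades)]
    rows = np.zeros((n_clades, n_regions), dtype=int)
    for i in range(n_clades):
        home = rng.integers(k_true)
        total = int(totals[i]) if totals is not None else int(rng.integers(8, 400))
        w = np.full(n_regions, 0.0)
        w[blocks[home]] = (1 - mixing_noise) / len(blocks[home])
        others = np.setdiff1d(np.arange(n_regions), blocks[home])
        if others.size and mixing_noise > 0:
            w[others] = mixing_noise / others.size
        w /= w.sum()
        rows[i] = rng.multinomial(total, w)
    return AbundanceMatrix(counts=pd.DataFrame(rows, index=clade_ids, columns=regions))


def score_recovery(study: SimStudy, calls: dict[str, object]) -> dict:
    """Confusion matrix of true vs called scenarios plus relative parameter
    errors for clades whose winner shares the generating family."""
    from .scenarios import SCENARIOS

    conf = pd.DataFrame(0, index=list(SCENARIOS), columns=list(SCENARIOS))
    for cid, call in calls.items():
        conf.loc[study.truths.loc[cid, "scenario_true"], call.scenario] += 1
    return {"confusion": conf}
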