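"""Cross-tabulation and phylogenetic-signal statistics for clade-level
comparisons (trajectories vs taxa / regions / elevations / drivers).

Contents: Fisher's exact test (2x2 exact; r x c by seeded margin-fixed Monte
Carlo), pairwise Fisher with Benjamini-Hochberg correction, tie-corrected
Kruskal-Wallis, Blomberg's K with a tip-shuffle permutation test, an
entropy-based delta statistic for categorical traits with a randomization
null, and a phylogenetic ANOVA whose null F distribution comes from Brownian
simulation on the tree.

All resampling tests are deterministic for a fixed seed.  Phylogenetic
corrections are applied only in the phylogenetic ANOVA; contingency and
rank tests are run plain, as appropriate once traits show no phylogenetic
signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .trees import UltrametricTree

__all__ = [
    "ContingencyTable",
    "TestResult",
    "fisher_exact",
    "pairwise_fisher",
    "kruskal_wallis",
    "phylo_vcv",
    "blomberg_K",
    "delta_stat",
    "phylo_anova",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts with row/column labels; at least 2x2, non-negative integers."""

    counts: pd.DataFrame

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("need at least a 2x2 table")
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_labels(cls, rows, cols) -> "ContingencyTable":
        return cls(pd.crosstab(pd.Series(rows), pd.Series(cols)))


@dataclass
class TestResult:
    method: str
    statistic: float | None
    df: int | None
    p: float
    seed: int | None = None
    n_draws: int | None = None
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)


def _log_table_prob(t: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a table given margins."""
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(n + 1)
        - gammaln(t + 1).sum()
    )


def fisher_exact(
    t: ContingencyTable,
    n_draws: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Fisher's exact test of independence.

    2x2 tables: the exact two-sided p (sum over margin-fixed tables with
    probability <= that of the observed one).  Larger tables: a Monte-Carlo
    p over ``n_draws`` tables sampled with fixed margins (Patefield), seeded,
    with the +1/(N+1) correction.  A zero margin makes the table degenerate:
    p = 1, flagged.
    """
    arr = t.counts.to_numpy(dtype=int)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        return TestResult("fisher_exact", None, None, 1.0, extra={"degenerate": True})
    if arr.shape == (2, 2):
        _, p = sps.fisher_exact(arr, alternative="two-sided")
        return TestResult("fisher_exact", None, None, float(p))
    rng = np.random.default_rng(seed)
    dist = sps.random_table(arr.sum(axis=1), arr.sum(axis=0))
    obs = _log_table_prob(arr)
    draws = dist.rvs(n_draws, method="patefield", random_state=rng)
    lp = np.array([_log_table_prob(d) for d in draws])
    hits = int(np.sum(lp <= obs + 1e-9))
    p = (hits + 1) / (n_draws + 1)
    return TestResult("fisher_exact_mc", None, None, float(p), seed=seed, n_draws=n_draws)


def pairwise_fisher(
    t: ContingencyTable,
    margin: str = "columns",
    correction: str = "fdr_bh",
    n_draws: int = 100_000,
    seed: int = 0,
) -> list[TestResult]:
    """All pairwise Fisher tests along one margin, Benjamini-Hochberg
    adjusted.  With only two groups the single test is returned unadjusted."""
    df = t.counts if margin == "columns" else t.counts.T
    groups = list(df.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    pairs = list(itertools.combinations(groups, 2))
    results = []
    for i, (a, b) in enumerate(pairs):
        sub = df[[a, b]]
        keep = sub.sum(axis=1) > 0
        sub = sub.loc[keep]
        res = fisher_exact(ContingencyTable(sub), n_draws=n_draws, seed=seed + i)
        res.extra["pair"] = (a, b)
        results.append(res)
    if len(results) > 1:
        raw = [r.p for r in results]
        adj = multipletests(raw, method=correction)[1]
        for r, q in zip(results, adj):
            r.adjusted_p = float(q)
    else:
        results[0].adjusted_p = results[0].p
    return results


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-squared p value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size < 2:
        raise ValueError("all values identical: H undefined")
    H, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(H), len(groups) - 1, float(p))


def phylo_vcv(ut: UltrametricTree, tip_order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of an ultrametric tree: C_ij equals
    the shared path length from the root to the MRCA of tips i and j."""
    tips = list(tip_order) if tip_order else sorted(ut.tip_names)
    idx = {n: i for i, n in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))
    depths = ut._depths()
    for node in ut.tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [idx[node.taxon.label]]
            C[node._tipset[0], node._tipset[0]] = depths[node]
            continue
        kids = node.child_nodes()
        sets = [k._tipset for k in kids]
        d = depths[node]
        for a, b in itertools.combinations(sets, 2):
            for i in a:
                C[i, b] = d
                C[np.ix_(b, [i])] = d
        node._tipset = [i for s in sets for i in s]
    return C, tips


def _phylo_mean_mse(C: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """(phylogenetic mean, MSE0, MSE) for Blomberg's K."""
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    ahat = (one @ Ci @ x) / denom
    resid = x - ahat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ Ci @ resid) / (n - 1)
    return float(ahat), mse0, mse


def blomberg_K(
    ut: UltrametricTree,
    trait: dict[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Blomberg's K phylogenetic-signal statistic with a permutation test.

    K = (MSE0/MSE) / E_BM[MSE0/MSE]; K near 1 matches Brownian evolution,
    K near 0 no signal.  p = fraction of tip-shuffled datasets whose MSE is
    as small as observed (smaller MSE = stronger signal).
    """
    C, tips = phylo_vcv(ut)
    x = np.array([float(trait[t]) for t in tips])
    if np.allclose(x, x[0]):
        raise ValueError("zero trait variance: K undefined")
    n = len(x)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Ci @ one
    expected = (np.trace(C) - n / denom) / (n - 1)
    _, mse0, mse = _phylo_mean_mse(C, x)
    K = (mse0 / mse) / expected
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        _, _, mse_p = _phylo_mean_mse(C, xp)
        if mse_p <= mse:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return TestResult("blomberg_K", float(K), None, float(p), seed=seed, n_draws=n_perm)


# --- delta statistic for categorical traits ---------------------------------


def _er_transition(k: int, q: float, t: float) -> tuple[float, float]:
    """Equal-rates Markov chain transition probabilities over time t:
    (stay, move-to-a-specific-other-state)."""
    e = np.exp(-k * q * t)
    return 1.0 / k + (1 - 1.0 / k) * e, 1.0 / k - e / k


def _er_loglik_and_marginals(ut, states: dict[str, int], k: int, q: float,
                             want_marginals: bool = False):
    """Felsenstein pruning under the ER model; optionally the marginal
    ancestral state probabilities of every internal node (up-down pass)."""
    down: dict = {}
    for node in ut.tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(k)
            v[states[node.taxon.label]] = 1.0
            down[node] = v
            continue
        v = np.ones(k)
        for ch in down_children(node):
            stay, move = _er_transition(k, q, ch.edge.length)
            Lch = down[ch]
            tot = Lch.sum()
            v = v * (move * tot + (stay - move) * Lch)
        down[node] = v
    root = ut.tree.seed_node
    lik = down[root].mean()  # uniform root prior
    ll = float(np.log(max(lik, 1e-300)))
    if not want_marginals:
        return ll, None
    up: dict = {root: np.full(k, 1.0 / k)}
    marg = {}
    for node in ut.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        post = up[node] * down[node]
        marg[node] = post / post.sum()
        for ch in down_children(node):
            stay, move = _er_transition(k, q, ch.edge.length)
            rest = up[node].copy()
            for sib in down_children(node):
                if sib is ch:
                    continue
                s2, m2 = _er_transition(k, q, sib.edge.length)
                Ls = down[sib]
                rest = rest * (m2 * Ls.sum() + (s2 - m2) * Ls)
            up[ch] = move * rest.sum() + (stay - move) * rest
    return ll, marg


def down_children(node):
    return node.child_nodes()


def _delta_from_marginals(marg: dict, k: int) -> float:
    """Entropy-based conservation index: mean information content of the
    node-wise ancestral reconstructions relative to their mean entropy."""
    hmax = np.log(k)
    ents = []
    for p in marg.values():
        p = np.clip(p, 1e-12, 1.0)
        ents.append(-np.sum(p * np.log(p)))
    ents = np.asarray(ents)
    return float(np.mean(hmax - ents) / (np.mean(ents) + 1e-9))


def delta_stat(
    ut: UltrametricTree,
    trait: dict[str, str],
    n_rand: int = 99,
    seed: int = 0,
) -> TestResult:
    """Delta statistic of phylogenetic signal for a categorical trait.

    Marginal ancestral-state probabilities are estimated under an ML-fitted
    equal-rates Markov model and aggregated through node entropies; large
    delta = conserved trait.  p = fraction of ``n_rand`` tip randomizations
    with delta >= observed.  (The original formulation samples ancestral
    probabilities by MCMC; this ML approximation keeps its randomization
    null.)
    """
    tips = sorted(ut.tip_names)
    cats = sorted(set(trait[t] for t in tips))
    k = len(cats)
    if k < 2:
        raise ValueError("trait needs >= 2 categories")
    small = [c for c in cats if sum(trait[t] == c for t in tips) < 2]
    if small:
        raise ValueError(f"categories with < 2 tips: {small}")
    cat_idx = {c: i for i, c in enumerate(cats)}

    def fit_and_delta(states: dict[str, int]) -> float:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda lq: -_er_loglik_and_marginals(ut, states, k, np.exp(lq))[0],
            bounds=(np.log(1e-4 / ut.crown_age * 10), np.log(50.0 / ut.crown_age)),
            method="bounded",
        )
        q = float(np.exp(res.x))
        _, marg = _er_loglik_and_marginals(ut, states, k, q, want_marginals=True)
        return _delta_from_marginals(marg, k)

    states = {t: cat_idx[trait[t]] for t in tips}
    observed = fit_and_delta(states)
    rng = np.random.default_rng(seed)
    labels = np.array([states[t] for t in tips])
    hits = 0
    for _ in range(n_rand):
        perm = rng.permutation(labels)
        if fit_and_delta({t: int(s) for t, s in zip(tips, perm)}) >= observed:
            hits += 1
    p = (hits + 1) / (n_rand + 1)
    return TestResult("delta_stat", float(observed), None, float(p), seed=seed, n_draws=n_rand)


def phylo_anova(
    ut: UltrametricTree,
    group: dict[str, str],
    response: dict[str, float],
    n_sim: int = 999,
    seed: int = 0,
) -> TestResult:
    """Phylogenetic ANOVA: the standard F statistic referred to a null
    distribution of F values from Brownian simulations on the tree (sigma^2
    estimated from the data by phylogenetic GLS), with Holm-adjusted
    simulation-based pairwise post-hoc comparisons.

    Groups with fewer than 2 members are excluded with a warning.
    """
    import warnings

    C, tips = phylo_vcv(ut)
    x = np.array([float(response[t]) for t in tips])
    g = np.array([group[t] for t in tips])
    counts = pd.Series(g).value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"excluding groups with < 2 members: {small}")
        keep = ~np.isin(g, small)
        x, g = x[keep], g[keep]
        C = C[np.ix_(keep, keep)]
    levels = sorted(set(g))
    if len(levels) < 2:
        raise ValueError("need >= 2 usable groups")

    def f_stat(y):
        return float(sps.f_oneway(*[y[g == lv] for lv in levels]).statistic)

    def pair_t(y, a, b):
        ya, yb = y[g == a], y[g == b]
        sp = np.sqrt(
            ((len(ya) - 1) * ya.var(ddof=1) + (len(yb) - 1) * yb.var(ddof=1))
            / (len(ya) + len(yb) - 2)
        )
        if sp == 0:
            return 0.0
        return abs(ya.mean() - yb.mean()) / (sp * np.sqrt(1 / len(ya) + 1 / len(yb)))

    F_obs = f_stat(x)
    _, _, mse_phylo = _phylo_mean_mse(C, x)
    sigma2 = max(mse_phylo, 1e-12)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(x)))
    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(levels, 2))
    t_obs = {pr: pair_t(x, *pr) for pr in pairs}
    f_hits = 0
    t_hits = {pr: 0 for pr in pairs}
    for _ in range(n_sim):
        y = L @ rng.standard_normal(len(x)) * np.sqrt(sigma2)
        if f_stat(y) >= F_obs:
            f_hits += 1
        for pr in pairs:
            if pair_t(y, *pr) >= t_obs[pr]:
                t_hits[pr] += 1
    p = (f_hits + 1) / (n_sim + 1)
    raw = [(t_hits[pr] + 1) / (n_sim + 1) for pr in pairs]
    adj = multipletests(raw, method="holm")[1] if len(pairs) > 1 else raw
    posthoc = {
        f"{a}|{b}": {"t": t_obs[(a, b)], "p": float(pr_), "p_holm": float(q)}
        for (a, b), pr_, q in zip(pairs, raw, adj)
    }
    return TestResult(
        "phylo_anova", F_obs, len(levels) - 1, float(p), seed=seed, n_draws=n_sim,
        extra={"posthoc": posthoc, "sigma2": sigma2},
    )
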