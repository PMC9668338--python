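"""Comparative statistics: exact/Monte-Carlo Fisher tests, BH adjustment,
Kruskal-Wallis, Blomberg's K, the delta statistic, phylogenetic ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neodiv.bd import RateSpec
from neodiv.phylostats import (
    ContingencyTable,
    blomberg_K,
    delta_stat,
    fisher_exact,
    kruskal_wallis,
    pairwise_fisher,
    phylo_anova,
    phylo_vcv,
)
from neodiv.simulate import simulate_tree


def table(rows):
    return ContingencyTable(pd.DataFrame(rows))


def brute_force_fisher_2x2(t: np.ndarray) -> float:
    """Exact two-sided Fisher p by full enumeration of margin-fixed tables."""
    from math import comb

    r0, r1 = t.sum(axis=1)
    c0, _ = t.sum(axis=0)
    n = t.sum()

    def prob(a):
        b = r0 - a
        c = c0 - a
        d = r1 - c
        if min(b, c, d) < 0:
            return None
        return comb(r0, a) * comb(r1, c) / comb(n, c0)

    p_obs = prob(t[0, 0])
    total = 0.0
    for a in range(0, min(r0, c0) + 1):
        p = prob(a)
        if p is not None and p <= p_obs * (1 + 1e-12):
            total += p
    return total


class TestFisherExact:
    @pytest.mark.parametrize(
        "t",
        [
            np.array([[3, 1], [1, 3]]),
            np.array([[10, 2], [4, 9]]),
            np.array([[1, 8], [7, 2]]),
            np.array([[5, 5], [5, 5]]),
        ],
    )
    def test_2x2_matches_enumeration(self, t):
        res = fisher_exact(table(t))
        assert res.p == pytest.approx(brute_force_fisher_2x2(t), abs=1e-12)

    def test_proportional_table_p_one(self):
        res = fisher_exact(table(np.array([[2, 4], [3, 6]])))
        assert res.p == pytest.approx(1.0)

    def test_zero_margin_degenerate(self):
        res = fisher_exact(table(np.array([[0, 0], [3, 4]])))
        assert res.p == 1.0 and res.extra.get("degenerate")

    def test_rxc_monte_carlo_deterministic(self):
        t = table(np.array([[8, 2, 1], [3, 7, 2], [1, 2, 9]]))
        a = fisher_exact(t, n_draws=20_000, seed=5)
        b = fisher_exact(t, n_draws=20_000, seed=5)
        assert a.p == b.p
        assert a.method == "fisher_exact_mc"

    def test_rxc_detects_strong_association(self):
        t = table(np.array([[20, 0, 0], [0, 20, 0], [0, 0, 20]]))
        assert fisher_exact(t, n_draws=20_000, seed=0).p < 0.001


class TestPairwiseFisher:
    def test_two_groups_single_uncorrected(self):
        t = table(np.array([[3, 1], [1, 3]]))
        out = pairwise_fisher(t)
        assert len(out) == 1 and out[0].adjusted_p == out[0].p

    def test_bh_formula_by_hand(self):
        t = table(np.array([[9, 1, 9, 1], [1, 9, 1, 9]]))
        out = pairwise_fisher(t, n_draws=5_000, seed=0)
        raw = np.array([r.p for r in out])
        adj = np.array([r.adjusted_p for r in out])
        m = len(raw)
        order = np.argsort(raw)
        expect = raw[order] * m / (np.arange(m) + 1)
        expect = np.minimum.accumulate(expect[::-1])[::-1]
        np.testing.assert_allclose(adj[order], np.minimum(expect, 1.0), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        t = table(np.array([[5, 2, 8], [2, 6, 1], [4, 4, 4]]))
        for r in pairwise_fisher(t, n_draws=2_000, seed=1):
            assert r.adjusted_p >= r.p - 1e-15


class TestKruskalWallis:
    def test_hand_computed_H(self):
        res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 21
        assert res.statistic == pytest.approx(12 / 42 * (12 + 75) - 21, abs=1e-9)
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_H_zero(self):
        res = kruskal_wallis([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])

    def test_null_p_roughly_uniform(self, rng):
        """Label-shuffled single-distribution data: p should be ~Uniform."""
        ps = []
        for _ in range(400):
            x = rng.normal(size=24)
            ps.append(kruskal_wallis([x[:12], x[12:]]).p)
        ps = np.array(ps)
        # coarse two-bin calibration: P(p < 0.5) ~ 0.5
        frac = np.mean(ps < 0.5)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 400)


@pytest.fixture(scope="module")
def signal_tree():
    return simulate_tree(
        RateSpec("speciation", "constant", 0.35),
        RateSpec("extinction", "constant", 0.05),
        crown_age=12.0, rho=1.0, seed=77, size_window=(48, 80),
    )


def simulate_bm(ut, rng, sigma2=1.0):
    C, tips = phylo_vcv(ut)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(tips)))
    x = L @ rng.standard_normal(len(tips)) * np.sqrt(sigma2)
    return dict(zip(tips, x))


class TestBlombergK:
    def test_brownian_calibration(self, signal_tree, rng):
        """Mean K over Brownian replicates sits near 1."""
        ks = []
        for _ in range(120):
            trait = simulate_bm(signal_tree, rng)
            ks.append(blomberg_K(signal_tree, trait, n_perm=0).statistic)
        assert 0.85 <= float(np.mean(ks)) <= 1.15

    def test_shuffled_trait_low_K_high_p(self, signal_tree, rng):
        low, insig = 0, 0
        n = 25
        for i in range(n):
            trait = simulate_bm(signal_tree, rng)
            vals = rng.permutation(list(trait.values()))
            shuffled = dict(zip(trait.keys(), vals))
            res = blomberg_K(signal_tree, shuffled, n_perm=199, seed=i)
            if res.statistic < 1.0:
                low += 1
            if res.p > 0.05:
                insig += 1
        assert low >= int(0.9 * n)
        assert insig >= int(0.8 * n)

    def test_determinism_and_zero_variance(self, signal_tree):
        trait = {t: 1.0 for t in signal_tree.tip_names}
        with pytest.raises(ValueError):
            blomberg_K(signal_tree, trait)
        trait = {t: float(i) for i, t in enumerate(signal_tree.tip_names)}
        a = blomberg_K(signal_tree, trait, n_perm=99, seed=4)
        b = blomberg_K(signal_tree, trait, n_perm=99, seed=4)
        assert (a.statistic, a.p) == (b.statistic, b.p)


class TestDeltaStat:
    def _clustered_trait(self, ut):
        """Trait perfectly clustered in the two crown subclades."""
        root_kids = ut.tree.seed_node.child_nodes()
        side_a = {lf.taxon.label for lf in root_kids[0].leaf_iter()}
        return {t: ("A" if t in side_a else "B") for t in ut.tip_names}

    def test_conserved_trait_beats_randomized_null(self, signal_tree):
        trait = self._clustered_trait(signal_tree)
        res = delta_stat(signal_tree, trait, n_rand=39, seed=0)
        assert res.p <= 0.05

    def test_randomized_trait_not_significant_mostly(self, signal_tree, rng):
        insig = 0
        n = 10
        labels = list(self._clustered_trait(signal_tree).values())
        for i in range(n):
            vals = rng.permutation(labels)
            trait = dict(zip(signal_tree.tip_names, vals))
            res = delta_stat(signal_tree, trait, n_rand=39, seed=i)
            if res.p > 0.05:
                insig += 1
        assert insig >= 7

    def test_determinism_and_single_category_error(self, signal_tree):
        trait = {t: "X" for t in signal_tree.tip_names}
        with pytest.raises(ValueError):
            delta_stat(signal_tree, trait)
        trait = self._clustered_trait(signal_tree)
        a = delta_stat(signal_tree, trait, n_rand=19, seed=2)
        b = delta_stat(signal_tree, trait, n_rand=19, seed=2)
        assert (a.statistic, a.p) == (b.statistic, b.p)


class TestPhyloAnova:
    def _groups(self, ut, rng, n_groups=3):
        tips = sorted(ut.tip_names)
        labels = [f"g{i % n_groups}" for i in range(len(tips))]
        rng.shuffle(labels)
        return dict(zip(tips, labels))

    def test_planted_shift_detected(self, signal_tree, rng):
        hits = 0
        n = 10
        for i in range(n):
            groups = self._groups(signal_tree, rng)
            resp = simulate_bm(signal_tree, rng)
            sd = np.std(list(resp.values()))
            for t, g in groups.items():
                if g == "g0":
                    resp[t] += 3 * sd
            res = phylo_anova(signal_tree, groups, resp, n_sim=199, seed=i)
            if res.p < 0.05:
                hits += 1
        assert hits >= int(0.9 * n)

    def test_null_is_calibrated(self, signal_tree, rng):
        """Type-I error within 3 binomial SE of 5% under the BM null."""
        n = 120
        rejections = 0
        for i in range(n):
            groups = self._groups(signal_tree, rng)
            resp = simulate_bm(signal_tree, rng)
            res = phylo_anova(signal_tree, groups, resp, n_sim=99, seed=i)
            if res.p <= 0.05:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rejections / n - 0.05) <= 3 * se + 1e-9

    def test_determinism_and_small_group_warning(self, signal_tree, rng):
        groups = self._groups(signal_tree, rng)
        one_tip = sorted(signal_tree.tip_names)[0]
        groups[one_tip] = "solo"
        resp = simulate_bm(signal_tree, rng)
        with pytest.warns(UserWarning, match="solo"):
            a = phylo_anova(signal_tree, groups, resp, n_sim=49, seed=9)
        with pytest.warns(UserWarning):
            b = phylo_anova(signal_tree, groups, resp, n_sim=49, seed=9)
        assert a.p == b.p and "posthoc" in a.extra
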