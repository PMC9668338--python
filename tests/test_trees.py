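"""Tree parsing, branching times, lineage counts, clade extraction."""

import numpy as np
import pytest

from neodiv.bd import RateSpec
from neodiv.simulate import simulate_tree
from neodiv.trees import (
    BranchingTimes,
    TreeValidationError,
    branching_times,
    extract_neotropical_clades,
    lineage_count_at,
    parse_newick,
    truncation_age,
    write_newick,
)


class TestParseNewick:
    def test_three_tip_tree(self, three_tip_tree):
        assert three_tip_tree.n_tips == 3
        assert three_tip_tree.crown_age == pytest.approx(2.0)
        assert three_tip_tree.tip_names == ("A", "B", "C")

    def test_non_ultrametric_rejected_naming_worst_tip(self):
        with pytest.raises(TreeValidationError, match="B"):
            parse_newick("((A:1,B:2):1,C:2);")

    def test_malformed_string(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_polytomy_rejected_by_default_resolvable_by_flag(self):
        nwk = "(A:2,B:2,C:2);"
        with pytest.raises(TreeValidationError, match="polytomy"):
            parse_newick(nwk)
        with pytest.warns(UserWarning):
            ut = parse_newick(nwk, resolve_polytomies=True)
        assert ut.n_tips == 3

    def test_negative_edge_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((A:1,B:1):-0.5,C:0.5);")

    def test_round_trip_preserves_branching_times(self):
        ut = simulate_tree(
            RateSpec("speciation", "constant", 0.25),
            RateSpec("extinction", "constant", 0.05),
            crown_age=12.0, rho=0.8, seed=7, size_window=(10, 60),
        )
        again = parse_newick(write_newick(ut))
        np.testing.assert_allclose(
            branching_times(again).ages, branching_times(ut).ages, atol=1e-9
        )


class TestBranchingTimes:
    @pytest.mark.parametrize(
        "nwk,expected",
        [
            ("((A:1,B:1):1,C:2);", [2.0, 1.0]),
            ("(A:5,B:5);", [5.0]),
            ("((A:3,B:3):7,(C:6,D:6):4);", [10.0, 6.0, 3.0]),
        ],
    )
    def test_read_off_topology(self, nwk, expected):
        bt = branching_times(parse_newick(nwk))
        np.testing.assert_allclose(bt.ages, expected)
        assert len(bt.ages) == bt.n_tips - 1

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BranchingTimes(ages=np.array([5.0, 6.0]), n_tips=3)  # not descending
        with pytest.raises(ValueError):
            BranchingTimes(ages=np.array([5.0]), n_tips=3)  # wrong length


class TestLineageCount:
    bt = BranchingTimes(ages=np.array([10.0, 6.0, 3.0]), n_tips=4)

    @pytest.mark.parametrize("age,expected", [(7.0, 2), (0.0, 4), (10.0, 2), (6.0, 2), (2.9, 4)])
    def test_half_open_convention(self, age, expected):
        assert lineage_count_at(self.bt, age) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lineage_count_at(self.bt, 11.0)

    def test_matches_node_traversal_on_simulated_tree(self, rng):
        ut = simulate_tree(
            RateSpec("speciation", "constant", 0.4),
            RateSpec("extinction", "constant", 0.1),
            crown_age=10.0, rho=1.0, seed=3, size_window=(20, 120),
        )
        bt = branching_times(ut)
        depths = ut._depths()
        for age in rng.uniform(0, ut.crown_age, 100):
            # direct count: edges spanning this age
            n_direct = 0
            for node in ut.tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                top = ut.crown_age - depths[node.parent_node]
                bot = ut.crown_age - depths[node]
                if bot <= age < top:  # edge alive at this age (half-open)
                    n_direct += 1
            assert lineage_count_at(bt, age) == n_direct


class TestTruncationAge:
    def test_brute_force_ltt_scan(self, rng):
        """The truncation age is the oldest age below which the LTT exceeds
        the bound — verified by scanning a fine age grid."""
        ut = simulate_tree(
            RateSpec("speciation", "constant", 0.5),
            RateSpec("extinction", "constant", 0.1),
            crown_age=10.0, rho=1.0, seed=9, size_window=(12, 40),
        )
        bt = branching_times(ut)
        t_star, ok = truncation_age(bt, 10)
        assert ok
        ages = np.linspace(0, bt.crown_age, 20001)
        exceed = [a for a in ages if lineage_count_at(bt, a) > 10]
        assert max(exceed) <= t_star <= max(exceed) + bt.crown_age / 20000 + 1e-12

    def test_small_tree_flagged(self):
        bt = BranchingTimes(ages=np.linspace(8, 1, 7), n_tips=8)
        t_star, ok = truncation_age(bt, 10)
        assert t_star == 0.0 and not ok

    def test_min_two_lineages_boundary(self):
        bt = BranchingTimes(ages=np.array([10.0, 6.0, 3.0]), n_tips=4)
        t_star, ok = truncation_age(bt, 2)
        assert ok
        # count exceeds 2 exactly below the second-oldest branching event
        assert t_star == pytest.approx(6.0)


class TestExtractNeotropicalClades:
    def test_spec_example(self):
        ut = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        flags = {"A": "in", "B": "in", "C": "out", "D": "in"}
        out = extract_neotropical_clades(ut, flags, threshold=0.8, min_tips=2)
        assert len(out) == 1
        assert set(out[0].tip_names) == {"A", "B"}

    def test_all_in_returns_whole_tree(self):
        ut = parse_newick("((A:1,B:1):1,C:2);")
        out = extract_neotropical_clades(ut, {t: "in" for t in ut.tip_names})
        assert len(out) == 1 and out[0].n_tips == 3

    def test_empty_flags_error(self, three_tip_tree):
        with pytest.raises(ValueError):
            extract_neotropical_clades(three_tip_tree, {})

    def test_antichain_and_threshold_by_brute_force(self, rng):
        """Returned clades never nest, all meet the threshold, and they are
        maximal — checked against exhaustive clade enumeration."""
        ut = simulate_tree(
            RateSpec("speciation", "constant", 0.5),
            RateSpec("extinction", "constant", 0.0),
            crown_age=8.0, rho=1.0, seed=21, size_window=(16, 64),
        )
        flags = {t: ("in" if rng.random() < 0.7 else "out") for t in ut.tip_names}
        for threshold in (0.8, 1.0):
            out = extract_neotropical_clades(ut, flags, threshold=threshold, min_tips=2)
            tip_sets = [frozenset(c.tip_names) for c in out]
            for i, a in enumerate(tip_sets):
                for j, b in enumerate(tip_sets):
                    assert i == j or not (a <= b)
            # brute force: all clades of the tree meeting the rule
            all_clades = []
            for node in ut.tree.preorder_internal_node_iter():
                labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
                frac = sum(flags[x] == "in" for x in labels) / len(labels)
                if len(labels) >= 2 and frac >= threshold:
                    all_clades.append(labels)
            maximal = [
                c for c in all_clades if not any(c < other for other in all_clades)
            ]
            assert sorted(map(sorted, maximal)) == sorted(map(sorted, tip_sets))


class TestMetadataCsv:
    def test_round_trip(self, tmp_path):
        import pandas as pd
        from neodiv.trees import REGIONS, load_metadata_csv

        df = pd.DataFrame(
            [
                {"clade_id": "c1", "taxon_group": "plant", "n_sampled": 10,
                 "n_described": 25, "elevation_class": "lowland",
                 **{r: i for i, r in enumerate(REGIONS)}},
                {"clade_id": "c2", "taxon_group": "bird", "n_sampled": 4,
                 "n_described": 4, "elevation_class": "mixed",
                 **{r: 0 for r in REGIONS}},
            ]
        )
        p = tmp_path / "meta.csv"
        df.to_csv(p, index=False)
        recs = load_metadata_csv(p)
        assert recs[0].sampling_fraction == pytest.approx(0.4)
        assert recs[0].region_counts["elsewhere"] == 12
        assert recs[1].taxon_group == "bird"

    def test_missing_column_named(self, tmp_path):
        import pandas as pd
        from neodiv.trees import load_metadata_csv

        p = tmp_path / "meta.csv"
        pd.DataFrame([{"clade_id": "x", "taxon_group": "plant"}]).to_csv(p, index=False)
        with pytest.raises(ValueError, match="n_sampled"):
            load_metadata_csv(p)
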