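import numpy as np
import pytest

from neodiv.bd import BDModel, RateSpec
from neodiv.simulate import simulate_tree
from neodiv.trees import BranchingTimes, branching_times, parse_newick


@pytest.fixture
def toy_bt() -> BranchingTimes:
    """4-tip branching times {10, 6, 3} used across likelihood tests."""
    return BranchingTimes(ages=np.array([10.0, 6.0, 3.0]), n_tips=4)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def constant_tree_200():
    """A mid-sized reconstructed tree simulated under constant rates
    (lambda=0.3, mu=0.1, rho=1), shared by recovery tests."""
    ut = simulate_tree(
        RateSpec("speciation", "constant", 0.3),
        RateSpec("extinction", "constant", 0.1),
        crown_age=25.0,
        rho=1.0,
        seed=11,
        size_window=(150, 320),
    )
    return ut, branching_times(ut)


def constant_model(lam: float, mu: float) -> BDModel:
    return BDModel(
        f"const_{lam}_{mu}",
        RateSpec("speciation", "constant", lam),
        RateSpec("extinction", "constant", mu),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
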