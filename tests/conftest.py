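import numpy as np
import pytest

from dielniche.phylo import Phylogeny
from dielniche.synth import make_light_schedule, simulate_cohort


@pytest.fixture(scope="session")
def schedule():
    """Standard 12:12 light cycle, 07:00-19:00, 30-min ramps."""
    return make_light_schedule("07:00", "19:00", 30)


@pytest.fixture(scope="session")
def star10():
    """Ten-tip star tree of unit depth."""
    return Phylogeny.from_newick(
        "(" + ",".join(f"t{i}:1" for i in range(10)) + ");")


@pytest.fixture(scope="session")
def tree3():
    """The hand-readable 3-tip tree ((A:1,B:1):1,C:2)."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree5():
    """Asymmetric 5-tip tree used for hand computations."""
    return Phylogeny.from_newick(
        "((A:0.3,B:0.3):0.7,((C:0.4,D:0.4):0.2,E:0.6):0.4);")


@pytest.fixture(scope="session")
def small_cohort():
    """12 synthetic species, 4 individuals, 3 days of binned data."""
    return simulate_cohort(n_species=12, n_individuals=4, days=3, seed=11)


@pytest.fixture(scope="session")
def full_cohort():
    """The standard 60-species cohort."""
    return simulate_cohort(n_species=60, n_individuals=8, days=6, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
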