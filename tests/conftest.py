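import numpy as np
import pandas as pd
import pytest

from phyloancova import SimConfig, TraitTable, parse_newick, simulate_dataset

# Single base seed for every stochastic check in the suite, fixed up front.
BASE_SEED = 12345


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); ultrametric with height 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_traits():
    """Six species covering both base and non-base factor levels."""
    return TraitTable(
        pd.DataFrame(
            {
                "species": ["a", "b", "c", "d", "e", "f"],
                "hct": [25.0, 27.0, 30.0, 22.0, 33.0, 28.0],
                "habitat": [
                    "Terrestrial",
                    "Terrestrial",
                    "Marine",
                    "Semi-aquatic",
                    "Marine",
                    "Aquatic",
                ],
                "clade": [
                    "Colubrinae",
                    "Elapidae",
                    "Elapidae",
                    "Natricinae",
                    "Acrochordidae",
                    "Acrochordidae",
                ],
            }
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study-scale conditions."""
    return simulate_dataset(SimConfig(seed=BASE_SEED))
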