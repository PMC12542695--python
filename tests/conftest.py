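import numpy as np
import pandas as pd
import pytest

from phyconiche.otu import OtuTable
from phyconiche.trees import read_newick

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return read_newick(TOY_NEWICK)


@pytest.fixture
def toy_table():
    counts = pd.DataFrame(
        {"S1": [4, 0, 1], "S2": [2, 3, 0]},
        index=["OTU1", "OTU2", "OTU3"],
    )
    stages = pd.Series({"S1": "initial", "S2": "plateau"})
    return OtuTable(counts, stages)


@pytest.fixture
def random_table():
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(30, 8)),
        index=[f"OTU{i}" for i in range(30)],
        columns=[f"S{j}" for j in range(8)],
    )
    counts.iloc[:, 0] += 1  # no empty sample
    stages = pd.Series(
        ["initial"] * 2 + ["plateau"] * 3 + ["last"] * 3, index=counts.columns
    )
    return OtuTable(counts, stages)


@pytest.fixture(scope="session")
def community_scenario():
    """One shared default-settings synthetic community (seeded)."""
    from phyconiche.synthetic import generate_community

    return generate_community(seed=20240801)
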