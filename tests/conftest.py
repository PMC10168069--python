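import numpy as np
import pandas as pd
import pytest

from funcstruct import CommunityMatrix, SoilTable, TraitTable, make_fixture


@pytest.fixture
def tiny():
    return make_fixture("tiny")


@pytest.fixture
def small_community():
    """5 plots x 5 species with mixed richness {1, 2, 3, 4, 5}."""
    ab = pd.DataFrame(
        [
            [2.0, 0.0, 0.0, 0.0, 0.0],
            [1.0, 3.0, 0.0, 0.0, 0.0],
            [0.0, 2.0, 2.0, 1.0, 0.0],
            [4.0, 0.0, 1.0, 2.0, 3.0],
            [1.0, 1.0, 1.0, 1.0, 1.0],
        ],
        index=[f"P{i}" for i in range(1, 6)],
        columns=[f"sp{i}" for i in range(1, 6)],
    )
    sites = pd.Series(["A", "A", "B", "B", "C"], index=ab.index)
    return CommunityMatrix(ab, sites)


@pytest.fixture
def small_traits():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        {
            "LT": [0.3, 0.5, 0.7, 0.9, 1.1],
            "SLA": [18.0, 14.0, 11.0, 9.0, 7.0],
            "PH": rng.uniform(50, 500, 5).round(1),
        },
        index=[f"sp{i}" for i in range(1, 6)],
    )
    return TraitTable(values, standardized=False)


@pytest.fixture
def small_soil(small_community):
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        {
            "Na": rng.lognormal(np.log(3000), 0.8, 5),
            "K": rng.lognormal(np.log(700), 0.5, 5),
            "pH": rng.normal(7.8, 0.2, 5),
        },
        index=small_community.plot_ids,
    )
    return SoilTable(values, {"Na": "mg/kg", "K": "mg/kg", "pH": "pH"})
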