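import numpy as np
import pandas as pd
import pytest

from snownet.chemistry import ChemTable
from snownet.community import OtuTable
from snownet.simulate import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Laptop-scale synthetic season used across recovery tests."""
    return SyntheticConfig(seed=7, n_otus=50, n_pos_pairs=5, n_neg_pairs=2)


@pytest.fixture
def tiny_otu_table():
    """4 ES + 4 LS samples, 5 OTUs, hand-set presence pattern."""
    counts = pd.DataFrame(
        {
            "OTU1": [5, 3, 2, 8, 1, 2, 3, 4],
            "OTU2": [0, 0, 1, 0, 0, 0, 2, 0],
            "OTU3": [1, 1, 1, 1, 1, 1, 1, 1],
            "OTU4": [0, 0, 0, 0, 0, 0, 0, 9],
            "OTU5": [2, 0, 4, 1, 0, 3, 0, 5],
        },
        index=[f"S{i}" for i in range(8)],
    )
    meta = pd.DataFrame(
        {"period": ["ES"] * 4 + ["LS"] * 4, "time_index": range(8)},
        index=counts.index,
    )
    return OtuTable(counts=counts, sample_meta=meta)


@pytest.fixture
def tiny_chem_table():
    values = pd.DataFrame(
        {
            "acetate": [np.nan, 5.1, 20.0],
            "lactate": [4.0, 2.0, np.nan],
            "pH": [5.2, 5.4, 5.6],
        },
        index=["a", "b", "c"],
    )
    mask = pd.DataFrame(
        {
            "acetate": [True, False, False],
            "lactate": [False, False, True],
            "pH": [False, False, False],
        },
        index=values.index,
    )
    lod = pd.Series({"acetate": 0.4, "lactate": 0.6})
    return ChemTable(values=values, below_lod=mask, lod=lod, ph_column="pH")
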