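import numpy as np
import pandas as pd
import pytest

from morphospace import pca, synthetic
from morphospace.data_model import CC_NAMES, CCTable


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic CC panel at the study-condition defaults (seed 0)."""
    return synthetic.generate_cc_dataset(synthetic.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def default_model(default_dataset):
    table, _ = default_dataset
    return pca.fit_pca(table)


@pytest.fixture(scope="session")
def default_scores(default_dataset, default_model):
    table, _ = default_dataset
    return pca.project(default_model, table)


def make_cc_frame(rows):
    """Rows of (NGA, PolID, Time, World, nine CC values)."""
    return pd.DataFrame(rows, columns=["NGA", "PolID", "Time", "World", *CC_NAMES])


@pytest.fixture()
def tiny_table():
    """Three handwritten records in one Old World NGA."""
    df = make_cc_frame([
        ("A", "A_p0", -200, "Old", 1.25, 2.0, 0.5, 1.0, 0.75, 0.25, 0.125, 0.0625, 3.0),
        ("A", "A_p0", -100, "Old", 1.50, 2.25, 0.75, 1.25, 1.0, 0.5, 0.25, 0.125, 3.25),
        ("A", "A_p1", 0, "Old", 2.0, 2.5, 1.0, 1.5, 1.25, 0.75, 0.5, 0.25, 3.5),
    ])
    return CCTable(df=df, provenance="fixture")
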