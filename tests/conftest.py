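import numpy as np
import pytest

import sctreesig as st

BALANCED_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced_tree():
    return st.parse_newick(BALANCED_NEWICK)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_expression():
    """4 cells x 3 genes with a zero and an unknown."""
    values = np.array([
        [1.0, 0.0, 5.0],
        [2.0, 2.0, 5.0],
        [3.0, 4.0, 5.0],
        [np.nan, 6.0, 5.0],
    ])
    return st.ExpressionMatrix(
        values=values,
        cell_ids=["c1", "c2", "c3", "c4"],
        feature_ids=["g1", "g2", "g3"],
        sample_of={"c1": "S1", "c2": "S1", "c3": "S2", "c4": "S2"},
    )


@pytest.fixture
def small_ordinal():
    values = np.array([
        [1.0, 3.0, np.nan],
        [2.0, 3.0, 4.0],
        [3.0, 3.0, 4.0],
    ])
    return st.OrdinalMatrix(
        values=values,
        cell_ids=["c1", "c2", "c3"],
        feature_ids=["g1", "g2", "g3"],
        sample_of={"c1": "S1", "c2": "S1", "c3": "S2"},
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small but complete synthetic dataset shared across tests."""
    cfg = st.SimulationConfig(
        samples={"T1": 8, "T2": 5, "T3": 8, "CTC1": 5, "CTC2": 5},
        n_genes=120, n_sites=80,
        dropout=("fixed", 0.6), seed=424242,
    )
    return st.simulate_dataset(cfg)
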