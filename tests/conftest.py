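import numpy as np
import pandas as pd
import pytest

import sfactivity as sfa


@pytest.fixture(scope="session")
def truth():
    """One planted ground-truth configuration shared across tests."""
    return sfa.make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def small_truth():
    """A small configuration for fast end-to-end chains."""
    return sfa.make_ground_truth(
        n_sf=12, n_onc=4, n_ts=4, n_exons=400, n_genes=400, targets_per_sf=30, seed=3
    )


@pytest.fixture
def toy_signature():
    """The 5-feature signature of the enrichment worked example."""
    return pd.Series([2.0, 1.0, 0.0, -1.0, -2.0], index=list("ABCDE"))


@pytest.fixture
def psi_matrix():
    data = pd.DataFrame(
        {
            "s1": [10.0, 50.0, np.nan],
            "s2": [30.0, 70.0, 90.0],
            "s3": [20.0, 60.0, 80.0],
        },
        index=["e1", "e2", "e3"],
    )
    return sfa.FeatureMatrix(data, "psi")
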