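import numpy as np
import pandas as pd
import pytest

from neurovuln.synthetic import (
    CellSpec,
    CnvSpec,
    SyntheticConfig,
    generate_dataset,
    generate_geometry,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_geometry():
    return generate_geometry(20, seed=3)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study shared across test modules."""
    cfg = SyntheticConfig(
        n_per_hemisphere=40,
        n_genes=400,
        n_donors=3,
        k_factors=8,
        n_cases=20,
        n_controls=20,
        cnv=CnvSpec(size=20, coupling_r=0.7, sign=1, n_ds=8, n_dsss=4),
        cells=CellSpec(genes_per_set=6),
    )
    return generate_dataset(cfg, seed=11)


@pytest.fixture
def random_features(rng):
    """10 regions x 5 features table."""
    return pd.DataFrame(
        rng.standard_normal((10, 5)),
        index=[f"r{i}" for i in range(10)],
        columns=["CT", "SA", "GM", "MC", "IC"],
    )
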