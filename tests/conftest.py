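import numpy as np
import pandas as pd
import pytest

from ordisp import (
    CovariateSchema,
    ModelSpec,
    Parameters,
    encode_covariates,
    setting_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def schemas3():
    """Two continuous covariates plus a 4-level ordinal one (benchmark layout)."""
    return setting_config(1).schemas


@pytest.fixture(scope="session")
def tiny_cluster(schemas3):
    """One 3-observation cluster with k=3 responses covering all categories."""
    rng = np.random.default_rng(3)
    raw = pd.DataFrame({
        "cluster": [1, 1, 1], "y": [1, 2, 3],
        "x1": rng.uniform(-1, 1, 3), "x2": rng.uniform(-1, 1, 3), "x3": [1, 3, 4],
    })
    return encode_covariates(raw, schemas3, k=3)


@pytest.fixture(scope="session")
def bench_params():
    """The benchmark truth: thresholds (-1,1), mixed-sign effects, Sigma_b PD."""
    return Parameters(
        thresholds=[-1.0, 1.0],
        beta=[-0.2, 0.2, -0.5, 0.5, 0.5],
        alpha=[-0.4, 0.4, 0.0, 0.0, 0.0],
        Sigma_b=[[0.10, 0.02], [0.02, 0.10]],
    )


@pytest.fixture(scope="session")
def small_dataset(schemas3):
    """A small clustered dataset (12 clusters x 15 obs) for fast fitting tests."""
    cfg = setting_config(1, n_clusters=12, cluster_size=15)
    return simulate_dataset(cfg, 5)


@pytest.fixture(scope="session")
def small_standardized(small_dataset, schemas3):
    return encode_covariates(small_dataset.raw, schemas3, standardize=True, k=3)
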