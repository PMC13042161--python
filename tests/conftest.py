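import numpy as np
import pytest
from hypothesis import settings

import tauspread as ts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_connectome() -> ts.Connectome:
    """Deterministic 12-region geometric connectome with centroids."""
    return ts.generate_connectome(ts.SyntheticSpec(n_regions=12, seed=7))


@pytest.fixture(scope="session")
def chain_connectome() -> ts.Connectome:
    """3-region chain A-B-C with unit weights and no geometry."""
    W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
    return ts.Connectome(W, ["A", "B", "C"])


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded default cohort with its ground truth (session-cached)."""
    spec = ts.SyntheticSpec(n_regions=40, seed=11, epicenter_index=5)
    conn = ts.generate_connectome(spec)
    table, truth = ts.generate_cohort(spec, conn)
    return spec, conn, table, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
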