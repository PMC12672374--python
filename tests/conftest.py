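import numpy as np
import pandas as pd
import pytest

from olgstate import SimulationConfig, simulate_multiome


@pytest.fixture(scope="session")
def small_dataset():
    """One modest paired dataset shared by read-only tests."""
    cfg = SimulationConfig(n_cells_per_sample=120, seed=7)
    return simulate_multiome(cfg)


@pytest.fixture(scope="session")
def linking_dataset():
    """Larger per-sample size so per-cell correlations are estimable."""
    cfg = SimulationConfig(
        n_cells_per_sample=125,
        samples=[("s1", "cfa", "r1"), ("s2", "cfa", "r2"), ("s3", "early", "r1"), ("s4", "peak", "r1")],
        seed=11,
    )
    return simulate_multiome(cfg)


@pytest.fixture()
def tiny_norm():
    """5-cell x 20-gene deterministic normalized matrix."""
    from olgstate.datatypes import NormalizedMatrix

    rng = np.random.default_rng(3)
    vals = rng.gamma(2.0, 1.0, size=(20, 5))
    return NormalizedMatrix(
        values=vals,
        features=pd.Index([f"g{i}" for i in range(20)]),
        cells=pd.Index([f"c{i}" for i in range(5)]),
        method="lognorm",
    )
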