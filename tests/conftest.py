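import numpy as np
import pytest

from deepcsd import (
    ExpressionDataset,
    NetworkParams,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark: 4 x 60 samples, 2000 genes,
    50 planted genes per pair, effect size 2, noise sd 0.5."""
    ds, truth = simulate_dataset(SimulationConfig(seed=11))
    return ds, truth


@pytest.fixture()
def tiny_dataset():
    rng = np.random.default_rng(5)
    return ExpressionDataset(
        gene_ids=[f"G{i}" for i in range(6)],
        sample_ids=[f"S{i}" for i in range(8)],
        values=rng.normal(6, 1, size=(6, 8)),
        labels=["CMS1", "CMS1", "CMS2", "CMS2", "CMS3", "CMS3", "CMS4", "CMS4"],
    )


@pytest.fixture()
def toy_params():
    """A small random network (5 -> 3 -> 4 over 10 genes)."""
    rng = np.random.default_rng(42)
    return NetworkParams(
        W1=rng.normal(0, 0.5, (5, 10)),
        theta1=rng.normal(0, 0.1, 5),
        W2=rng.normal(0, 0.5, (3, 5)),
        theta2=rng.normal(0, 0.1, 3),
        W3=rng.normal(0, 0.5, (4, 3)),
        theta3=rng.normal(0, 0.1, 4),
        dropout_keep_p=0.8,
        l1_coef=0.05,
        l2_coef=0.1,
    )
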