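import numpy as np
import pytest

from countpower import (
    CountMatrix,
    SampleDesign,
    SimulationConfig,
    make_use_case_fixture,
    simulate_counts,
)


@pytest.fixture
def toy_counts():
    """5 genes x 4 samples, two groups of two."""
    counts = np.array(
        [
            [10.0, 12.0, 50.0, 40.0],
            [0.0, 0.0, 0.0, 0.0],
            [5.0, 4.0, 6.0, 5.0],
            [100.0, 110.0, 95.0, 105.0],
            [1.0, 0.0, 2.0, 0.0],
        ]
    )
    return CountMatrix(
        [f"g{i}" for i in range(5)], ["a1", "a2", "b1", "b2"], counts
    )


@pytest.fixture
def toy_design():
    samples = ["a1", "a2", "b1", "b2"]
    return SampleDesign(samples, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture(scope="session")
def nb_dataset():
    """Moderate NB simulation: 2000 genes, 4 vs 4, BCOV 0.2, 10% DE."""
    cfg = SimulationConfig(
        n_genes=2000,
        n_per_group=4,
        mean_depth=2000 * 50.0,
        depth_spread=0.1,
        baseline_log_sd=1.0,
        bcov=0.2,
        de_fraction=0.1,
        seed=314159,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def use_case():
    """32-sample crossed-factor fixture (two cell lines x oxygen x
    treatment x mRNA fraction, duplicated)."""
    return make_use_case_fixture(seed=42)
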