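import numpy as np
import pytest

from perturbdiff.data_io import ExpressionMatrix
from perturbdiff.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated screen shared across read-only tests."""
    config = SimConfig(n_genes=20, n_modules=4, n_cell_lines=2, n_compounds=3,
                       doses=(0.1, 1.0), times=(6.0, 24.0),
                       replicates_per_condition=3, seed=42)
    control, perturbed, metadata, truth = simulate_dataset(config)
    return {"config": config, "control": control, "perturbed": perturbed,
            "metadata": metadata, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_matrix(rng):
    x = rng.normal(size=(12, 6))
    return ExpressionMatrix(x, [f"s{i}" for i in range(12)],
                            [f"g{i}" for i in range(6)])
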