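import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mgsig.simulate import (
    SimExpressionSpec,
    SimGenomeSpec,
    generate_expression_dataset,
    generate_genome,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_expression():
    """300-probe simulation with the planted 30-gene module (8 seeds)."""
    spec = SimExpressionSpec(n_probes=300, module_correlation=0.8, rng_seed=7)
    matrix, truth = generate_expression_dataset(spec)
    return matrix, truth


@pytest.fixture(scope="session")
def toy_genome():
    """Default toy genome: 200 genes, 20 targets, moderate repeat densities."""
    spec = SimGenomeSpec(rng_seed=11)
    return generate_genome(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_matrix():
    return pd.DataFrame(
        [[1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]],
        index=["a", "b", "c"],
        columns=["x", "y", "z"],
    )
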