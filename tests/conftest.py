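import numpy as np
import pytest

from ithkit.datamodel import ExpressionMatrix
from ithkit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_patients=6, n_genes=120, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression():
    values = np.array(
        [
            [1.0, 2.0],
            [3.0, 4.0],
            [5.0, 6.0],
        ]
    )
    return ExpressionMatrix(values, ["gA", "gB", "gC"], ["s1", "s2"])
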