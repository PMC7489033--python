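import numpy as np
import pytest

from demcost import (
    CostParameters,
    GeneratorConfig,
    build_cost_schedule,
    generate_cohort,
)

#: Hand-checkable stochastic matrix used across projection tests.
P_EXAMPLE = np.array(
    [
        [0.70, 0.20, 0.10],
        [0.10, 0.60, 0.30],
        [0.05, 0.15, 0.80],
    ]
)

INITIAL = (784.0, 413.0, 144.0)


@pytest.fixture(scope="session")
def default_params():
    return CostParameters()


@pytest.fixture(scope="session")
def default_schedule(default_params):
    return build_cost_schedule(default_params)


@pytest.fixture(scope="session")
def big_cohort():
    """100k complete-pair synthetic cohort, shared by the large-sample tests."""
    config = GeneratorConfig(n_clients=100_000, dropout_prob=0.0, seed=20260928)
    return config, generate_cohort(config)
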