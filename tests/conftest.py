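import numpy as np
import pytest

from periwall import (
    baseline_parameter_set,
    load_distributions,
    solve_radial_flow,
    with_imposed_lambda,
)


@pytest.fixture(scope="session")
def registry():
    return load_distributions()


@pytest.fixture(scope="session")
def baseline(registry):
    """Parameter set at the centre of every default distribution."""
    return baseline_parameter_set(registry)


@pytest.fixture(scope="session")
def physiologic_ps(registry):
    """Baseline configuration with a unit mass-balance deviation imposed."""
    return with_imposed_lambda(baseline_parameter_set(registry), 1.1)


@pytest.fixture(scope="session")
def physiologic_flow(physiologic_ps):
    return solve_radial_flow(physiologic_ps)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
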