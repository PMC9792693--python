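import numpy as np
import pytest

import partsa
from partsa import DistributionSpec


@pytest.fixture(scope="session")
def base_config():
    return partsa.load_config()


@pytest.fixture(scope="session")
def table_curves():
    """The published best-fit survival curves for the two arms."""
    return {
        "sugemalimab": {
            "pfs": DistributionSpec("loglogistic", (1.6637, 9.3549)),
            "os": DistributionSpec("loglogistic", (1.3722, 24.9818)),
        },
        "placebo": {
            "pfs": DistributionSpec("loglogistic", (1.9645, 5.3347)),
            "os": DistributionSpec("lognormal", (2.8289, 0.9785)),
        },
    }


@pytest.fixture(scope="session")
def base_run(base_config):
    """Deterministic base case, shared across tests (pure function of config)."""
    return partsa.run_base_case(base_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
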