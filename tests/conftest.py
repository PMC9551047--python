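import numpy as np
import pytest

import nsurplus as ns


@pytest.fixture(scope="session")
def config():
    return ns.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(config):
    return ns.generate_bundle(config)


@pytest.fixture(scope="session")
def components(bundle):
    return ns.run_components(bundle)


@pytest.fixture(scope="session")
def ensemble(bundle):
    """(components, 16 surplus results) on the shared bundle."""
    return ns.build_ensemble(bundle)


@pytest.fixture(scope="session")
def truth_bundle():
    return ns.generate_bundle(ns.SyntheticConfig(seed=11, truth_mode=True))


@pytest.fixture
def one_cell_grid():
    return ns.GridSpec.regular(1, 1, country_id=np.array([1]))


@pytest.fixture
def two_cell_grid():
    """1x2 grid, both cells in country 1."""
    return ns.GridSpec.regular(1, 2, country_id=np.array([1, 1]))
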