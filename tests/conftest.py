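import numpy as np
import pytest

from senmeth import simulate


@pytest.fixture(scope="session")
def panel():
    return simulate.default_panel()


@pytest.fixture(scope="session")
def casr(panel):
    return next(s for s in panel if s.name == "CASR")


@pytest.fixture()
def config():
    return simulate.default_config(seed=7, n_cells_bulk=400, reads_per_sample=400)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
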