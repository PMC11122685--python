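import numpy as np
import pytest

from polsite import synthetic


@pytest.fixture(scope="session")
def helix20():
    return synthetic.helix_coords(20)


@pytest.fixture(scope="session")
def enm_ensemble(helix20):
    """A medium ENM ensemble plus its exact model covariance."""
    ens, cov = synthetic.gen_enm_ensemble(
        helix20, cutoff=15.0, temperature_K=300.0, n_frames=2000, seed=11
    )
    return ens, cov


@pytest.fixture
def rng():
    return np.random.default_rng(853)
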