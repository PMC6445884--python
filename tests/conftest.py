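import numpy as np
import pytest

from prionscape import synthetic_data
from prionscape.prld_detection import (AmyloidMatrix, CompositionModel,
                                       call_prionlike)


@pytest.fixture(scope="session")
def default_model() -> CompositionModel:
    return CompositionModel.default()


@pytest.fixture(scope="session")
def default_matrix() -> AmyloidMatrix:
    return AmyloidMatrix.default()


@pytest.fixture(scope="session")
def uniform_model() -> CompositionModel:
    """Identity composition model: prion == background == uniform."""
    uniform = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    return CompositionModel(prion_freqs=uniform, background_freqs=dict(uniform))


@pytest.fixture(scope="session")
def small_proteome() -> synthetic_data.SyntheticProteome:
    return synthetic_data.generate_proteome(120, 0.15, seed=11)


@pytest.fixture(scope="session")
def small_calls(small_proteome):
    return call_prionlike(small_proteome.sequences())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
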