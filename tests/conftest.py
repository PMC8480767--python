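import numpy as np
import pytest

from stpnet import generate_embeddings, generate_session


@pytest.fixture(scope="session")
def embeddings():
    return generate_embeddings(seed=2)


@pytest.fixture(scope="session")
def session_sequence():
    seq = generate_session(n_trials=200, seed=11)
    seq.validate()
    return seq


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
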