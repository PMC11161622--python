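import logging

import numpy as np
import pytest

from flowcpm import EmbeddingSpace, make_embedding_space


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    """Generators and fold loops log expected warnings; keep test output
    readable but let tests opt back in via caplog."""
    logging.getLogger("flowcpm").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_space() -> EmbeddingSpace:
    return make_embedding_space(vocab_size=80, dim=25, seed=101)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
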