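import numpy as np
import pytest

from stereolang.embeddings import EmbeddingModel
from stereolang.lexicons import Lexicon, make_contrast


@pytest.fixture
def toy_model():
    """A 5-word, 2-dimensional embedding table with hand-checkable geometry."""
    vecs = {
        "robot": np.array([1.0, 0.0]),
        "smart": np.array([1.0, 0.0]),
        "clever": np.array([1.0, 1.0]),
        "dumb": np.array([0.0, 1.0]),
        "slow": np.array([-1.0, 1.0]),
        "artificial": np.array([1.0, 0.0]),
        "intelligence": np.array([0.0, 1.0]),
    }
    return EmbeddingModel(id="toy", dimension=2, vectors=vecs)


@pytest.fixture
def toy_contrast():
    return make_contrast(
        Lexicon("hi", "attribute", ("smart", "clever"), "high", "competence"),
        Lexicon("lo", "attribute", ("dumb", "slow"), "low", "competence"),
        label="competence",
    )


@pytest.fixture
def toy_targets():
    return Lexicon("tg", "target", ("robot", "artificial intelligence"), "none")
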