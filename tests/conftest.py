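import numpy as np
import pytest

from trapnet.labels import CATEGORIES_5
from trapnet.synthetic import SceneParams, generate_dataset


@pytest.fixture(scope="session")
def small_easy_dataset():
    """20 scenes per category, easy mode, fixed splits."""
    return generate_dataset(
        {c: 20 for c in CATEGORIES_5}, SceneParams.easy(),
        split_fractions=(0.6, 0.2, 0.2), seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
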