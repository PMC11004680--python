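import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from medfuse import HsvImage, PhantomSpec, make_pair


def random_image(seed: int, shape=(16, 16)) -> np.ndarray:
    return np.random.default_rng(seed).random(shape)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def phantom_pair() -> tuple[HsvImage, HsvImage]:
    return make_pair(PhantomSpec(size=(64, 64), seed=3))
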