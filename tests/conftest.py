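import numpy as np
import pytest

from kinconflict import GameParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_params(rng: np.random.Generator, n: int, y_max: float = 5.0) -> list[GameParams]:
    """Uniform draws over the valid parameter box (y bounded away from 0)."""
    s = rng.uniform(0.0, 1.0, n)
    c = rng.uniform(0.0, 1.0, n)
    y = rng.uniform(0.05, y_max, n)
    return [GameParams(s=si, c=ci, y=yi) for si, ci, yi in zip(s, c, y)]
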