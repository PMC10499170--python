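import numpy as np
import pytest


def random_pd_matrix(rng: np.random.Generator, k: int) -> np.ndarray:
    """A well-conditioned random positive-definite k x k matrix."""
    A = rng.standard_normal((k, k))
    return A @ A.T + 0.5 * np.eye(k)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture
def small_block() -> np.ndarray:
    """5 subjects x 3 measures, integer-valued, with visible subject and
    treatment effects and non-spherical-looking columns."""
    return np.array(
        [
            [3.0, 5.0, 9.0],
            [2.0, 4.0, 5.0],
            [6.0, 7.0, 13.0],
            [1.0, 3.0, 4.0],
            [5.0, 5.0, 10.0],
        ]
    )
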