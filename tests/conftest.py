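import numpy as np
import pytest

from vpgg import GameParameters


@pytest.fixture
def small_params() -> GameParameters:
    """A small population with all mechanisms active."""
    return GameParameters(
        M=5, N=3, c=1.0, r=2.2, sigma=0.6, alpha=0.4, beta=1.0,
        gamma=0.3, kappa=1.0, epsilon=1e-2,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_valid_params(
    rng: np.random.Generator,
    M: int,
    N: int,
    epsilon: float = 1e-2,
    kappa: float = 1.0,
) -> GameParameters:
    """Draw game constants uniformly inside the admissible region."""
    r = float(rng.uniform(1.05, N))
    sigma = float(rng.uniform(1e-3, r - 1.0 - 1e-6))
    alpha = float(rng.uniform(0.0, 1.0))
    beta = float(rng.uniform(0.5, 2.0))
    gamma = float(rng.uniform(0.0, beta * 0.99))
    c = float(rng.uniform(0.5, 2.0))
    return GameParameters(
        M=M, N=N, c=c, r=r, sigma=sigma, alpha=alpha, beta=beta,
        gamma=gamma, kappa=kappa, epsilon=epsilon,
    )


def all_states(M: int):
    for i in range(M + 1):
        for j in range(M - i + 1):
            for k in range(M - i - j + 1):
                yield (i, j, k)
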