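import numpy as np
import pytest

from mlsconflict.games import GameCoefficients, PayoffMatrix, coefficients_from_payoffs
from mlsconflict.victory import (
    fermi_kernel,
    fraction_kernel,
    local_update_kernel,
    normalized_diff_kernel,
    tullock_kernel,
)


@pytest.fixture
def pd_game() -> GameCoefficients:
    """Dominance game of the main simulation set: gamma=1.5, alpha=beta=-1, P=1."""
    return GameCoefficients(alpha=-1.0, beta=-1.0, gamma=1.5, P=1.0)


@pytest.fixture
def hd_game() -> GameCoefficients:
    """Coexistence game with x_eq = 0.5: gamma=3.5, alpha=-2, beta=1, P=1."""
    return GameCoefficients(alpha=-2.0, beta=1.0, gamma=3.5, P=1.0)


@pytest.fixture
def sh_game() -> GameCoefficients:
    """Bistable game with x_eq = 0.5: gamma=0, alpha=2, beta=-1, P=2."""
    return GameCoefficients(alpha=2.0, beta=-1.0, gamma=0.0, P=2.0)


@pytest.fixture
def pdel_game() -> GameCoefficients:
    """Cooperation-dominant game: payoffs R=4 > T=2 > S=1 > P=0."""
    return coefficients_from_payoffs(PayoffMatrix(R=4.0, S=1.0, T=2.0, P=0.0))


GAME_FIXTURES = ["pd_game", "hd_game", "sh_game", "pdel_game"]
KERNEL_FAMILIES = ["fraction", "local_update", "fermi", "normalized", "tullock"]


def make_kernel(family: str, game: GameCoefficients):
    if family == "fraction":
        return fraction_kernel()
    if family == "local_update":
        return local_update_kernel(game)
    if family == "fermi":
        return fermi_kernel(game, s=1.0)
    if family == "normalized":
        return normalized_diff_kernel(game)
    if family == "tullock":
        return tullock_kernel(game, a=1.0)
    raise ValueError(family)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
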