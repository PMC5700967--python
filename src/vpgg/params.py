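"""Parameter and state containers for the voluntary public goods game.

The model has four strategies: cooperator (C), defector (D), punisher (P)
and loner (L, non-participant).  A population of ``M`` individuals plays
public goods games in randomly sampled groups of ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

STRATEGIES: tuple[str, ...] = ("C", "D", "P", "L")


class ParameterError(ValueError):
    """Raised when game parameters violate the model's admissible region."""


@dataclass(frozen=True)
class GameParameters:
    """All game and dynamics constants.

    Parameters
    ----------
    M : population size.
    N : group size of a single public goods game, ``2 <= N <= M``.
    c : investment cost paid by each contributing participant.
    r : return coefficient on the common pool, ``1 < r < N``.
    sigma : loner income coefficient; a loner earns ``sigma * c``,
        with ``0 < sigma < r - 1``.
    alpha : probability that a punisher fines a defector in its group,
        in ``[0, 1]``.
    beta : fine inflicted on a defector per punisher.
    gamma : cost borne by a punisher per defector, ``gamma < beta``.
    kappa : responsiveness of strategy switching to payoff differences.
    epsilon : mutation/noise rate; must be positive for ergodicity.
    """

    M: int
    N: int
    c: float = 1.0
    r: float = 3.0
    sigma: float = 1.0
    alpha: float = 0.5
    beta: float = 1.0
    gamma: float = 0.3
    kappa: float = 1.0
    epsilon: float = 1e-2

    def __post_init__(self) -> None:
        if not (self.M >= self.N >= 2):
            raise ParameterError(f"require M >= N >= 2, got M={self.M}, N={self.N}")
        # The game is a social dilemma for 1 < r < N; the boundary r = N is
        # admitted since every payoff formula remains well defined there.
        if not (1.0 < self.r <= self.N):
            raise ParameterError(f"require 1 < r <= N, got r={self.r}, N={self.N}")
        if not (0.0 < self.sigma < self.r - 1.0):
            raise ParameterError(
                f"require 0 < sigma < r - 1, got sigma={self.sigma}, r={self.r}"
            )
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"require alpha in [0, 1], got {self.alpha}")
        if not (0.0 <= self.gamma < self.beta):
            raise ParameterError(
                f"require 0 <= gamma < beta, got gamma={self.gamma}, beta={self.beta}"
            )
        if self.c <= 0.0:
            raise ParameterError(f"require c > 0, got {self.c}")
        if self.kappa < 0.0:
            raise ParameterError(f"require kappa >= 0, got {self.kappa}")
        if self.epsilon <= 0.0:
            raise ParameterError(f"require epsilon > 0, got {self.epsilon}")

    def with_epsilon(self, epsilon: float) -> "GameParameters":
        """Return a copy with a different noise rate."""
        return replace(self, epsilon=epsilon)

    def with_game(self, **kwargs) -> "GameParameters":
        """Return a copy with some game constants replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationState:
    """A lattice point ``(i, j, k)``: counts of cooperators, defectors and
    punishers.  The loner count ``l = M - i - j - k`` is implied once a
    population size is given."""

    i: int
    j: int
    k: int

    def __post_init__(self) -> None:
        if min(self.i, self.j, self.k) < 0:
            raise ParameterError(f"negative strategy count in {self}")

    def validate(self, M: int) -> None:
        if self.i + self.j + self.k > M:
            raise ParameterError(f"{self} exceeds population size {M}")

    def loners(self, M: int) -> int:
        return M - self.i - self.j - self.k

    def participants(self) -> int:
        return self.i + self.j + self.k

    def count(self, strategy: str, M: int) -> int:
        if strategy == "C":
            return self.i
        if strategy == "D":
            return self.j
        if strategy == "P":
            return self.k
        if strategy == "L":
            return self.loners(M)
        raise KeyError(strategy)

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.i, self.j, self.k)


def state_space_size(M: int) -> int:
    """Number of states ``(i, j, k)`` with ``i + j + k <= M``."""
    return (M + 1) * (M + 2) * (M + 3) // 6
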