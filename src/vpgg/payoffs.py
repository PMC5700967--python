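"""Closed-form expected payoffs for the four strategies at a population state.

For a focal participant, the group it plays in is a random sample of
``N - 1`` other individuals drawn without replacement from the remaining
``M - 1``.  The number of co-participants is multivariate hypergeometric,
which admits the closed forms implemented here: a shared participation
term ``h * sigma * c + B`` (``h`` is the probability that all sampled
co-players are loners, in which case the game cannot happen and the focal
individual falls back on the loner income), a contribution cost ``Phi(l) * c``
for contributing strategies, an expected fine ``(k/(M-1)) (N-1) alpha beta``
for defectors and an expected sanctioning cost ``(j/(M-1)) (N-1) alpha gamma``
for punishers.

Boundary conventions:

* a loner always earns ``sigma * c``;
* if only one participant exists in the whole population (``i+j+k == 1``)
  it can never find co-players, so it too earns ``sigma * c``;
* a strategy with count zero has no well-defined game payoff and is
  assigned the count-weighted average payoff of the strategies present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import GameParameters, ParameterError, PopulationState


def binom(n: int, k: int) -> int:
    """Binomial coefficient extended by zero outside ``0 <= k <= n``."""
    if k < 0 or n < 0 or k > n:
        return 0
    return math.comb(n, k)


@dataclass(frozen=True)
class PayoffProfile:
    """Expected payoffs (payoff units) of the four strategies at one state."""

    pi_C: float
    pi_D: float
    pi_P: float
    pi_L: float

    def of(self, strategy: str) -> float:
        return {"C": self.pi_C, "D": self.pi_D, "P": self.pi_P, "L": self.pi_L}[
            strategy
        ]


def sample_participation_prob(
    params: GameParameters, state: PopulationState, S0: int
) -> float:
    """Probability that a focal participant's group contains exactly ``S0``
    participants (itself included), for ``1 <= S0 <= N``."""
    n_part = state.participants()
    if n_part == 0:
        raise ParameterError("no participant present; S0 is undefined")
    if not (1 <= S0 <= params.N):
        raise ParameterError(f"S0 must be in [1, N], got {S0}")
    l = state.loners(params.M)
    num = binom(n_part - 1, S0 - 1) * binom(l, params.N - S0)
    return num / binom(params.M - 1, params.N - 1)


def _h(params: GameParameters, l: int) -> float:
    """Probability that all N-1 sampled co-players are loners."""
    return binom(l, params.N - 1) / binom(params.M - 1, params.N - 1)


def _shared_benefit(params: GameParameters, state: PopulationState) -> float:
    """Common pool benefit B for a focal participant (cost not deducted)."""
    M, N, r, c = params.M, params.N, params.r, params.c
    l = state.loners(M)
    h = _h(params, l)
    return (
        r
        * c
        * (state.i + state.k)
        / (M - l - 1)
        * (1.0 - (M - (l - N + 1) * h) / (N * (M - l)))
    )


def contribution_cost_factor(params: GameParameters, l: int) -> float:
    """Phi(l): expected net cost, in units of c, of contributing rather
    than defecting, for a focal participant facing ``l`` loners."""
    M, N, r = params.M, params.N, params.r
    h = _h(params, l)
    return (
        1.0
        - (r / N) * (M - N) / (M - l - 1)
        + h * ((r / N) * (l + 1) / (M - l - 1) + r * (M - l - 2) / (M - l - 1) - 1.0)
    )


def population_average_payoff(
    params: GameParameters, state: PopulationState, partial: PayoffProfile
) -> float:
    """Count-weighted mean payoff over the strategies present at ``state``."""
    l = state.loners(params.M)
    total = (
        state.i * partial.pi_C
        + state.j * partial.pi_D
        + state.k * partial.pi_P
        + l * partial.pi_L
    )
    return total / params.M


def payoff_profile(params: GameParameters, state: PopulationState) -> PayoffProfile:
    """Expected payoff of each strategy at ``state``, with all boundary
    conventions applied; every state yields a finite profile."""
    state.validate(params.M)
    M, N, c, sigma = params.M, params.N, params.c, params.sigma
    l = state.loners(M)
    n_part = state.participants()
    loner_income = sigma * c

    if n_part == 0:
        return PayoffProfile(loner_income, loner_income, loner_income, loner_income)

    if n_part == 1:
        # The lone participant never finds co-players and is forced onto
        # the fixed loner income.
        pi_C = pi_D = pi_P = loner_income
    else:
        h = _h(params, l)
        B = _shared_benefit(params, state)
        base = h * loner_income + B
        phi_c = contribution_cost_factor(params, l) * c
        pi_C = base - phi_c
        pi_D = base - (state.k / (M - 1)) * (N - 1) * params.alpha * params.beta
        pi_P = base - phi_c - (state.j / (M - 1)) * (N - 1) * params.alpha * params.gamma

    partial = PayoffProfile(pi_C, pi_D, pi_P, loner_income)
    avg = population_average_payoff(params, state, partial)

    return PayoffProfile(
        pi_C if state.i > 0 else avg,
        pi_D if state.j > 0 else avg,
        pi_P if state.k > 0 else avg,
        loner_income if l > 0 else avg,
    )
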