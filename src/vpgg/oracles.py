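"""Independent brute-force reference implementations.

These deliberately avoid the closed forms and sparse machinery of the main
modules: payoffs are computed by exhaustive enumeration of every possible
sampled group in exact rational arithmetic, the stationary distribution by
dense null-space extraction, and long-run occupancy by event-driven
simulation.  They are shipped (not test-only) so any state's payoff or any
small generator's stationary vector can be audited, but are guarded by size
limits — they exist for validation, not production sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
from scipy import linalg

from .params import GameParameters, ParameterError, PopulationState
from .qbd import GeneratorMatrix
from .solver import Distribution

_MAX_ENUM_M = 12


def enumerate_expected_payoff(
    params: GameParameters, state: PopulationState, focal: str
) -> Fraction:
    """Exact expected payoff of a focal individual of strategy ``focal``.

    Sums over every composition of the ``N - 1`` co-players drawn without
    replacement from the other ``M - 1`` individuals (multivariate
    hypergeometric weights), applying the per-sample game payoff; the
    probabilistic fine/cost enters through its conditional expectation
    given the sample (``alpha * beta`` per punisher met by a defector,
    ``alpha * gamma`` per defector met by a punisher).  All arithmetic is
    rational, so agreement checks at 1e-12 are meaningful.
    """
    if params.M > _MAX_ENUM_M:
        raise ParameterError(
            f"enumeration oracle limited to M <= {_MAX_ENUM_M}, got M={params.M}"
        )
    state.validate(params.M)
    if state.count(focal, params.M) < 1:
        raise ParameterError(f"focal strategy {focal} absent from {state}")

    M, N = params.M, params.N
    c = Fraction(params.c)
    sigma = Fraction(params.sigma)
    r = Fraction(params.r)
    alpha = Fraction(params.alpha)
    beta = Fraction(params.beta)
    gamma = Fraction(params.gamma)

    if focal == "L":
        return sigma * c

    l = state.loners(M)
    # counts available as co-players after removing the focal individual
    rem = {
        "C": state.i - (focal == "C"),
        "D": state.j - (focal == "D"),
        "P": state.k - (focal == "P"),
        "L": l,
    }
    denom = comb(M - 1, N - 1)
    total = Fraction(0)
    weight_sum = Fraction(0)
    for nc in range(min(rem["C"], N - 1) + 1):
        for nd in range(min(rem["D"], N - 1 - nc) + 1):
            for np_ in range(min(rem["P"], N - 1 - nc - nd) + 1):
                nl = N - 1 - nc - nd - np_
                if nl > rem["L"]:
                    continue
                w = Fraction(
                    comb(rem["C"], nc)
                    * comb(rem["D"], nd)
                    * comb(rem["P"], np_)
                    * comb(rem["L"], nl),
                    denom,
                )
                if w == 0:
                    continue
                weight_sum += w
                # group composition including the focal individual
                n_C = nc + (focal == "C")
                n_D = nd + (focal == "D")
                n_P = np_ + (focal == "P")
                S0 = n_C + n_D + n_P
                if S0 == 1:
                    # no co-participants: the game cannot happen and the
                    # lone participant falls back on the loner income
                    payoff = sigma * c
                elif focal == "C":
                    payoff = r * c * (n_C + n_P) / S0 - c
                elif focal == "D":
                    payoff = r * c * (n_C + n_P) / S0 - alpha * beta * n_P
                else:  # focal == "P"
                    payoff = r * c * (n_C + n_P) / S0 - c - alpha * gamma * n_D
                total += w * payoff
    assert weight_sum == 1
    return total


def dense_stationary(gen: GeneratorMatrix) -> Distribution:
    """Stationary distribution by dense null space of Q^T; |S| <= 500."""
    n = gen.dim
    if n > 500:
        raise ParameterError(f"dense oracle limited to |S| <= 500, got {n}")
    ns = linalg.null_space(gen.Q.toarray().T)
    if ns.shape[1] != 1:
        raise ParameterError(
            f"generator null space has dimension {ns.shape[1]}, expected 1 "
            "(broken generator or epsilon = 0)"
        )
    v = ns[:, 0]
    v = v / v.sum()
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    residual = float(np.max(np.abs(v @ gen.Q)))
    return Distribution(
        v=v, indexer=gen.indexer, epsilon=gen.params.epsilon,
        iterations=0, residual=residual,
    )


@dataclass
class OccupancyEstimate:
    """Time-weighted state occupancy of a simulated trajectory."""

    fractions: np.ndarray
    total_time: float
    events: int
    seed: int

    def total_variation(self, dist: Distribution) -> float:
        return 0.5 * float(np.abs(self.fractions - dist.v).sum())


def gillespie_occupancy(
    gen: GeneratorMatrix,
    horizon: int,
    seed: int,
    start: tuple[int, int, int] | None = None,
) -> OccupancyEstimate:
    """Simulate the chain for ``horizon`` jump events and accumulate the
    fraction of time spent in each state.

    Exponential holding times use the state's total exit rate; the jump
    target is drawn from the normalized off-diagonal rates.  Bit-for-bit
    reproducible for a fixed seed.
    """
    if horizon < 1:
        raise ParameterError("horizon must be >= 1")
    n = gen.dim
    Q = gen.Q.tocsr()
    # flatten the (at most 12-wide) jump stencil per state
    max_deg = int(np.diff(Q.indptr).max())
    targets = np.zeros((n, max_deg), dtype=np.int64)
    cumprob = np.ones((n, max_deg), dtype=float)
    exit_rate = np.zeros(n, dtype=float)
    for s in range(n):
        row = Q.indices[Q.indptr[s] : Q.indptr[s + 1]]
        dat = Q.data[Q.indptr[s] : Q.indptr[s + 1]]
        off = row != s
        rates = dat[off]
        exit_rate[s] = rates.sum()
        csum = np.cumsum(rates) / rates.sum()
        targets[s, : len(csum)] = row[off]
        cumprob[s, : len(csum)] = csum

    rng = np.random.default_rng(seed)
    state = gen.indexer.index(start) if start is not None else 0
    time_in = np.zeros(n, dtype=float)

    chunk = 1_000_000
    done = 0
    while done < horizon:
        m = min(chunk, horizon - done)
        exp_u = rng.exponential(1.0, size=m)
        jump_u = rng.random(size=m)
        state = _simulate_block(
            state, exp_u, jump_u, targets, cumprob, exit_rate, time_in
        )
        done += m

    total = time_in.sum()
    return OccupancyEstimate(
        fractions=time_in / total, total_time=float(total),
        events=horizon, seed=seed,
    )


def _simulate_block_py(state, exp_u, jump_u, targets, cumprob, exit_rate, time_in):
    for t in range(exp_u.shape[0]):
        time_in[state] += exp_u[t] / exit_rate[state]
        u = jump_u[t]
        col = 0
        while cumprob[state, col] < u:
            col += 1
        state = targets[state, col]
    return state


try:  # pragma: no cover - thin jit wrapper
    from numba import njit

    _simulate_block = njit(cache=False)(_simulate_block_py)
except ImportError:  # pragma: no cover
    _simulate_block = _simulate_block_py
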