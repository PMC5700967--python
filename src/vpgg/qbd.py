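"""State indexing and assembly of the infinitesimal generator.

The strategy-count process is a continuous-time Markov chain on the lattice
``S = {(i, j, k) : i + j + k <= M}``.  Because individuals switch strategy
one at a time, the only transitions out of a state are the twelve
single-individual moves ``x -> y`` between distinct strategies, each at rate

    p_{x->y} = epsilon + kappa * max(pi_y - pi_x, 0).

Ordering states lexicographically in ``(i, j, k)`` makes the generator
block-tridiagonal in the cooperator count ``i`` — a (generalized)
quasi-birth-and-death structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .params import GameParameters, ParameterError, PopulationState, state_space_size
from .payoffs import PayoffProfile, payoff_profile

#: the twelve single-individual moves: (source, target, di, dj, dk)
MOVES: tuple[tuple[str, str, int, int, int], ...] = (
    ("C", "P", -1, 0, +1),
    ("C", "L", -1, 0, 0),
    ("C", "D", -1, +1, 0),
    ("D", "P", 0, -1, +1),
    ("D", "L", 0, -1, 0),
    ("D", "C", +1, -1, 0),
    ("P", "D", 0, +1, -1),
    ("P", "L", 0, 0, -1),
    ("P", "C", +1, 0, -1),
    ("L", "C", +1, 0, 0),
    ("L", "P", 0, 0, +1),
    ("L", "D", 0, +1, 0),
)


class StateIndexer:
    """Bijection between states ``(i, j, k)`` and indices ``0 .. |S|-1``,
    lexicographic in ``(i, j, k)`` so that level blocks over ``i`` are
    contiguous."""

    def __init__(self, M: int):
        if M < 2:
            raise ParameterError(f"require M >= 2, got {M}")
        self.M = M
        self.states: list[tuple[int, int, int]] = [
            (i, j, k)
            for i in range(M + 1)
            for j in range(M - i + 1)
            for k in range(M - i - j + 1)
        ]
        self._index = {s: n for n, s in enumerate(self.states)}

    def __len__(self) -> int:
        return len(self.states)

    def index(self, state: PopulationState | tuple[int, int, int]) -> int:
        if isinstance(state, PopulationState):
            state = state.as_tuple()
        return self._index[state]

    def state(self, n: int) -> PopulationState:
        return PopulationState(*self.states[n])

    def __contains__(self, ijk: tuple[int, int, int]) -> bool:
        return ijk in self._index


def transfer_rate(
    params: GameParameters, profile: PayoffProfile, x: str, y: str
) -> float:
    """Switching rate of one individual from strategy ``x`` to ``y``."""
    if x == y:
        raise ParameterError("transfer rate requires x != y")
    gain = profile.of(y) - profile.of(x)
    return params.epsilon + params.kappa * max(gain, 0.0)


@dataclass
class GeneratorMatrix:
    """Sparse infinitesimal generator Q with its state indexing."""

    Q: sparse.csr_matrix
    indexer: StateIndexer
    params: GameParameters

    @property
    def dim(self) -> int:
        return self.Q.shape[0]

    def rate(self, source: tuple[int, int, int], target: tuple[int, int, int]) -> float:
        return self.Q[self.indexer.index(source), self.indexer.index(target)]

    def to_dense(self) -> np.ndarray:
        return self.Q.toarray()

    def to_coo_records(self) -> list[tuple[int, int, float]]:
        """(row, col, rate) triples of the structural entries."""
        coo = self.Q.tocoo()
        return sorted(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))

    def export_dense_csv(self, path: str) -> None:
        """Debug export of Q as a dense CSV (small M only)."""
        if self.dim > 500:
            raise ParameterError("dense CSV export limited to |S| <= 500")
        header = ",".join("s%d_%d_%d" % s for s in self.indexer.states)
        np.savetxt(path, self.to_dense(), delimiter=",", header=header,
                   comments="", fmt="%.17g")

    def export_coo_tsv(self, path: str) -> None:
        """Debug export of the structural entries as (row, col, rate) TSV."""
        with open(path, "w") as fh:
            fh.write("row\tcol\trate\n")
            for r, c, v in self.to_coo_records():
                fh.write(f"{r}\t{c}\t{v:.17g}\n")


class GeneratorFactory:
    """Precomputed transition structure for one set of game constants.

    The payoff-driven part of every rate, ``kappa * max(pi_y - pi_x, 0)``,
    does not depend on the noise rate, so it is computed once per parameter
    set; :meth:`build` then assembles Q for any ``epsilon`` by adding the
    uniform noise term to each structural edge.
    """

    def __init__(self, params: GameParameters):
        self.params = params
        self.indexer = StateIndexer(params.M)
        n = len(self.indexer)
        M = params.M

        rows: list[int] = []
        cols: list[int] = []
        gains: list[float] = []

        for idx, (i, j, k) in enumerate(self.indexer.states):
            state = PopulationState(i, j, k)
            profile = payoff_profile(params, state)
            for x, y, di, dj, dk in MOVES:
                if state.count(x, M) < 1:
                    continue
                rows.append(idx)
                cols.append(self.indexer.index((i + di, j + dj, k + dk)))
                gains.append(
                    params.kappa * max(profile.of(y) - profile.of(x), 0.0)
                )

        self._rows = np.asarray(rows, dtype=np.int64)
        self._cols = np.asarray(cols, dtype=np.int64)
        self._gains = np.asarray(gains, dtype=float)
        self._degree = np.bincount(self._rows, minlength=n).astype(float)
        self._n = n
        assert n == state_space_size(M)

    def build(self, epsilon: float | None = None) -> GeneratorMatrix:
        params = (
            self.params if epsilon is None else self.params.with_epsilon(epsilon)
        )
        off = self._gains + params.epsilon
        diag = -(
            np.bincount(self._rows, weights=off, minlength=self._n)
        )
        rows = np.concatenate([self._rows, np.arange(self._n)])
        cols = np.concatenate([self._cols, np.arange(self._n)])
        vals = np.concatenate([off, diag])
        Q = sparse.csr_matrix((vals, (rows, cols)), shape=(self._n, self._n))
        return GeneratorMatrix(Q=Q, indexer=self.indexer, params=params)


def build_generator(params: GameParameters) -> GeneratorMatrix:
    """Assemble Q in one pass over the state space.

    Each admissible move (source strategy count >= 1) contributes the bare
    switching rate ``p_{x->y}`` as the off-diagonal entry to the neighbour
    state; the diagonal is the negative row sum so that Q 1 = 0.
    """
    return GeneratorFactory(params).build()
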