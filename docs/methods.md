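# Methods

## Model and assumptions

The population is finite (`M` individuals), well mixed, and holds four
pure strategies: cooperator (C), defector (D), punisher (P) and loner (L).
Play is by random group formation: `N` individuals are drawn without
replacement, participants (C, D, P) each invest `c`, the pool is multiplied
by `r` and split equally among the `S` participants in the group, and
loners take the outside option `σc`. Punishment is probabilistic peer
punishment: independently for each punisher–defector pair in a group, with
probability `α` the defector pays `β` and the punisher pays `γ`. A group
with a single participant cannot play; that participant receives `σc`,
like a loner.

Payoffs are *expected* payoffs over group composition (multivariate
hypergeometric, focal individual excluded from the draw) and over the
punishment coin flips. Realized-payoff variance is deliberately not
modeled. The closed forms used by the package are:

- shared participation term `h·σc + B`, with
  `h = C(l, N−1)/C(M−1, N−1)` the probability that every sampled co-player
  is a loner, and `B` the expected pool share of a focal participant;
- cooperators and punishers additionally pay the contribution cost
  `Φ(l)·c`, where `Φ(l)` is the expected net cost of contributing rather
  than defecting;
- defectors pay the expected fine `(k/(M−1))(N−1)αβ`, punishers the
  expected sanctioning cost `(j/(M−1))(N−1)αγ`. These use the expected
  number of sampled punishers/defectors directly; by linearity of
  expectation this is exact, which the enumeration oracle confirms at
  1e-12.

Binomial coefficients with out-of-range arguments are taken as zero, which
makes the closed forms valid on every lattice boundary without case
splits. Two conventions close the remaining gaps: a population with a
single participant (`i+j+k = 1`) forces that participant onto `σc`
(the closed forms are 0/0 there), and a strategy with count zero — whose
game payoff is undefined — is assigned the count-weighted mean payoff of
the strategies present. When several strategies are absent simultaneously
the same count-weighted mean over present types is used; this is a design
choice (an unweighted mean over the defined values would differ), made
because "average payoff of the population" reads most literally as the
per-capita mean.

## Dynamics

Strategy revision is asynchronous (one individual at a time), myopic, and
noisy: the switch rate from `x` to `y` at state `(i, j, k)` is
`ε + κ·max(π_y − π_x, 0)` whenever at least one `x`-individual exists.
Rates are *per move*, not multiplied by the source-strategy count: the
twelve admissible single-individual moves each carry the bare rate above.
Scaling by abundance is a common alternative; the per-move form is the
model this package implements, and changing it changes the stationary law.

The count process is then a continuous-time Markov chain whose generator
`Q` is block-tridiagonal in the cooperator count (a generalized
quasi-birth-and-death process), assembled sparsely in one pass over the
`(M+1)(M+2)(M+3)/6` states with the diagonal fixed by `Q·1 = 0`. Because
every structural edge has rate ≥ ε > 0 and each move has its reverse move,
the chain is irreducible, hence ergodic with a unique stationary
distribution `v^ε`.

## Solvers

`stationary_distribution` defaults to Gauss–Seidel sweeps on the singular
balance system `Qᵀx = 0`: with `Qᵀ = L + D + U`, iterate
`(D + L)x⁺ = −Ux` (one sparse lower-triangular solve per sweep),
renormalize, and stop when the successive-iterate max-norm change falls
below `tol` (default 1e-12, max 1e6 sweeps). The sweep map is nonnegative
and its normalized iterates converge to the unique stationary vector for
an irreducible generator. A `method="direct"` path solves the same system
by one sparse LU factorization with the last balance equation replaced by
the normalization `Σx = 1` (minimum-degree column ordering); it is used by
the sweep driver because it is ~7× faster at M=20 (~0.07 s vs ~1.1 s per
solve) and agrees with Gauss–Seidel to below 1e-10. Both are checked in
the test suite against a dense null-space solution (M ≤ 6, agreement
1e-8) and against event-driven simulation (M=8, total-variation < 0.02
after 1e7 events).

## Small-noise limit and SSE identification

The stochastically stable equilibria are the states with positive mass in
`lim_{ε→0⁺} v^ε`. The limit is approximated along the decreasing schedule
`ε ∈ {1e-2, 1e-3, …, 1e-8}` (each solve warm-startable from the previous
one in the Gauss–Seidel path), stopping when the three aggregate class
masses (all-L, all-D, C+P) each move by less than `agg_tol = 1e-3`
between consecutive rungs; exhausting the schedule without settling raises
an error carrying the last two aggregate vectors. The schedule reaches
1e-8 because for the reference population (M=20, N=4) aggregate masses
measurably drift until ε ≈ 1e-6–1e-7. Since strictly positive limit mass
is not decidable in floating point, the SSE set uses the same `agg_tol`
as its per-state threshold. The aggregate classes are: all-L
`{(0,0,0), (0,0,1), (0,1,0), (1,0,0)}` (a single participant can never
play, so these are all effectively universal non-participation), all-D
`(0, M, 0)`, and the cooperator–punisher edge `{(i, 0, M−i)}`.

## Oracles

Three independent reference implementations ship with the package (size
guarded; for audit and testing, not production): exhaustive enumeration of
every group composition in exact rational arithmetic (M ≤ 12), dense
null-space extraction of the stationary vector (|S| ≤ 500), and a seeded
Gillespie simulator (exponential holding times, categorical jumps;
bit-reproducible per seed, numba-accelerated). The enumeration oracle
makes the 1e-12 closed-form comparisons meaningful; the simulator ties the
generator's semantics to trajectory behaviour.

## Parameter-plane sweeps

Sweeps cover `1.1 ≤ r < N`, `0 < σ < r − 1` on rectangular grids (default
steps 0.25, configurable). The degenerate boundary `σ = r − 1` — where the
loner income ties the all-cooperator group payoff and neutral drift keeps
mass off the candidate states — is excluded with a 1e-9 guard so float
rounding cannot place grid points on it. The reproduction script uses
steps of 0.1 for both axes: the peak of the all-L mass sits in the
small-σ, small-r corner (near r ≈ 1.2, σ ≈ 0.1), which a 0.25 grid never
samples (its smallest σ is 0.25), biasing corner maxima downward by ~0.1.
Grid cells are independent; solver failures are recorded per cell and the
sweep continues.

## Numerical choices and limitations

- Payoffs in the main path are IEEE double; the oracle is exact rational;
  comparison tolerance 1e-12.
- Aggregate masses are not provably monotone in ε; the test suite checks
  monotone concentration of candidate mass empirically on a small
  population rather than asserting it as a theorem.
- The ε→0 limit is numerical, not a Freidlin–Wentzell resistance-tree
  computation; results at phase boundaries in `(r, σ)` depend on how far
  the schedule descends (`agg_tol` controls this).
- Problem sizes in the test suite are deliberately modest — payoff
  equivalence at M ≤ 8, solver cross-checks at M ≤ 8, candidate-support
  sweeps on the 0.25 grid — chosen to exercise every code path while
  keeping the suite fast; the reproduction script runs the full-size
  (M=20) sweeps on the 0.1 grid.
- Discrete-time embedded-chain analysis, fixation probabilities,
  weak-selection approximations and spatial/network structure are out of
  scope.
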