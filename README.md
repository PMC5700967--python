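# vpgg — stochastic stability in the voluntary public goods game with punishment

`vpgg` computes the long-run behaviour of a finite, well-mixed population
playing an optional public goods game with probabilistic peer punishment.
It is aimed at researchers in evolutionary game theory who want exact
small-noise equilibrium selection — which strategy configurations a noisy
adaptive population actually settles on — rather than deterministic
replicator or fixation-probability approximations.

## Model

A population of `M` individuals holds one of four strategies: cooperator
(C), defector (D), punisher (P) or loner (L). Groups of `N` players are
sampled at random; participants (C, D, P) invest `c` into a common pool
multiplied by `r` (`1 < r ≤ N`) and shared among the `S` participants,
loners take a fixed income `σc` (`0 < σ < r − 1`), and each punisher fines
each defector in its group with probability `α` (fine `β` per punisher,
cost `γ < β` per defector punished). A group with a single participant
cannot play and that participant also earns `σc`.

With counts `(i, j, k)` (loners `l = M − i − j − k`), group composition is
multivariate hypergeometric and expected payoffs have closed forms, e.g.

    π_D = h·σc + B − (k/(M−1))(N−1)αβ,      h = C(l, N−1) / C(M−1, N−1),

with a shared pool term `B` and a contribution-cost factor `Φ(l)` such that
the no-punishment defection premium is `π_D − π_C = Φ(l)·c`.

Individuals revise strategies one at a time: the switch rate from `x` to
`y` is `ε + κ·max(π_y − π_x, 0)`, where `ε > 0` is noise and `κ` the
responsiveness. The count process is then an ergodic continuous-time
Markov chain on the `(M+1)(M+2)(M+3)/6` states whose generator is
block-tridiagonal in `i` — a generalized quasi-birth-and-death process.
Its stationary distribution `v^ε` (solved by Gauss–Seidel sweeps or a
direct sparse factorization) is tracked along a decreasing noise schedule;
the states keeping positive mass as `ε → 0⁺` are the stochastically stable
equilibria (SSE). Empirically all limit mass concentrates on 26 candidate
states: the four "all L" states, the "all D" state `(0, M, 0)`, and the
cooperator–punisher edge `(i, 0, M−i)`.

## Worked example

Expected payoffs at a state are available from the library or the CLI:

```bash
$ vpgg payoff --M 3 --N 2 --r 2 --c 1 --sigma 0.5 --state 1,1,0
{
 "state": {"i": 1, "j": 1, "k": 0, "l": 1},
 "pi_C": 0.25,
 "pi_D": 0.75,
 "pi_P": 0.5,
 "pi_L": 0.5
}
```

The defector meets the cooperator or the loner with equal probability,
earning the full pool share `rc/2 = 1` or the fallback `σc = 0.5`, hence
`π_D = 0.75`; the cooperator nets `0.25`; and the defection premium is the
contribution-cost factor `Φ(1)·c = 0.5`.

Equilibrium selection for the reference population (`M=20, N=4, c=1, κ=1,
β=1`) with moderate punishment (`α=0.5, γ=0.3`) at `r=3, σ=1`:

```python
from vpgg import GameParameters, limit_distribution

p = GameParameters(M=20, N=4, c=1, kappa=1, beta=1,
                   alpha=0.5, gamma=0.3, r=3.0, sigma=1.0)
report = limit_distribution(p)
print(report.aggregates)
# {'all_L': 0.055799, 'all_D': 7.7e-05, 'c_plus_p': 0.944044, 'other': 8.1e-05}
```

The population is driven to the cooperator–punisher edge with probability
0.944: punishment at only 50% probability suffices to make cooperative
states the overwhelmingly most likely long-run outcome at these returns.
The same report lists the individual SSE states; here the mass is spread
along `(i, 0, 20−i)` with the mode near half cooperators, half punishers.

Phase diagrams over the `(r, σ)` plane at fixed `(α, γ)`:

```bash
vpgg sweep --M 20 --N 4 --alpha 1 --gamma 0.3 --r-step 0.25 --sigma-step 0.25 --out sweep.csv
vpgg verify            # oracle cross-checks (enumeration, dense solve, simulation)
```

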