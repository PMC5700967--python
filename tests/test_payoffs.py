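"""Closed-form payoffs: worked examples, boundary conventions and the
identities that pin the formulas down."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpgg import (
    GameParameters,
    ParameterError,
    PopulationState,
    payoff_profile,
    population_average_payoff,
    sample_participation_prob,
)
from vpgg.payoffs import PayoffProfile, contribution_cost_factor

from conftest import all_states, random_valid_params


class TestSampleParticipationProb:
    def test_two_participants_among_four(self):
        # M=4, N=2, two participants, two loners: the lone co-player drawn
        # for a focal participant is a loner with probability 2/3.
        p = GameParameters(M=4, N=2, r=1.5, sigma=0.3)
        s = PopulationState(1, 1, 0)
        assert sample_participation_prob(p, s, 1) == pytest.approx(2 / 3)
        assert sample_participation_prob(p, s, 2) == pytest.approx(1 / 3)

    def test_no_loners_means_full_participation(self):
        p = GameParameters(M=6, N=3, r=2.0, sigma=0.5)
        s = PopulationState(2, 2, 2)
        assert sample_participation_prob(p, s, p.N) == 1.0
        for S0 in range(1, p.N):
            assert sample_participation_prob(p, s, S0) == 0.0

    def test_distribution_sums_to_one(self, rng):
        for M, N in [(4, 2), (6, 3), (8, 4)]:
            p = random_valid_params(rng, M, N)
            for ijk in all_states(M):
                s = PopulationState(*ijk)
                if s.participants() == 0:
                    continue
                total = sum(
                    sample_participation_prob(p, s, S0) for S0 in range(1, N + 1)
                )
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_no_participant_is_domain_error(self):
        p = GameParameters(M=4, N=2, r=1.5, sigma=0.3)
        with pytest.raises(ParameterError):
            sample_participation_prob(p, PopulationState(0, 0, 0), 1)


class TestPayoffProfile:
    def test_worked_example_one_cooperator_one_defector(self):
        # M=3, N=2: the defector earns the full pool share when paired with
        # the cooperator and sigma*c when paired with the loner.
        p = GameParameters(M=3, N=2, r=2.0, c=1.0, sigma=0.5)
        prof = payoff_profile(p, PopulationState(1, 1, 0))
        assert prof.pi_D == pytest.approx(0.75)
        assert prof.pi_C == pytest.approx(0.25)
        assert prof.pi_L == pytest.approx(0.5)
        # their gap is the contribution cost factor Phi(l) times c
        assert prof.pi_D - prof.pi_C == pytest.approx(
            contribution_cost_factor(p, 1) * p.c
        )

    def test_loner_always_earns_fixed_income(self, rng):
        p = random_valid_params(rng, 7, 3)
        for ijk in all_states(7):
            s = PopulationState(*ijk)
            if s.loners(7) >= 1:
                assert payoff_profile(p, s).pi_L == pytest.approx(p.sigma * p.c)

    def test_lone_participant_forced_to_loner_income(self, rng):
        for strat_state in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            p = random_valid_params(rng, 6, 3)
            prof = payoff_profile(p, PopulationState(*strat_state))
            assert prof.pi_C == pytest.approx(p.sigma * p.c)
            assert prof.pi_D == pytest.approx(p.sigma * p.c)
            assert prof.pi_P == pytest.approx(p.sigma * p.c)

    def test_no_punishment_makes_cooperators_and_punishers_equal(self, rng):
        p = random_valid_params(rng, 8, 4).with_game(alpha=0.0)
        for ijk in all_states(8):
            s = PopulationState(*ijk)
            if s.i >= 1 and s.k >= 1:
                prof = payoff_profile(p, s)
                assert prof.pi_C == pytest.approx(prof.pi_P, abs=1e-12)

    def test_defection_premium_is_phi_minus_expected_fine(self, rng):
        # pi_D - pi_C = Phi(l) c - (k/(M-1)) (N-1) alpha beta wherever both
        # strategies are present with at least two participants total.
        M = 8
        p = random_valid_params(rng, M, 4)
        for ijk in all_states(M):
            s = PopulationState(*ijk)
            if s.i >= 1 and s.j >= 1 and s.participants() >= 2:
                prof = payoff_profile(p, s)
                expected = contribution_cost_factor(p, s.loners(M)) * p.c - (
                    s.k / (M - 1)
                ) * (p.N - 1) * p.alpha * p.beta
                assert prof.pi_D - prof.pi_C == pytest.approx(expected, abs=1e-12)

    def test_exchange_symmetry_without_punishment(self, rng):
        # with alpha = 0 cooperators and punishers are interchangeable
        M = 7
        p = random_valid_params(rng, M, 3).with_game(alpha=0.0)
        for ijk in all_states(M):
            i, j, k = ijk
            a = payoff_profile(p, PopulationState(i, j, k))
            b = payoff_profile(p, PopulationState(k, j, i))
            assert a.pi_C == pytest.approx(b.pi_P, abs=1e-12)
            assert a.pi_P == pytest.approx(b.pi_C, abs=1e-12)
            assert a.pi_D == pytest.approx(b.pi_D, abs=1e-12)
            assert a.pi_L == pytest.approx(b.pi_L, abs=1e-12)

    @given(
        M=st.integers(2, 10),
        data=st.data(),
        r=st.floats(1.05, 4.0),
        frac=st.floats(1e-3, 0.999),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_every_state_yields_finite_profile(self, M, data, r, frac, alpha):
        N = data.draw(st.integers(2, min(M, 4)))
        r = min(r, float(N))
        sigma = frac * (r - 1.0)
        p = GameParameters(M=M, N=N, r=r, sigma=sigma, alpha=alpha)
        i = data.draw(st.integers(0, M))
        j = data.draw(st.integers(0, M - i))
        k = data.draw(st.integers(0, M - i - j))
        prof = payoff_profile(p, PopulationState(i, j, k))
        for v in (prof.pi_C, prof.pi_D, prof.pi_P, prof.pi_L):
            assert math.isfinite(v)


class TestPopulationAverage:
    def test_all_loners(self):
        p = GameParameters(M=6, N=3, r=2.0, sigma=0.5)
        prof = payoff_profile(p, PopulationState(0, 0, 0))
        assert prof.pi_C == prof.pi_D == prof.pi_P == prof.pi_L == 0.5

    def test_single_present_type_sets_all_payoffs(self):
        p = GameParameters(M=6, N=3, r=2.0, sigma=0.5)
        prof = payoff_profile(p, PopulationState(0, 6, 0))
        assert prof.pi_C == prof.pi_D == prof.pi_P == prof.pi_L

    def test_equal_counts_average(self):
        p = GameParameters(M=6, N=3, r=2.0, sigma=0.5)
        partial = PayoffProfile(pi_C=2.0, pi_D=1.0, pi_P=0.0, pi_L=0.0)
        avg = population_average_payoff(p, PopulationState(3, 3, 0), partial)
        assert avg == pytest.approx(1.5)

    def test_absent_strategies_get_count_weighted_mean(self):
        p = GameParameters(M=4, N=2, r=1.8, sigma=0.5)
        s = PopulationState(3, 0, 0)  # 3 cooperators, 1 loner
        prof = payoff_profile(p, s)
        mean = (3 * prof.pi_C + 1 * prof.pi_L) / 4
        assert prof.pi_D == pytest.approx(mean)
        assert prof.pi_P == pytest.approx(mean)
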