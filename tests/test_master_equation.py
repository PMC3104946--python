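"""Generators, master-equation solvers, and the validation backends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hilladair import (
    AdairRates,
    HillRates,
    adair_transitions,
    build_generator,
    enumerate_adair_space,
    enumerate_hill_space,
    evolve,
    evolve_laplace_durbin,
    hill_transitions,
    initial_distribution,
    initial_state_escape_rate,
    simulate_ssa,
    stationary_distribution,
)


class TestTransitions:
    def test_hill_forward_counts_ligand_combinations(self):
        # binding all h=2 ligands at once: rate alpha * n0 * C(nA, 2)
        trs = hill_transitions((2, 0, 5), HillRates(0.5, 0.25), h=2)
        assert trs == [((1, 1, 3), pytest.approx(0.5 * 2 * 10))]

    def test_hill_back_only_when_fully_bound(self):
        trs = hill_transitions((0, 2, 1), HillRates(0.5, 0.25), h=2)
        assert trs == [((1, 1, 3), pytest.approx(0.5))]

    def test_hill_forward_infeasible_when_too_few_ligands(self):
        assert hill_transitions((2, 0, 1), HillRates(1.0, 1.0), h=2) == []

    def test_adair_initial_state_single_channel(self):
        rates = AdairRates((1.0, 10.0), (10.0, 1.0))
        trs = adair_transitions((2, 0, 0, 5), rates)
        assert trs == [((1, 1, 0, 4), pytest.approx(10.0))]

    def test_adair_intermediate_state_three_channels(self):
        rates = AdairRates((1.0, 10.0), (10.0, 1.0))
        trs = dict(adair_transitions((1, 1, 0, 4), rates))
        assert trs == {
            (0, 2, 0, 3): pytest.approx(4.0),   # step-1 forward
            (2, 0, 0, 5): pytest.approx(10.0),  # step-1 back
            (1, 0, 1, 3): pytest.approx(40.0),  # step-2 forward
        }

    def test_adair_fully_bound_back_only(self):
        rates = AdairRates((1.0, 1.0), (1.0, 1.0))
        trs = adair_transitions((0, 0, 2, 1), rates)
        assert trs == [((0, 1, 1, 2), pytest.approx(2.0))]


class TestGenerator:
    def test_hill_generator_is_tridiagonal(self):
        space = enumerate_hill_space(2, 2, 5)
        Q = build_generator(space, HillRates(0.5, 0.25))
        assert Q.shape == (3, 3)
        for i in range(3):
            for j in range(3):
                if abs(i - j) > 1:
                    assert Q[i, j] == 0.0

    def test_adair_generator_edge_count(self):
        # 6 reversible elementary transitions -> 12 directed edges; verify
        # against an independent pairwise reachability count
        space = enumerate_adair_space(2, 2, 5)
        Q = build_generator(space, AdairRates((1.0, 1.0), (1.0, 1.0)))
        edges = 0
        for a in space:
            for b in space:
                if a == b:
                    continue
                # one elementary step moves one ligand between A and a protein
                docc = [y - x for x, y in zip(a[:-1], b[:-1])]
                if (
                    abs(b[-1] - a[-1]) == 1
                    and sorted(docc) == [-1, 0, 1]
                    and abs(docc.index(1) - docc.index(-1)) == 1
                ):
                    edges += 1
        assert edges == 12
        assert np.count_nonzero(Q - np.diag(np.diag(Q))) == edges

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        h=st.integers(1, 4),
        p0=st.integers(1, 3),
        l0=st.integers(1, 8),
        rates=st.lists(st.floats(0.01, 100), min_size=8, max_size=8),
    )
    def test_columns_sum_to_zero_and_offdiagonals_nonnegative(self, h, p0, l0, rates):
        space = enumerate_adair_space(h, p0, l0)
        Q = build_generator(space, AdairRates(tuple(rates[:h]), tuple(rates[4 : 4 + h])))
        assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)


class TestEvolve:
    def test_t0_is_identity(self, h2_spaces, weak_coop_rates):
        _, adair, _ = h2_spaces
        Q = build_generator(adair, weak_coop_rates)
        p0 = initial_distribution(adair)
        traj = evolve(Q, p0, [0.0])
        assert np.array_equal(traj.distributions[0], p0)

    def test_probability_conserved_both_models(self, h2_spaces, strong_coop_rates):
        hill, adair, _ = h2_spaces
        times = np.linspace(0, 5, 51)
        for space, rates in [
            (hill, HillRates(0.5, 0.25)),
            (adair, strong_coop_rates),
        ]:
            traj = evolve(build_generator(space, rates), initial_distribution(space), times)
            assert np.all(traj.distributions >= 0)
            assert np.allclose(traj.distributions.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_ssa_oracle(self, h2_spaces, strong_coop_rates):
        """Master-equation solution vs a 1e5-replicate Gillespie estimate."""
        _, adair, _ = h2_spaces
        Q = build_generator(adair, strong_coop_rates)
        p0 = initial_distribution(adair)
        ref = evolve(Q, p0, [1.0]).distributions[0]
        emp = simulate_ssa(adair, strong_coop_rates, p0, 1.0, 100_000, seed=20111)
        tv = 0.5 * np.abs(emp - ref).sum()
        assert tv < 0.01
        # per-state: within 3 Monte-Carlo standard errors (plus tiny floor)
        se = np.sqrt(ref * (1 - ref) / 100_000)
        assert np.all(np.abs(emp - ref) <= 3 * se + 1e-4)


class TestDurbinBackend:
    def test_agrees_with_expm_within_one_percent(self, h2_spaces, weak_coop_rates):
        _, adair, _ = h2_spaces
        Q = build_generator(adair, weak_coop_rates)
        p0 = initial_distribution(adair)
        times = [0.1, 0.25, 1.0, 5.0]
        ref = evolve(Q, p0, times).distributions
        alt = evolve_laplace_durbin(Q, p0, times).distributions
        mask = ref > 1e-6
        assert np.max(np.abs(alt - ref)[mask] / ref[mask]) < 0.01

    def test_t0_returns_initial_distribution(self, h2_spaces, weak_coop_rates):
        _, adair, _ = h2_spaces
        Q = build_generator(adair, weak_coop_rates)
        p0 = initial_distribution(adair)
        traj = evolve_laplace_durbin(Q, p0, [0.0])
        assert np.allclose(traj.distributions[0], p0, atol=1e-2)

    def test_single_state_space_is_constant(self):
        space = enumerate_hill_space(2, 0, 5)
        Q = build_generator(space, HillRates(1.0, 1.0))
        traj = evolve_laplace_durbin(Q, np.ones(1), [0.5, 2.0])
        assert np.allclose(traj.distributions, 1.0, atol=1e-6)


class TestStationary:
    def test_single_state(self):
        space = enumerate_hill_space(2, 0, 5)
        Q = build_generator(space, HillRates(1.0, 1.0))
        assert np.array_equal(stationary_distribution(Q), [1.0])

    def test_hill_detailed_balance_closed_form(self):
        """1-D birth-death chain: pi(i+1)/pi(i) = fwd(i)/back(i+1) exactly."""
        space = enumerate_hill_space(2, 2, 5)
        rates = HillRates(0.5, 0.25)
        Q = build_generator(space, rates)
        pi = stationary_distribution(Q)
        from math import comb

        w = [1.0]
        for i in range(len(space) - 1):
            n0, _, nA = space.states[i]
            fwd = rates.alpha * n0 * comb(nA, 2)
            back = rates.beta * (i + 1)
            w.append(w[-1] * fwd / back)
        closed = np.array(w) / sum(w)
        assert np.allclose(pi, closed, atol=1e-13)

    def test_long_time_limit(self, h2_spaces, weak_coop_rates):
        _, adair, _ = h2_spaces
        Q = build_generator(adair, weak_coop_rates)
        rates = np.abs(Q[Q != 0])
        t_long = 1e4 / rates.min()
        late = evolve(Q, initial_distribution(adair), [t_long]).distributions[0]
        assert np.allclose(late, stationary_distribution(Q), atol=1e-8)


class TestEscapeRate:
    def test_hill_and_adair_lifetimes_match_after_calibration(self):
        hill = enumerate_hill_space(2, 2, 5)
        adair = enumerate_adair_space(2, 2, 5)
        Qh = build_generator(hill, HillRates(0.5, 0.25))
        Qa = build_generator(adair, AdairRates((1.0, 1.0), (1.0, 1.0)))
        rh = initial_state_escape_rate(Qh, hill.index_of(hill.initial_state))
        ra = initial_state_escape_rate(Qa, adair.index_of(adair.initial_state))
        assert rh == pytest.approx(10.0)
        assert ra == pytest.approx(10.0)

    def test_no_proteins_means_no_escape(self):
        space = enumerate_hill_space(2, 0, 5)
        Q = build_generator(space, HillRates(1.0, 1.0))
        assert initial_state_escape_rate(Q, 0) == 0.0


class TestSSA:
    def test_rate_free_system_stays_put(self):
        space = enumerate_hill_space(2, 2, 1)  # nA < h: no forward reaction
        p0 = initial_distribution(space)
        emp = simulate_ssa(space, HillRates(1.0, 1.0), p0, 10.0, 1000, seed=1)
        assert np.array_equal(emp, p0)

    def test_fixed_seed_reruns_bit_identical(self, h2_spaces, weak_coop_rates):
        _, adair, _ = h2_spaces
        p0 = initial_distribution(adair)
        a = simulate_ssa(adair, weak_coop_rates, p0, 1.0, 5000, seed=7)
        b = simulate_ssa(adair, weak_coop_rates, p0, 1.0, 5000, seed=7)
        assert np.array_equal(a, b)


def test_rate_validation():
    with pytest.raises(ValueError):
        HillRates(0.0, 1.0)
    with pytest.raises(ValueError):
        HillRates(1.0, -1.0)
    with pytest.raises(ValueError):
        AdairRates((1.0, 0.0), (1.0, 1.0))
    with pytest.raises(ValueError):
        AdairRates((1.0,), (1.0, 1.0))
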