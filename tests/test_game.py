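"""Game engine: softmax allocation, per-game payoffs, normalization bound
and the three synchronous strategy-update rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pggalloc import game, netgen
from pggalloc.game import (
    GameParams,
    allocate_investments,
    capital_per_node,
    compute_payoffs,
    initial_state,
    normalization_constant,
    pair_index,
    step,
    update_strategies_fermi,
    update_strategies_replicator,
    update_strategies_unconditional_imitation,
)


def path2():
    return netgen.Graph(2, [(0, 1)])


def path3():
    return netgen.Graph(3, [(0, 1), (1, 2)])


def row_sums(state, g):
    row_ptr, _, _ = g.games()
    return np.add.reduceat(state.I, row_ptr[:-1])


class TestParams:
    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(r=-1.0), "r"),
            (dict(r=2.0, c=0.0), "c"),
            (dict(r=2.0, alpha=-0.1), "alpha"),
            (dict(r=2.0, scheme="bogus"), "scheme"),
            (dict(r=2.0, update_rule="bogus"), "update_rule"),
            (dict(r=2.0, update_rule="fermi", beta=0.0), "beta"),
        ],
    )
    def test_validation_names_the_offending_field(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            GameParams(**kwargs)


class TestInitialState:
    def test_coop_prob_one_gives_all_cooperators(self, wheel5):
        st_ = initial_state(wheel5, GameParams(r=2.0), seed=0, coop_prob=1.0)
        assert st_.s.all()

    def test_fcp_even_split(self):
        # degree-3 node plays 4 games; capital 1 splits to 0.25 each
        g = netgen.make_wheel(3)  # K4, every degree 3
        st_ = initial_state(g, GameParams(r=2.0, c=1.0, scheme="FCP"), seed=0)
        assert np.allclose(st_.I, 0.25)

    def test_fcg_even_split_is_c_per_game(self):
        g = netgen.make_wheel(3)
        st_ = initial_state(g, GameParams(r=2.0, c=1.0, scheme="FCG"), seed=0)
        assert np.allclose(st_.I, 1.0)

    def test_payoffs_start_at_zero(self, small_ucm, default_params):
        st_ = initial_state(small_ucm, default_params, seed=1)
        assert not st_.Pi_pair.any() and not st_.Pi_tot.any()


class TestAllocation:
    def test_alpha_zero_is_even_split_for_any_payoffs(self, small_ucm):
        p = GameParams(r=4.0, alpha=0.0)
        st_ = initial_state(small_ucm, p, seed=0)
        st_.Pi_pair = np.random.default_rng(1).normal(size=st_.Pi_pair.size)
        allocate_investments(st_, small_ucm, p)
        _, row, _ = small_ucm.games()
        expected = (1.0 / (small_ucm.degrees + 1))[row]
        assert np.allclose(st_.I, expected, atol=1e-12)

    def test_two_game_softmax_hand_value(self):
        # payoffs (1, 0) at alpha=1: shares (e/(e+1), 1/(e+1))
        g = path2()
        p = GameParams(r=2.0, alpha=1.0)
        st_ = initial_state(g, p, seed=0)
        st_.Pi_pair = np.array([1.0, 0.0, 0.0, 0.0])  # node 0's games first
        allocate_investments(st_, g, p)
        e = np.e
        assert st_.I[0] == pytest.approx(e / (e + 1), abs=1e-12)
        assert st_.I[1] == pytest.approx(1 / (e + 1), abs=1e-12)

    def test_three_game_softmax_hand_value(self):
        # payoffs (2, 0, 0) at alpha=4: first share 1/(1 + 2 e^-8)
        g = path3()
        p = GameParams(r=2.0, alpha=4.0)
        st_ = initial_state(g, p, seed=0)
        i0 = pair_index(g, 1, 0)
        st_.Pi_pair[:] = 0.0
        st_.Pi_pair[i0] = 2.0
        allocate_investments(st_, g, p)
        assert st_.I[i0] == pytest.approx(1 / (1 + 2 * np.exp(-8)), rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 4.0])
    @pytest.mark.parametrize("scheme", ["FCP", "FCG"])
    def test_rows_sum_to_capital(self, small_ucm, alpha, scheme):
        p = GameParams(r=4.0, alpha=alpha, scheme=scheme)
        st_ = initial_state(small_ucm, p, seed=2)
        st_.Pi_pair = np.random.default_rng(3).normal(scale=2.0, size=st_.Pi_pair.size)
        allocate_investments(st_, small_ucm, p)
        cap = capital_per_node(small_ucm, p)
        assert np.allclose(row_sums(st_, small_ucm), cap, atol=1e-9)
        assert np.all(st_.I >= 0)

    @given(shift=st.floats(-500, 500), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_softmax_shift_invariance(self, shift, seed):
        """Adding a constant to all of one player's payoffs leaves her
        allocation unchanged (guards the row-max stabilization)."""
        g = netgen.make_wheel(4)
        p = GameParams(r=3.0, alpha=2.0)
        st_ = initial_state(g, p, seed=0)
        st_.Pi_pair = np.random.default_rng(seed).normal(size=st_.Pi_pair.size)
        allocate_investments(st_, g, p)
        base = st_.I.copy()
        row_ptr, _, _ = g.games()
        st_.Pi_pair[row_ptr[0]:row_ptr[1]] += shift
        allocate_investments(st_, g, p)
        assert np.allclose(st_.I, base, rtol=1e-9, atol=1e-12)

    def test_extreme_payoffs_stay_finite(self, wheel5):
        p = GameParams(r=4.0, alpha=4.0)
        st_ = initial_state(wheel5, p, seed=0)
        st_.Pi_pair = np.full(st_.Pi_pair.size, 1e6)
        st_.Pi_pair[0] = -1e6
        allocate_investments(st_, wheel5, p)
        assert np.all(np.isfinite(st_.I))


class TestPayoffs:
    def test_full_investment_game_pays_c_times_r_minus_one(self):
        # every participant pours full capital c=1 into one game, r=3.5
        g = netgen.make_complete(4)
        p = GameParams(r=3.5, c=1.0)
        st_ = initial_state(g, p, seed=0, coop_prob=1.0)
        st_.I[:] = 0.0
        for i in range(4):
            st_.I[pair_index(g, i, 0)] = 1.0
        compute_payoffs(st_, g, p)
        for i in range(4):
            assert st_.Pi_pair[pair_index(g, i, 0)] == pytest.approx(2.5, abs=1e-9)

    def test_all_defectors_earn_nothing(self, small_ucm, default_params):
        st_ = initial_state(small_ucm, default_params, seed=0, coop_prob=0.0)
        compute_payoffs(st_, small_ucm, default_params)
        assert not st_.Pi_pair.any()

    def test_triangle_hand_values_and_conservation(self, triangle):
        p = GameParams(r=2.0, c=1.0, alpha=0.0)
        st_ = initial_state(triangle, p, seed=0, coop_prob=1.0)
        compute_payoffs(st_, triangle, p)
        assert np.allclose(st_.Pi_pair, 1 / 3)
        assert np.allclose(st_.Pi_tot, 1.0)
        assert st_.Pi_tot.sum() == pytest.approx((p.r - 1) * 3.0, abs=1e-12)

    @given(seed=st.integers(0, 10_000), coop=st.floats(0.1, 0.9))
    @settings(max_examples=25, deadline=None)
    def test_conservation_on_random_states(self, seed, coop):
        """Sum of all player payoffs equals (r-1) times the capital the
        cooperators actually invested, every round."""
        g = netgen.build_ucm_graph(
            netgen.sample_powerlaw_degree_sequence(60, 2.5, 2, 7, seed=seed),
            seed=seed)
        p = GameParams(r=3.7, alpha=1.5)
        rng = np.random.default_rng(seed)
        st_ = initial_state(g, p, seed=rng, coop_prob=coop)
        M = normalization_constant(g, p)
        for _ in range(3):
            step(st_, g, p, M, rng)
            invested = st_.effective_contrib(g).sum()
            # Pi arrays hold the payoffs of the step's pre-update state;
            # recompute on the current state for a like-for-like check
            compute_payoffs(st_, g, p)
            assert st_.Pi_tot.sum() == pytest.approx(
                (p.r - 1) * invested, abs=1e-6 * g.N)


class TestNormalization:
    def test_single_edge_bound(self):
        assert normalization_constant(path2(), GameParams(r=2.0, c=1.0)) == 5.0

    def test_wheel_bound(self, wheel5):
        assert normalization_constant(wheel5, GameParams(r=3.0, c=1.0)) == 19.0

    def test_observed_differences_never_exceed_m(self, small_ucm):
        p = GameParams(r=4.0, alpha=2.0)
        M = normalization_constant(small_ucm, p)
        rng = np.random.default_rng(8)
        st_ = initial_state(small_ucm, p, seed=rng)
        worst = 0.0
        for _ in range(50):
            step(st_, small_ucm, p, M, rng)
            pi = st_.Pi_tot
            u, v = small_ucm.edges[:, 0], small_ucm.edges[:, 1]
            worst = max(worst, float(np.abs(pi[u] - pi[v]).max()))
        assert worst <= M


class TestUpdateRules:
    def _two_node_state(self, pi0, pi1, s=(0, 1)):
        g = path2()
        p = GameParams(r=2.0)
        st_ = initial_state(g, p, seed=0)
        st_.s = np.array(s, dtype=np.int8)
        st_.Pi_tot = np.array([pi0, pi1], dtype=float)
        return g, st_

    def test_replicator_equal_payoffs_never_copies(self):
        g, st_ = self._two_node_state(1.0, 1.0)
        for seed in range(20):
            s_before = st_.s.copy()
            update_strategies_replicator(st_, g, 5.0, np.random.default_rng(seed))
            assert np.array_equal(st_.s, s_before)

    def test_replicator_full_gap_always_copies(self):
        for seed in range(20):
            g, st_ = self._two_node_state(0.0, 5.0)
            update_strategies_replicator(st_, g, 5.0, np.random.default_rng(seed))
            assert st_.s[0] == 1  # copied the richer neighbour's strategy

    def test_replicator_quarter_gap_copies_a_quarter_of_the_time(self):
        n, copies = 4000, 0
        for seed in range(n):
            g, st_ = self._two_node_state(0.0, 1.25)  # dPi = M/4
            update_strategies_replicator(st_, g, 5.0, np.random.default_rng(seed))
            copies += int(st_.s[0] == 1)
        assert copies / n == pytest.approx(0.25, abs=0.025)

    def test_fermi_symmetric_point_copies_half_the_time(self):
        n, copies = 4000, 0
        for seed in range(n):
            g, st_ = self._two_node_state(1.0, 1.0)
            update_strategies_fermi(st_, g, 1.0, np.random.default_rng(seed))
            copies += int(st_.s[0] == 1)
        assert copies / n == pytest.approx(0.5, abs=0.03)

    def test_fermi_strong_selection_limit(self):
        for seed in range(50):
            g, st_ = self._two_node_state(0.0, 1.0)
            update_strategies_fermi(st_, g, 1000.0, np.random.default_rng(seed))
            assert st_.s[0] == 1

    def test_unconditional_imitation_keeps_when_own_is_best(self, wheel5):
        p = GameParams(r=2.0, update_rule="unconditional_imitation")
        st_ = initial_state(wheel5, p, seed=0)
        st_.s = np.zeros(wheel5.N, dtype=np.int8)
        st_.s[5] = 1
        st_.Pi_tot = np.zeros(wheel5.N)
        st_.Pi_tot[5] = 10.0  # hub strictly best everywhere it appears
        update_strategies_unconditional_imitation(st_, wheel5,
                                                  np.random.default_rng(0))
        assert st_.s[5] == 1 and st_.s[:5].all()  # leaves copy the hub

    def test_unconditional_imitation_copies_best_neighbor(self):
        g = path3()
        p = GameParams(r=2.0, update_rule="unconditional_imitation")
        st_ = initial_state(g, p, seed=0)
        st_.s = np.array([1, 0, 0], dtype=np.int8)
        st_.Pi_tot = np.array([3.0, 1.0, 0.0])
        update_strategies_unconditional_imitation(st_, g, np.random.default_rng(0))
        assert st_.s[1] == 1  # node 1 copies node 0
        assert st_.s[0] == 1  # own payoff strictly highest: keeps


class TestStep:
    def test_all_defector_state_is_absorbing(self, small_ucm, default_params):
        st_ = initial_state(small_ucm, default_params, seed=0, coop_prob=0.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            step(st_, small_ucm, default_params, rng=rng)
            assert not st_.s.any()
            assert not st_.Pi_tot.any()

    @pytest.mark.parametrize("rule", ["replicator", "unconditional_imitation", "fermi"])
    def test_all_cooperator_state_keeps_strategies(self, small_ucm, rule):
        p = GameParams(r=4.0, alpha=2.0, update_rule=rule)
        st_ = initial_state(small_ucm, p, seed=0, coop_prob=1.0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            step(st_, small_ucm, p, rng=rng)
            assert st_.s.all()

    def test_regular_all_c_alpha0_closed_form(self, ring6):
        # k-regular all-cooperator even split: Pi_i = c(r-1) every round
        p = GameParams(r=2.5, c=1.0, alpha=0.0)
        st_ = initial_state(ring6, p, seed=0, coop_prob=1.0)
        rng = np.random.default_rng(2)
        M = normalization_constant(ring6, p)
        for _ in range(4):
            step(st_, ring6, p, M, rng)
            assert np.allclose(st_.Pi_tot, p.c * (p.r - 1), atol=1e-12)

    def test_trajectory_bit_reproducible(self, small_ucm, default_params):
        def run():
            rng = np.random.default_rng(77)
            st_ = initial_state(small_ucm, default_params, seed=rng)
            for _ in range(20):
                step(st_, small_ucm, default_params, rng=rng)
            return st_

        a, b = run(), run()
        assert np.array_equal(a.s, b.s)
        assert np.array_equal(a.I, b.I)
        assert np.array_equal(a.Pi_tot, b.Pi_tot)
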