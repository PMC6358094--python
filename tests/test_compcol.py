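"""Competition-colonization tradeoff: displacement kernel and dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichecluster import (
    CCParams,
    cc_weights,
    deterministic_dynamics,
    displacement_matrix,
    draw_fecundities,
    fecundity_to_trait,
    simulate_compcol,
)
from nichecluster.compcol import F_MAX, fecundity_grid


class TestDisplacementMatrix:
    def test_equal_fecundity_gives_even_odds(self):
        G = displacement_matrix(np.array([2.0, 2.0]), s=0.15)
        np.testing.assert_allclose(G, 0.5)

    def test_hand_value(self):
        # f_j - f_i = 5.2 at s = 0.15: 0.5(1 - tanh 0.78)
        G = displacement_matrix(np.array([1.0, 6.2]), s=0.15)
        assert G[0, 1] == pytest.approx(0.5 * (1 - np.tanh(0.78)), rel=1e-12)

    def test_hierarchy_direction(self):
        """High-fecundity propagules rarely displace low-fecundity residents."""
        G = displacement_matrix(np.array([1.0, 100.0]), s=0.5)
        assert G[0, 1] < 0.01  # fecund propagule vs competitive resident
        assert G[1, 0] > 0.99  # competitive propagule vs fecund resident

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(1.0, 6.2), min_size=2, max_size=8),
        st.floats(0.01, 5.0),
    )
    def test_antisymmetry_property(self, fec, s):
        G = displacement_matrix(np.array(fec), s)
        np.testing.assert_allclose(G + G.T, 1.0, atol=1e-12)
        # open interval up to floating saturation of tanh at large s*df
        assert np.all((G >= 0) & (G <= 1))
        assert np.all(np.diag(G) == 0.5)


class TestCCWeights:
    def test_equal_fecundities_reduce_to_neutral(self):
        N = np.array([4, 2, 1])
        f = np.full(3, 3.0)
        G = displacement_matrix(f, 0.15)
        death, local, _ = cc_weights(N, f, G, mu=1.0)
        np.testing.assert_allclose(death / death.sum(), N / N.sum())
        np.testing.assert_allclose(local / local.sum(), N / N.sum())

    def test_minimum_fecundity_species_never_recruits_locally(self):
        f = np.array([1.0, 3.0])
        G = displacement_matrix(f, 0.15)
        _, local, _ = cc_weights(np.array([5, 5]), f, G, mu=1.0)
        assert local[0] == 0.0

    def test_fecund_species_die_more_by_hand(self):
        """For N=(1,1), f=(2,4): the fecund species has the higher death
        weight (it is displaced more often under the tradeoff)."""
        f = np.array([2.0, 4.0])
        G = displacement_matrix(f, 0.15)
        death, _, _ = cc_weights(np.array([1, 1]), f, G, mu=1.0)
        assert death[1] > death[0]
        # explicit hand evaluation of species 2's weight
        expect = (4 + 2) * G[1, 0] + (4 + 4) * 0.5
        assert death[1] == pytest.approx(expect)

    def test_immigrant_weights_favor_fecundity(self):
        f = np.array([1.5, 6.0])
        G = displacement_matrix(f, 0.15)
        _, _, imm = cc_weights(np.array([1, 1]), f, G, mu=1.0, q=np.array([0.5, 0.5]))
        assert imm[1] > imm[0]
        assert imm.sum() == pytest.approx(1.0)


class TestFecundityTraitMap:
    def test_endpoints_and_midpoint(self):
        f = np.array([1.0, np.sqrt(F_MAX), F_MAX])
        np.testing.assert_allclose(fecundity_to_trait(f), [0.0, 0.5, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fecundity_to_trait(np.array([0.5]))

    def test_draws_are_log_uniform_in_range(self, rng):
        f = draw_fecundities(5000, rng)
        assert f.min() >= 1.0 and f.max() <= F_MAX
        x = fecundity_to_trait(f)
        # uniform on the trait axis: mean 1/2 within 4 SE
        assert abs(x.mean() - 0.5) < 4 * x.std() / np.sqrt(x.size)


class TestDeterministicDynamics:
    def test_single_species_closed_form_equilibrium(self):
        """One species equilibrates at N* = (f - mu)/f."""
        f = np.array([4.0])
        G = displacement_matrix(f, 0.15)
        res = deterministic_dynamics(np.array([0.01]), f, G, mu=1.0, t_end=1e4)
        assert res.N_eq[0] == pytest.approx((4.0 - 1.0) / 4.0, rel=1e-6)
        assert res.n_survivors == 1
        assert res.max_eigenvalue < 0

    def test_equilibrium_is_stable_and_saturated(self):
        """Default grid: equilibrium is internally stable and uninvadable."""
        f = fecundity_grid(201)
        G = displacement_matrix(f, 0.15)
        res = deterministic_dynamics(np.full(201, 1e-3), f, G, mu=1.0)
        assert res.max_eigenvalue < 0
        # saturation: no excluded species has positive invasion growth
        B = (f[:, None] + f[None, :]) * G
        inv = (f - 1.0) - B @ res.N_eq
        excluded = np.setdiff1d(np.arange(201), res.survivors)
        assert inv[excluded].max() < 1e-6

    def test_survivor_count_grid_insensitive(self):
        counts = {}
        for n in (201, 402):
            f = fecundity_grid(n)
            G = displacement_matrix(f, 0.15)
            res = deterministic_dynamics(np.full(n, 1e-3), f, G, mu=1.0)
            counts[n] = res.n_survivors
        assert abs(counts[201] - counts[402]) <= 1

    def test_survivors_lie_within_transient_cluster_support(self):
        """Equilibrium survivors sit inside the transient abundance peak."""
        f = fecundity_grid(201)
        G = displacement_matrix(f, 0.15)
        transient = deterministic_dynamics(
            np.full(201, 1e-3), f, G, mu=1.0, t_end=300.0, tol=0.0
        )
        final = deterministic_dynamics(np.full(201, 1e-3), f, G, mu=1.0)
        peak_set = np.flatnonzero(
            transient.N_eq > 1e-3 * transient.N_eq.max()
        )
        assert np.all(np.isin(final.survivors, peak_set))

    def test_invalid_initial_state_rejected(self):
        f = np.array([2.0, 3.0])
        G = displacement_matrix(f, 0.15)
        with pytest.raises(ValueError):
            deterministic_dynamics(np.array([0.0, 1.0]), f, G)


def test_stochastic_run_conserves_J_and_uses_tradeoff_axis(small_pool):
    comm = simulate_compcol(
        small_pool, CCParams(), J=300, m=0.1, generations=5, seed=21
    )
    assert comm.J == 300
    # the community's pool carries fecundities and the log-map trait axis
    assert comm.pool.fecundity is not None
    np.testing.assert_allclose(
        comm.pool.trait, fecundity_to_trait(comm.pool.fecundity)
    )


def test_stochastic_run_reproducible(small_pool):
    a = simulate_compcol(small_pool, CCParams(), J=200, m=0.1, generations=3, seed=5)
    b = simulate_compcol(small_pool, CCParams(), J=200, m=0.1, generations=3, seed=5)
    assert np.array_equal(a.N, b.N)
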