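import numpy as np
import pytest
from scipy.optimize import brentq

from oracles import symmetric_net_growth

from cheatnet.cheating import CheatingConfig
from cheatnet.community import generate_community
from cheatnet.dynamics import (
    DynamicsParams,
    check_stability,
    integrate_strengths,
    integrate_to_equilibrium,
    make_rhs,
    persistence,
    rhs,
    similarity_matrices,
)

ONE = np.array([[1.0]])


class TestSimilarity:
    def test_identical_rows_give_unit_similarity(self):
        M = np.array([[1.0, 0.5, 0.0], [1.0, 0.5, 0.0]])
        sim = similarity_matrices(M, np.zeros_like(M))
        assert sim.Pi[0, 1] == pytest.approx(1.0)

    def test_disjoint_partner_sets_give_zero(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        sim = similarity_matrices(M, np.zeros_like(M))
        assert sim.Pi[0, 1] == 0.0

    def test_no_cheating_gives_identity_gamma(self):
        M = np.ones((3, 4))
        sim = similarity_matrices(M, np.zeros_like(M))
        assert np.array_equal(sim.Gamma, np.eye(3))

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(4)
        M = rng.random((6, 8))
        C = rng.random((6, 8))
        sim = similarity_matrices(M, C)
        for S in (sim.Pi, sim.Gamma, sim.Theta):
            assert np.allclose(S, S.T)
            assert np.allclose(np.diag(S), 1.0)
            assert (S >= 0).all() and (S <= 1.0 + 1e-12).all()


class TestRhs:
    def test_extinction_is_absorbing(self):
        r = np.array([-0.1])
        dP, dA = rhs(
            np.array([0.0]), np.array([1.0]), r, r, ONE, np.zeros((1, 1)),
            DynamicsParams(), 0.0,
        )
        assert dP[0] == 0.0

    def test_zero_cost_removes_plant_cheating_term(self):
        """With Lambda = 0 the plant derivative ignores C entirely."""
        com = generate_community(seed=1)
        rng = np.random.default_rng(0)
        C = rng.random(com.IM.shape) * (1 - com.IM)
        P0 = rng.random(com.n_P) + 0.5
        A0 = rng.random(com.n_A) + 0.5
        dP_c, _ = rhs(P0, A0, com.r_P, com.r_A, com.IM, C,
                      DynamicsParams(), 0.0)
        dP_0, _ = rhs(P0, A0, com.r_P, com.r_A, com.IM, np.zeros_like(C),
                      DynamicsParams(), 0.0)
        assert np.allclose(dP_c, dP_0, atol=1e-14)

    def test_invalid_abundances_rejected(self):
        r = np.array([-0.1])
        with pytest.raises(ValueError):
            rhs(np.array([np.nan]), np.array([1.0]), r, r, ONE,
                np.zeros((1, 1)), DynamicsParams(), 0.0)
        with pytest.raises(ValueError):
            rhs(np.array([-1.0]), np.array([1.0]), r, r, ONE,
                np.zeros((1, 1)), DynamicsParams(), 0.0)

    def test_mutualism_condition_enforced(self):
        r = np.array([-0.1])
        with pytest.raises(ValueError):
            rhs(np.array([1.0]), np.array([1.0]), r, r, ONE,
                np.zeros((1, 1)), DynamicsParams(alpha=1.0), 1.2)

    def test_pollinator_benefit_monotone_in_cheating_strength(self):
        """alpha*x/(1 + beta*x + k) rises with x, so more cheating
        strength never lowers the pollinator benefit at fixed state."""
        r = np.array([-0.1])
        P0, A0 = np.array([0.8]), np.array([0.6])
        prev = -np.inf
        for cval in (0.0, 0.2, 0.5, 0.9):
            _, dA = rhs(P0, A0, r, r, ONE, np.array([[cval]]),
                        DynamicsParams(), 0.0)
            benefit = dA[0] / A0[0] - r[0] + A0[0]
            assert benefit >= prev - 1e-12
            prev = benefit


class TestTwoSpeciesOracle:
    """Independent scalar root-finding against the integrated dynamics."""

    def test_interior_equilibrium_matched(self):
        r = -0.01
        x_star = brentq(symmetric_net_growth, 0.1, 1.0, args=(r,),
                        xtol=1e-14)
        res = integrate_strengths(
            np.array([r]), np.array([r]), ONE, np.zeros((1, 1))
        )
        assert res.converged and res.stable
        assert res.persistence == 100.0
        assert np.allclose(res.abundances, x_star, atol=1e-6)
        f = make_rhs(np.array([r]), np.array([r]), ONE, np.zeros((1, 1)),
                     DynamicsParams(), 0.0)
        assert np.abs(f(0.0, np.array([x_star, x_star]))).max() < 1e-10

    def test_no_interior_root_means_extinction(self):
        """At r = -0.1 the scalar equation has no positive root: the
        saturating benefit (max ~0.025) cannot offset the mortality."""
        r = -0.1
        xs = np.linspace(1e-6, 5.0, 2000)
        assert (symmetric_net_growth(xs, r) < 0).all()
        res = integrate_strengths(
            np.array([r]), np.array([r]), ONE, np.zeros((1, 1))
        )
        assert res.persistence == 0.0 and res.stable


class TestIntegrate:
    def test_baseline_identical_whatever_idle_parameters(self):
        com = generate_community(seed=5)
        params = DynamicsParams()
        base = integrate_to_equilibrium(
            com, CheatingConfig(0.0, 0.0, 0.0), params
        )
        for delta_bar, psi in [(0.5, 1.0), (1.0, 0.3)]:
            other = integrate_to_equilibrium(
                com, CheatingConfig(delta_bar, 0.0, psi), params
            )
            assert np.array_equal(other.abundances, base.abundances)

    def test_hopeless_parameters_collapse(self):
        com = generate_community(n_P=5, n_A=5, phi=0.5, seed=2)
        com.r_P[:] = -0.5
        com.r_A[:] = -0.5
        res = integrate_to_equilibrium(
            com, None, DynamicsParams(alpha=0.001)
        )
        assert res.persistence == 0.0

    def test_trajectory_recording_round_trips(self, tmp_path):
        res = integrate_strengths(
            np.array([-0.01]), np.array([-0.01]), ONE, np.zeros((1, 1)),
            record_trajectory=True,
        )
        assert res.trajectory.shape == (res.steps_used + 1, 2)
        assert np.allclose(res.trajectory[0], 1.0)  # initial abundance
        assert np.allclose(res.trajectory[-1], res.abundances)
        out = tmp_path / "traj.tsv"
        res.trajectory_tsv(out)
        assert out.read_text().splitlines()[0] == "time\tP0\tA0"

    def test_abundances_stay_nonnegative(self, community20):
        res = integrate_to_equilibrium(community20, None, DynamicsParams())
        assert (res.abundances >= 0).all()
        assert res.converged


class TestStability:
    def test_logistic_carrying_capacity_is_stable(self):
        def f(t, y):
            return y * (1.0 - y)

        assert check_stability(np.array([1.0]), f)

    def test_total_extinction_is_stable(self):
        r = np.array([-0.2, -0.3])
        f = make_rhs(r, r, np.eye(2), np.zeros((2, 2)),
                     DynamicsParams(), 0.0)
        assert check_stability(np.zeros(4), f)

    def test_agrees_with_central_difference_jacobian(self):
        com = generate_community(seed=7)
        res = integrate_to_equilibrium(com, None, DynamicsParams())
        f = make_rhs(com.r_P, com.r_A, com.IM, np.zeros_like(com.IM),
                     DynamicsParams(), 0.0)
        y = res.abundances
        alive = np.flatnonzero(y > 1e-5)
        n = len(alive)
        J = np.zeros((n, n))
        for col, k in enumerate(alive):
            h = 1e-6 * max(1.0, abs(y[k]))
            up, dn = y.copy(), y.copy()
            up[k] += h
            dn[k] -= h
            J[:, col] = (f(0, up)[alive] - f(0, dn)[alive]) / (2 * h)
        fd_stable = np.linalg.eigvals(J).real.max() < 1e-8
        assert res.stable == fd_stable


class TestPersistence:
    def test_half_above_threshold(self):
        assert persistence(np.array([1.0, 1e-6, 0.5, 0.0])) == 50.0

    def test_all_above(self):
        assert persistence(np.array([0.1, 0.2])) == 100.0

    def test_exactly_threshold_counts_extinct(self):
        assert persistence(np.array([1e-5, 1.0])) == 50.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            persistence(np.array([]))
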