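"""Xylem network solver against dense oracles and network identities."""

import numpy as np
import pytest

from rootflow3d.doussan import (
    compute_kroot_and_effective_potential,
    compute_suf,
    solve_xylem,
)
from rootflow3d.root_architecture import RootSystem

from conftest import random_tree


def dense_oracle(system, kr, kx, psi_s, collar_bc, gravity=True):
    """Independent dense assembly of the nodal Kirchhoff balance, solved
    with numpy.linalg.solve (loop-based, no sparse machinery)."""
    n = system.n_nodes
    L = system.lengths()
    z = system.pos[:, 2] if gravity else np.zeros(n)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for j in range(1, n):
        p = system.parent[j]
        a = kx[j] / L[j]
        for (u, v) in ((j, p), (p, j)):
            A[u, u] += a
            A[u, v] -= a
        # gravity contributions of the axial link
        b[j] -= a * (z[j] - z[p])
        b[p] -= a * (z[p] - z[j])
        A[j, j] += kr[j]
        b[j] += kr[j] * psi_s[j]
    mode, val = collar_bc
    if mode == "flux":
        b[0] -= val
        psi = np.linalg.solve(A, b)
    else:
        psi = np.zeros(n)
        psi[0] = val
        rhs = b[1:] - A[1:, 0] * val
        psi[1:] = np.linalg.solve(A[1:, 1:], rhs)
    return psi


class TestSolveXylem:
    def test_no_flow_equilibrium_single_segment(self, single_segment_system):
        """At zero transpiration and uniform soil potential the xylem
        settles at constant total potential and all fluxes vanish."""
        kr = np.array([0.0, 1e-3])
        kx = np.array([0.0, 1e-2])
        psi_s = np.array([0.0, -100.0])
        sol = solve_xylem(single_segment_system, kr, kx, psi_s,
                          ("flux", 0.0))
        assert sol.J_r[1] == pytest.approx(0.0, abs=1e-12)
        total = sol.psi_x + single_segment_system.pos[:, 2]
        assert np.ptp(total) == pytest.approx(0.0, abs=1e-9)

    def test_two_segment_chain_matches_hand_assembled_dense_solve(
            self, two_segment_chain):
        kr = np.array([0.0, 2e-3, 1e-3])
        kx = np.array([0.0, 5e-2, 2e-2])
        psi_s = np.array([0.0, -150.0, -350.0])
        T = 0.04
        # hand-assembled 3x3 nodal balance (gravity off)
        a1, a2 = kx[1] / 1.0, kx[2] / 1.0
        A = np.array([
            [a1, -a1, 0.0],
            [-a1, a1 + a2 + kr[1], -a2],
            [0.0, -a2, a2 + kr[2]],
        ])
        b = np.array([-T, kr[1] * psi_s[1], kr[2] * psi_s[2]])
        ref = np.linalg.solve(A, b)
        sol = solve_xylem(two_segment_chain, kr, kx, psi_s, ("flux", T),
                          gravity=False)
        np.testing.assert_allclose(sol.psi_x, ref, atol=1e-10)

    @pytest.mark.parametrize("n_nodes", [5, 40, 200])
    def test_matches_dense_oracle_on_random_trees(self, n_nodes):
        rng = np.random.default_rng(n_nodes)
        rs = random_tree(rng, n_nodes)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, n_nodes - 1)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, n_nodes - 1)]
        psi_s = np.r_[0.0, rng.uniform(-800, -50, n_nodes - 1)]
        sol = solve_xylem(rs, kr, kx, psi_s, ("flux", 0.7))
        ref = dense_oracle(rs, kr, kx, psi_s, ("flux", 0.7))
        np.testing.assert_allclose(sol.psi_x, ref, rtol=1e-9, atol=1e-9)

    def test_collar_mass_balance(self):
        rng = np.random.default_rng(5)
        rs = random_tree(rng, 80)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, 79)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, 79)]
        psi_s = np.r_[0.0, rng.uniform(-500, -50, 79)]
        for T in (0.0, 0.3, 2.5):
            sol = solve_xylem(rs, kr, kx, psi_s, ("flux", T))
            assert sol.J_r.sum() == pytest.approx(T, abs=1e-8 * max(T, 1))

    def test_flux_and_potential_bc_consistent(self):
        rng = np.random.default_rng(9)
        rs = random_tree(rng, 60)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, 59)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, 59)]
        psi_s = np.r_[0.0, rng.uniform(-500, -50, 59)]
        sol = solve_xylem(rs, kr, kx, psi_s, ("flux", 1.2))
        sol2 = solve_xylem(rs, kr, kx, psi_s, ("psi", sol.psi_collar))
        assert sol2.T_act == pytest.approx(1.2, rel=1e-8)
        np.testing.assert_allclose(sol2.psi_x, sol.psi_x, atol=1e-8)

    def test_maximum_principle_without_gravity(self):
        """With gravity off and uniform soil potential, all xylem
        potentials lie between the soil potential and the collar."""
        rng = np.random.default_rng(13)
        rs = random_tree(rng, 120)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, 119)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, 119)]
        psi_s = np.full(120, -200.0)
        sol = solve_xylem(rs, kr, kx, psi_s, ("flux", 1.0), gravity=False)
        lo, hi = sol.psi_collar, -200.0
        assert np.all(sol.psi_x >= lo - 1e-9)
        assert np.all(sol.psi_x <= hi + 1e-9)

    def test_zero_axial_conductance_diagnosed(self, two_segment_chain):
        kr = np.array([0.0, 1e-3, 1e-3])
        kx = np.array([0.0, 1e-2, 0.0])
        with pytest.raises(ValueError, match="isolates the subtree"):
            solve_xylem(two_segment_chain, kr, kx, np.zeros(3),
                        ("flux", 0.1))

    def test_fully_isolated_system_diagnosed(self, two_segment_chain):
        with pytest.raises(ValueError, match="isolated"):
            solve_xylem(two_segment_chain, np.zeros(3),
                        np.array([0, 1e-2, 1e-2]), np.zeros(3),
                        ("flux", 0.1))


class TestSUF:
    def test_single_segment_suf_is_one(self, single_segment_system):
        suf = compute_suf(single_segment_system, np.array([0, 1e-3]),
                          np.array([0, 1e-2]))
        assert suf[1] == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetric_branches_split_evenly(self):
        pos = np.array([[0, 0, 0], [1, 0, -1.0], [-1, 0, -1.0]])
        rs = RootSystem(pos, [-1, 0, 0], [0, 0.05, 0.05], [0, 1, 1],
                        [-np.inf, 0, 0], [-1, 0, 1])
        suf = compute_suf(rs, np.array([0, 1e-3, 1e-3]),
                          np.array([0, 1e-2, 1e-2]))
        np.testing.assert_allclose(suf[1:], [0.5, 0.5], atol=1e-12)

    def test_sums_to_one_and_scaling_invariant(self):
        rng = np.random.default_rng(21)
        rs = random_tree(rng, 150)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, 149)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, 149)]
        suf = compute_suf(rs, kr, kx)
        assert suf.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(suf[1:] >= -1e-12)
        for c in (0.01, 7.3):
            suf_c = compute_suf(rs, c * kr, c * kx)
            np.testing.assert_allclose(suf_c, suf, atol=1e-10)


class TestKrootEffectivePotential:
    def test_zero_transpiration_collar_equals_effective_potential(self):
        rng = np.random.default_rng(31)
        rs = random_tree(rng, 50)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, 49)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, 49)]
        psi_s = np.r_[0.0, rng.uniform(-600, -100, 49)]
        sol = solve_xylem(rs, kr, kx, psi_s, ("flux", 0.0), gravity=False)
        sol.suf = compute_suf(rs, kr, kx)
        k_root, psi_eff = compute_kroot_and_effective_potential(sol)
        assert k_root is None
        assert sol.psi_collar == pytest.approx(psi_eff, abs=1e-6)

    def test_single_segment_kroot_is_series_conductance(
            self, single_segment_system):
        kr = np.array([0.0, 1e-3])
        kx = np.array([0.0, 1e-2])
        psi_s = np.array([0.0, -100.0])
        sol = solve_xylem(single_segment_system, kr, kx, psi_s,
                          ("flux", 0.05), gravity=False)
        sol.suf = compute_suf(single_segment_system, kr, kx)
        k_root, _ = compute_kroot_and_effective_potential(sol)
        series = 1.0 / (1.0 / kr[1] + 1.0 / (kx[1] / 1.0))
        assert k_root == pytest.approx(series, rel=1e-10)

    def test_uniform_soil_gives_that_effective_potential(self):
        rng = np.random.default_rng(41)
        rs = random_tree(rng, 30)
        kr = np.r_[0.0, rng.uniform(1e-4, 5e-3, 29)]
        kx = np.r_[0.0, rng.uniform(1e-3, 1e-1, 29)]
        psi_s = np.full(30, -100.0)
        sol = solve_xylem(rs, kr, kx, psi_s, ("flux", 0.4), gravity=False)
        sol.suf = compute_suf(rs, kr, kx)
        _, psi_eff = compute_kroot_and_effective_potential(sol)
        assert psi_eff == pytest.approx(-100.0, abs=1e-9)
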