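"""Hierarchy construction and numerically exact propagation limits."""

from math import comb

import numpy as np
import pytest

from blochcorridor.bath import BathSpec, correlation_expansion, terminator_coefficient
from blochcorridor.heom import (
    HierarchyState,
    _HeomWorkspace,
    _hamiltonian_matrix,
    build_hierarchy,
    heom_rhs,
    propagate_heom,
)
from blochcorridor.model import CouplingSpec, PauliOp, SystemParams, build_coupling_operator


@pytest.fixture(scope="module")
def small_exp():
    b = BathSpec(lam=0.8, gamma=1.0, omega0=3.0, T=3.0)
    return b, correlation_expansion(b, 2)


class TestBuildHierarchy:
    def test_two_terms_tier_one(self):
        b = BathSpec(lam=1.0, gamma=0.5, omega0=1.5, T=3.0)
        exp = correlation_expansion(b, 0)
        exp_small = exp.__class__(cR=exp.cR[:1], gR=exp.gR[:1], cI=exp.cI[:1], gI=exp.gI[:1])
        h = build_hierarchy(exp_small, 1)
        assert h.n_ados == 3
        assert sorted(map(tuple, h.indices.tolist())) == [(0, 0), (0, 1), (1, 0)]

    def test_stars_and_bars_count(self, small_exp):
        _, exp = small_exp
        k = exp.NR + exp.NI
        for nc in (1, 2, 3):
            h = build_hierarchy(exp, nc)
            assert h.n_ados == comb(k + nc, nc)

    def test_neighbor_links_are_mutual(self, small_exp):
        _, exp = small_exp
        h = build_hierarchy(exp, 3)
        for i in range(h.n_ados):
            for k in range(h.n_terms):
                j = h.up[i, k]
                if j >= 0:
                    assert h.down[j, k] == i

    def test_guardrail(self, small_exp):
        _, exp = small_exp
        with pytest.raises(ValueError):
            build_hierarchy(exp, 40)


class TestHeomRHS:
    def test_decoupled_hierarchy_at_zero_coupling(self, small_exp):
        b, exp = small_exp
        h = build_hierarchy(exp, 2)
        p = SystemParams(epsilon=0.5, delta=1.0)
        ados = np.zeros((h.n_ados, 2, 2), dtype=complex)
        ados[0] = np.array([[0.7, 0.2 - 0.1j], [0.2 + 0.1j, 0.3]])
        state = HierarchyState(h, ados)
        d = heom_rhs(state, 0.0, np.zeros((2, 2)), p)
        H = _hamiltonian_matrix(0.0, p)
        want = -1j * (H @ ados[0] - ados[0] @ H)
        assert np.abs(d.ados[0] - want).max() < 1e-14
        assert np.abs(d.ados[1:]).max() == 0.0

    def test_trace_of_physical_rhs_vanishes(self, small_exp):
        b, exp = small_exp
        h = build_hierarchy(exp, 2)
        p = SystemParams(epsilon=0.5, delta=1.0)
        L = build_coupling_operator(CouplingSpec(kind="asymmetric_local", c1=2.0, c2=0.5))
        rng = np.random.default_rng(8)
        ados = rng.normal(size=(h.n_ados, 2, 2)) + 1j * rng.normal(size=(h.n_ados, 2, 2))
        ados = ados + np.swapaxes(ados, 1, 2).conj()  # Hermitian ADOs
        state = HierarchyState(h, ados)
        d = heom_rhs(state, 0.0, L.to_matrix(), p, gamma_term=terminator_coefficient(b, 2))
        assert abs(np.trace(d.ados[0])) < 1e-12

    def test_sparse_generator_matches_matrix_free(self, small_exp):
        b, exp = small_exp
        h = build_hierarchy(exp, 3)
        p = SystemParams(epsilon=0.5, delta=1.0)
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0)).to_matrix()
        ws = _HeomWorkspace(h, L, terminator_coefficient(b, 2))
        rng = np.random.default_rng(9)
        ados = rng.normal(size=(h.n_ados, 2, 2)) + 1j * rng.normal(size=(h.n_ados, 2, 2))
        H0 = _hamiltonian_matrix(0.0, p)
        want = ws.rhs(0.0, ados, H0)
        A, _ = ws.build_sparse(H0)
        got = (A @ ados.reshape(-1)).reshape(ados.shape)
        assert np.abs(got - want).max() < 1e-12


class TestPropagation:
    def test_zero_coupling_rabi(self):
        p = SystemParams(epsilon=0.0, delta=1.0)
        b = BathSpec(lam=1e-10, gamma=1.0, omega0=3.0, T=3.0)
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
        grid = np.linspace(0, 20, 201)
        tr = propagate_heom(np.array([[1, 0], [0, 0]], dtype=complex), grid, p, L, b, Nc=2, n_matsubara=1)
        assert np.abs(tr.n_av[:, 2] - np.cos(grid)).max() < 1e-6

    def test_driven_zero_coupling_closed_form(self):
        p = SystemParams(epsilon=0.0, delta=1.0, B0=2.0, omegaB=5.0)
        b = BathSpec(lam=1e-10, gamma=1.0, omega0=3.0, T=3.0)
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
        grid = np.linspace(0, 10, 201)
        tr = propagate_heom(np.array([[1, 0], [0, 0]], dtype=complex), grid, p, L, b, Nc=2, n_matsubara=1)
        phase = grid + (p.B0 / p.omegaB) * np.sin(p.omegaB * grid)
        assert np.abs(tr.n_av[:, 2] - np.cos(phase)).max() < 1e-5

    def test_pure_dephasing_exact_decoherence(self):
        """Commuting coupling: populations frozen, coherence decays with the
        nonperturbative closed form |rho01| = |rho01(0)| e^{-Gamma(t)},
        Gamma(t) = 4 c^2 Re int_0^t (t - s) C(s) ds."""
        p = SystemParams(epsilon=1.0, delta=1e-8)
        c = 0.5
        Lz = PauliOp(0.0, np.array([0.0, 0.0, c]))
        b = BathSpec(lam=0.8, gamma=1.0, omega0=3.0, T=3.0)
        grid = np.linspace(0, 8, 81)
        rho0 = np.array([[0.5, 0.5], [0.5, 0.5]], dtype=complex)
        tr = propagate_heom(rho0, grid, p, Lz, b, Nc=6, n_matsubara=3)

        exp = correlation_expansion(b, 12)
        def deco(t):
            s = sum(cc * (t / g - (1 - np.exp(-g * t)) / g**2) for cc, g in zip(exp.cR, exp.gR))
            return 4 * c * c * np.real(s)

        coh = 0.5 * np.hypot(tr.n_av[:, 0], tr.n_av[:, 1])
        want = 0.5 * np.exp(-np.array([deco(t) for t in grid]))
        assert np.abs(coh - want).max() < 5e-3
        assert np.abs(tr.n_av[:, 2] - tr.n_av[0, 2]).max() < 1e-7

    def test_weak_coupling_matches_redfield(self, system, basis, sigma_x_channels, weak_bath):
        from blochcorridor.redfield import GammaCache, propagate_redfield

        grid = np.arange(0, 20.0001, 0.01)
        tr_r = propagate_redfield([0, 0, 1], grid, system, sigma_x_channels, GammaCache(sigma_x_channels, weak_bath))
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
        tr_h = propagate_heom(np.array([[1, 0], [0, 0]], dtype=complex), grid[::20], system, L, weak_bath, Nc=4, n_matsubara=2)
        assert np.abs(tr_r.n_av[::20] - tr_h.n_av).max() < 0.02

    def test_long_time_gibbs(self, system, basis):
        b = BathSpec(lam=0.5, gamma=1.0, omega0=3.0, T=3.0)
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
        grid = np.arange(0, 300.0, 1.0)
        tr = propagate_heom(np.array([[1, 0], [0, 0]], dtype=complex), grid, system, L, b, Nc=4, n_matsubara=2)
        nz_gibbs = -(system.epsilon / basis.Omega) * np.tanh(0.5 * basis.Omega / b.T)
        assert tr.n_av[-1, 2] == pytest.approx(nz_gibbs, rel=0.05)

    def test_nc_convergence_is_monotone(self, system, generic_bath):
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
        grid = np.linspace(0, 15, 76)
        rho0 = np.array([[1, 0], [0, 0]], dtype=complex)
        runs = {
            nc: propagate_heom(rho0, grid, system, L, generic_bath, Nc=nc, n_matsubara=2)
            for nc in (2, 3, 4, 5, 6)
        }
        diffs = [np.abs(runs[nc].n_av - runs[6].n_av).max() for nc in (2, 3, 4, 5)]
        assert diffs[0] > diffs[1] > diffs[2] > diffs[3]
        assert diffs[3] < 1e-3  # the Nc = 5 setting is converged here

    def test_invalid_rho0_rejected(self, system, generic_bath):
        L = build_coupling_operator(CouplingSpec(kind="transition", c=1.0))
        with pytest.raises(ValueError):
            propagate_heom(np.array([[1, 0], [0, 1]], dtype=complex), np.linspace(0, 1, 5), system, L, generic_bath)
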