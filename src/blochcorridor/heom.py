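"""Hierarchical equations of motion for the two-level system.

Numerically exact benchmark propagator.  The bath correlation function is
decomposed into exponentials (two resonant terms plus Matsubara terms for
the real part, two resonant terms for the imaginary part) and the reduced
density matrix is embedded in a ladder of auxiliary density operators
(ADOs) indexed by a multi-index n over the expansion terms:

    d/dt rho_n = (Liouvillian - sum n_ab g_ab) rho_n
                 - i sum_ab [L, rho_{n_ab+}]
                 - i sum_b  c_bR n_Rb [L, rho_{n_Rb-}]
                 + sum_b    c_bI n_Ib {L, rho_{n_Ib-}}

truncated at total tier Nc, with a Markovian terminator for the discarded
Matsubara tail folded into the Liouvillian.  Internally the ADOs carry the
standard scaling rho_n / sqrt(prod n_k! |c_k|^{n_k}) for numerical
stability; the zero-index ADO is the physical density matrix and is
unaffected by the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .bath import BathSpec, CorrelationExpansion, correlation_expansion, terminator_coefficient
from .model import PauliOp, SystemParams, drive_amplitude
from .redfield import BlochTrajectory, density_to_bloch

__all__ = [
    "ADOIndex",
    "Hierarchy",
    "HierarchyState",
    "build_hierarchy",
    "heom_rhs",
    "propagate_heom",
]

_MAX_ADOS = 1_000_000


@dataclass(frozen=True)
class ADOIndex:
    """Multi-index over correlation expansion terms; tier = sum of entries."""

    n: tuple[int, ...]

    @property
    def tier(self) -> int:
        return sum(self.n)

    def raised(self, k: int) -> "ADOIndex":
        m = list(self.n)
        m[k] += 1
        return ADOIndex(tuple(m))

    def lowered(self, k: int) -> "ADOIndex":
        m = list(self.n)
        m[k] -= 1
        return ADOIndex(tuple(m))


@dataclass
class Hierarchy:
    """Enumerated ADO indices with neighbour links and term data.

    indices : (N, K) integer array, row 0 is the zero index
    up/down : (N, K) integer arrays of neighbour positions, -1 if absent
    c, nu   : (K,) complex amplitudes and decay rates of the expansion
    kind    : (K,) array of "R"/"I" markers
    """

    indices: np.ndarray
    up: np.ndarray
    down: np.ndarray
    c: np.ndarray
    nu: np.ndarray
    kind: np.ndarray
    Nc: int
    per_index_cap: bool = False

    @property
    def n_ados(self) -> int:
        return self.indices.shape[0]

    @property
    def n_terms(self) -> int:
        return self.indices.shape[1]


@dataclass
class HierarchyState:
    """All ADOs as one (N, 2, 2) complex array; ados[0] is physical."""

    hierarchy: Hierarchy
    ados: np.ndarray

    @property
    def rho(self) -> np.ndarray:
        return self.ados[0]


def build_hierarchy(
    exp: CorrelationExpansion, Nc: int, per_index_cap: bool = False
) -> Hierarchy:
    """Enumerate multi-indices and neighbour links.

    Default truncation keeps total tier <= Nc (standard practice); with
    ``per_index_cap`` each entry is individually capped at Nc instead.
    """
    if Nc < 1:
        raise ValueError("Nc must be >= 1")
    k = exp.NR + exp.NI
    count = comb(k + Nc, Nc) if not per_index_cap else (Nc + 1) ** k
    if count > _MAX_ADOS:
        raise ValueError(f"hierarchy would contain {count} ADOs (> {_MAX_ADOS})")

    idx_list: list[tuple[int, ...]] = []

    def rec(prefix: tuple[int, ...], remaining: int):
        if len(prefix) == k:
            idx_list.append(prefix)
            return
        cap = remaining if not per_index_cap else Nc
        for v in range(cap + 1):
            rec(prefix + (v,), remaining - v if not per_index_cap else remaining)

    rec((), Nc)
    idx_list.sort(key=lambda t: (sum(t), t))
    indices = np.array(idx_list, dtype=int)
    pos = {tuple(row): i for i, row in enumerate(indices)}
    n = len(idx_list)
    up = -np.ones((n, k), dtype=int)
    down = -np.ones((n, k), dtype=int)
    for i, row in enumerate(indices):
        for j in range(k):
            r = list(row)
            r[j] += 1
            up[i, j] = pos.get(tuple(r), -1)
            r[j] -= 2
            if r[j] >= 0:
                down[i, j] = pos.get(tuple(r), -1)
    c = np.concatenate([exp.cR, exp.cI])
    nu = np.concatenate([exp.gR, exp.gI])
    kind = np.array(["R"] * exp.NR + ["I"] * exp.NI)
    return Hierarchy(indices, up, down, c, nu, kind, Nc, per_index_cap)


class _HeomWorkspace:
    """Precomputed coupling factors for the vectorized RHS."""

    def __init__(self, h: Hierarchy, L: np.ndarray, gamma_term: float):
        self.h = h
        self.L = np.asarray(L, dtype=complex)
        absc = np.abs(h.c)
        absc_safe = np.where(absc > 0, absc, 1.0)
        nmat = h.indices.astype(float)
        # scaled-ADO factors: up sqrt((n_k+1)|c_k|), down sqrt(n_k/|c_k|)
        self.s_up = np.sqrt((nmat + 1.0) * absc[None, :])
        self.s_down = np.sqrt(nmat / absc_safe[None, :])
        self.damp = nmat @ h.nu  # (N,) complex
        # tier-down operator coefficients: rho_out += s*(alpha L r + abar r L)
        self.alpha = np.where(h.kind == "R", -1j * h.c, h.c)
        self.abar = np.where(h.kind == "R", 1j * h.c, h.c)
        self.gamma_term = gamma_term
        LL = self.L @ self.L
        self.LL = LL
        # precomputed gather/scatter index lists per expansion term
        self._up_links = []
        self._down_links = []
        for k in range(h.n_terms):
            rows = np.where(h.up[:, k] >= 0)[0]
            self._up_links.append((rows, h.up[rows, k], -1j * self.s_up[rows, k]))
            rows = np.where(h.down[:, k] >= 0)[0]
            self._down_links.append((rows, h.down[rows, k], self.s_down[rows, k]))

    def build_sparse(self, H0: np.ndarray):
        """Assemble the full hierarchy generator as one sparse matrix.

        Acting on the flattened (N*4,) state; returns (A_static, A_drive)
        where the drive contributes (Delta(t) - Delta) * A_drive for a
        modulated tunnelling term.
        """
        from scipy import sparse

        h = self.h
        n = h.n_ados
        I2 = np.eye(2, dtype=complex)
        I4 = sparse.identity(4, dtype=complex, format="csr")

        def lmul(M):  # M @ rho on row-major vec(rho)
            return sparse.kron(sparse.csr_matrix(M), I2, format="csr")

        def rmul(M):  # rho @ M
            return sparse.kron(I2, sparse.csr_matrix(M.T), format="csr")

        L = self.L
        comm_L = lmul(L) - rmul(L)
        comm_H = lmul(H0) - rmul(H0)
        blocks = -1j * comm_H
        if self.gamma_term != 0.0:
            blocks = blocks + self.gamma_term * (
                2.0 * lmul(L) @ rmul(L.conj().T) - lmul(self.LL) - rmul(self.LL)
            )
        A = sparse.kron(sparse.identity(n, dtype=complex, format="csr"), blocks, format="coo")
        A = A - sparse.kron(
            sparse.diags(self.damp.astype(complex)), sparse.identity(4, dtype=complex), format="coo"
        )
        for k in range(h.n_terms):
            rows, src, s = self._up_links[k]
            if len(rows):
                P = sparse.coo_matrix((s, (rows, src)), shape=(n, n))
                A = A + sparse.kron(P, comm_L, format="coo")
            rows, src, s = self._down_links[k]
            if len(rows):
                P = sparse.coo_matrix((s.astype(complex), (rows, src)), shape=(n, n))
                M = self.alpha[k] * lmul(L) + self.abar[k] * rmul(L)
                A = A + sparse.kron(P, M, format="coo")
        hx = 0.5 * np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
        Ad = sparse.kron(
            sparse.identity(n, dtype=complex, format="csr"), -1j * (lmul(hx) - rmul(hx)), format="csr"
        )
        return A.tocsr(), Ad

    def rhs(self, t: float, ados: np.ndarray, H: np.ndarray) -> np.ndarray:
        L = self.L
        out = -1j * (H @ ados - ados @ H)
        out -= self.damp[:, None, None] * ados
        if self.gamma_term != 0.0:
            out += self.gamma_term * (
                2.0 * (L @ ados @ L) - (self.LL @ ados + ados @ self.LL)
            )
        for k in range(self.h.n_terms):
            rows, src, s = self._up_links[k]
            if len(rows):
                r = ados[src]
                out[rows] += s[:, None, None] * (L @ r - r @ L)
            rows, src, s = self._down_links[k]
            if len(rows):
                r = ados[src]
                out[rows] += s[:, None, None] * (
                    self.alpha[k] * (L @ r) + self.abar[k] * (r @ L)
                )
        return out


def heom_rhs(
    state: HierarchyState,
    t: float,
    L: np.ndarray,
    p: SystemParams,
    gamma_term: float = 0.0,
) -> HierarchyState:
    """Time derivative of the (scaled) hierarchy state at time t."""
    if state.ados.shape != (state.hierarchy.n_ados, 2, 2):
        raise ValueError("ADO array shape does not match the hierarchy")
    ws = _HeomWorkspace(state.hierarchy, L, gamma_term)
    H = _hamiltonian_matrix(t, p)
    return HierarchyState(state.hierarchy, ws.rhs(t, state.ados, H))


def _hamiltonian_matrix(t: float, p: SystemParams) -> np.ndarray:
    return PauliOp(
        0.0, np.array([0.5 * drive_amplitude(t, p), 0.0, 0.5 * p.epsilon])
    ).to_matrix()


def default_heom_dt(h: Hierarchy, p: SystemParams, b: BathSpec) -> float:
    """Stability-limited RK4 step: fastest hierarchy decay plus oscillation."""
    rate = h.Nc * np.max(np.abs(h.nu.real)) + np.hypot(p.epsilon, p.delta) + b.omega0
    return min(0.02, 1.5 / max(rate, 1e-12))


def propagate_heom(
    rho0: np.ndarray,
    grid: np.ndarray,
    p: SystemParams,
    L: PauliOp | np.ndarray,
    b: BathSpec,
    Nc: int = 5,
    n_matsubara: int = 2,
    dt: float | None = None,
    use_terminator: bool = True,
    per_index_cap: bool = False,
    return_state: bool = False,
):
    """Integrate the hierarchy with fixed-step RK4.

    ``grid`` is the output grid; internally an integer number of RK4
    substeps is taken per output interval with a stability-limited default
    step.  The Bloch vector of the zero-index ADO is returned.
    """
    rho0 = np.asarray(rho0, dtype=complex)
    if rho0.shape != (2, 2):
        raise ValueError("rho0 must be 2x2")
    if abs(np.trace(rho0) - 1.0) > 1e-9 or np.abs(rho0 - rho0.conj().T).max() > 1e-9:
        raise ValueError("rho0 must be a unit-trace Hermitian density matrix")
    grid = np.asarray(grid, dtype=float)
    Lmat = L.to_matrix() if isinstance(L, PauliOp) else np.asarray(L, dtype=complex)

    exp = correlation_expansion(b, n_matsubara)
    h = build_hierarchy(exp, Nc, per_index_cap)
    gamma_term = terminator_coefficient(b, n_matsubara) if use_terminator else 0.0
    ws = _HeomWorkspace(h, Lmat, gamma_term)

    if dt is None:
        dt = default_heom_dt(h, p, b)

    # the hierarchy is linear: precompute the generator as a sparse matrix
    # (static Hamiltonian; the oscillatory drive enters through A_drive)
    H0 = PauliOp(0.0, np.array([0.5 * p.delta, 0.0, 0.5 * p.epsilon])).to_matrix()
    A, Ad = ws.build_sparse(H0)
    driven = p.B0 > 0

    x = np.zeros(h.n_ados * 4, dtype=complex)
    x[:4] = rho0.ravel()
    out = np.empty((len(grid), 3))
    out[0] = density_to_bloch(rho0)
    t = grid[0]

    def f(tt, y):
        d = A @ y
        if driven:
            d += (p.B0 * np.cos(p.omegaB * tt)) * (Ad @ y)
        return d

    for i in range(len(grid) - 1):
        span = grid[i + 1] - grid[i]
        nsub = max(1, int(np.ceil(span / dt)))
        hstep = span / nsub
        for j in range(nsub):
            tj = t + j * hstep
            k1 = f(tj, x)
            k2 = f(tj + 0.5 * hstep, x + 0.5 * hstep * k1)
            k3 = f(tj + 0.5 * hstep, x + 0.5 * hstep * k2)
            k4 = f(tj + hstep, x + hstep * k3)
            x = x + (hstep / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = grid[i + 1]
        rho = x[:4].reshape(2, 2)
        out[i + 1] = density_to_bloch(rho)
        tr = np.trace(rho).real
        if not np.isfinite(tr) or abs(tr - 1.0) > 1e-4:
            raise RuntimeError(
                f"hierarchy lost trace ({tr}) at t={t}; reduce the step or raise Nc"
            )
    traj = BlochTrajectory(times=grid, n_av=out)
    if return_state:
        return traj, HierarchyState(h, x.reshape(h.n_ados, 2, 2))
    return traj
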