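"""Deterministic Bloch-vector propagation of the Redfield master equation.

The reduced density matrix rho = (I + n.sigma)/2 evolves under

    dn/dt = B(t) x n + eta(t) . n + T(t)

where, summing over the eigenbasis channels mu with Pauli vectors a_mu and
time-dependent coefficients Gamma_mu(omega_mu, t) = gamma_mu/2 + i S_mu,

    B(t)   = 2 H_S(t) + 4 Im[Gamma_mu a0_mu a_mu*]          (precession)
    eta(t) = sum_mu 4 Re[Gamma_mu a_mu a_mu*^T] - 2 gamma_mu |a_mu|^2 I
    T(t)   = sum_mu 2 i gamma_mu (a_mu x a_mu*)             (torque)

This is the exact Bloch image of the channel-diagonal (secular) generator

    drho/dt = -i[H_S, rho]
              + sum_mu Gamma_mu (L_mu rho L_mu+ - L_mu+ L_mu rho) + h.c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .bath import BathSpec, CorrelationExpansion, correlation_expansion, dissipation_coefficient
from .model import Channel, PauliOp, SystemParams, drive_amplitude

__all__ = [
    "BlochTrajectory",
    "EOMTerms",
    "GammaCache",
    "eom_terms",
    "bloch_rhs",
    "propagate_redfield",
    "bloch_to_density",
    "density_to_bloch",
    "bloch_density_roundtrip",
]


@dataclass
class BlochTrajectory:
    """Ensemble-averaged Bloch vector time series; |n(t)| <= 1."""

    times: np.ndarray
    n_av: np.ndarray  # shape (nt, 3)

    @property
    def purity(self) -> np.ndarray:
        return np.linalg.norm(self.n_av, axis=1)

    def component(self, axis: str) -> np.ndarray:
        return self.n_av[:, "xyz".index(axis)]


@dataclass
class EOMTerms:
    """Precession field, relaxation tensor and torque at one instant."""

    B: np.ndarray  # (3,)
    eta: np.ndarray  # (3, 3)
    Tvec: np.ndarray  # (3,)

    @property
    def matrix(self) -> np.ndarray:
        """Full linear map: cross(B) + eta."""
        bx, by, bz = self.B
        cross = np.array([[0.0, -bz, by], [bz, 0.0, -bx], [-by, bx, 0.0]])
        return cross + self.eta


class GammaCache:
    """Per-channel Gamma_mu(omega_mu, t) evaluated on demand.

    ``markovian=True`` freezes every coefficient at its long-time value,
    turning the time-dependent (slippage) generator into the standard
    Markovian one.
    """

    def __init__(
        self,
        channels: Sequence[Channel],
        b: BathSpec,
        expansion: CorrelationExpansion | None = None,
        n_matsubara: int = 4,
        markovian: bool = False,
    ):
        self.channels = list(channels)
        self.expansion = expansion if expansion is not None else correlation_expansion(b, n_matsubara)
        self.bath = b
        self.markovian = markovian

    def gammas(self, t) -> np.ndarray:
        """Complex Gamma_mu for each channel; shape (n_channels,) + t.shape."""
        tt = np.full_like(np.asarray(t, dtype=float), np.inf) if self.markovian else t
        return np.array(
            [dissipation_coefficient(ch.omega, tt, self.bath, self.expansion) for ch in self.channels]
        )


def eom_terms(t: float, channels: Sequence[Channel], gammas: np.ndarray, p: SystemParams) -> EOMTerms:
    """Assemble precession, relaxation and torque at time t.

    ``gammas`` holds the complex Gamma_mu(omega_mu, t), one per channel.
    The drive enters the precession field through Delta(t).
    """
    if len(gammas) != len(channels):
        raise ValueError("need one Gamma per channel (missing Gamma cache entry?)")
    hvec = np.array([0.5 * drive_amplitude(t, p), 0.0, 0.5 * p.epsilon])
    B = 2.0 * hvec
    eta = np.zeros((3, 3))
    Tvec = np.zeros(3)
    for ch, G in zip(channels, gammas):
        a = ch.op.avec
        a0 = ch.op.a0
        gam = 2.0 * G.real
        B = B + 4.0 * np.imag(G * a0 * np.conj(a))
        eta = eta + 4.0 * np.real(G * np.outer(a, np.conj(a))) - 2.0 * gam * np.real(
            np.dot(a, np.conj(a))
        ) * np.eye(3)
        Tvec = Tvec + np.real(2.0j * gam * np.cross(a, np.conj(a)))
    return EOMTerms(B=B, eta=eta, Tvec=Tvec)


def bloch_rhs(t: float, n: np.ndarray, terms: EOMTerms) -> np.ndarray:
    """dn/dt = B x n + eta . n + T."""
    return np.cross(terms.B, n) + terms.eta @ n + terms.Tvec


def bloch_to_density(n: np.ndarray) -> np.ndarray:
    """rho = (I + n.sigma)/2; requires |n| <= 1."""
    n = np.asarray(n, dtype=float)
    if np.linalg.norm(n) > 1.0 + 1e-9:
        raise ValueError(f"|n| = {np.linalg.norm(n):.6f} > 1 is unphysical")
    return 0.5 * (np.eye(2, dtype=complex) + PauliOp(0.0, n).to_matrix())


def density_to_bloch(rho: np.ndarray) -> np.ndarray:
    """n = Tr[sigma rho]."""
    op = PauliOp.from_matrix(rho)
    return 2.0 * np.real(op.avec)


def bloch_density_roundtrip(n: np.ndarray) -> np.ndarray:
    """Map a Bloch vector to its density matrix and back (identity)."""
    return density_to_bloch(bloch_to_density(n))


def propagate_redfield(
    n0: np.ndarray,
    grid: np.ndarray,
    p: SystemParams,
    channels: Sequence[Channel],
    cache: GammaCache,
) -> BlochTrajectory:
    """Fixed-step RK4 over the Bloch equation of motion.

    ``grid`` must be uniform; Gamma_mu is evaluated analytically at the
    nodes and half nodes.  Raises if |n| persistently escapes the unit ball
    (step too large).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2:
        raise ValueError("grid must contain at least two times")
    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt, rtol=1e-8):
        raise ValueError("grid must be uniform")
    n0 = np.asarray(n0, dtype=float)
    if np.linalg.norm(n0) > 1.0 + 1e-9:
        raise ValueError("|n0| must be <= 1")

    gam_nodes = cache.gammas(grid).T  # (nt, nch)
    gam_half = cache.gammas(grid[:-1] + 0.5 * dt).T

    out = np.empty((len(grid), 3))
    out[0] = n0
    n = n0.copy()
    overshoot = 0
    for i in range(len(grid) - 1):
        t = grid[i]
        tm = eom_terms(t, channels, gam_nodes[i], p)
        th = eom_terms(t + 0.5 * dt, channels, gam_half[i], p)
        te = eom_terms(t + dt, channels, gam_nodes[i + 1], p)
        k1 = bloch_rhs(t, n, tm)
        k2 = bloch_rhs(t + 0.5 * dt, n + 0.5 * dt * k1, th)
        k3 = bloch_rhs(t + 0.5 * dt, n + 0.5 * dt * k2, th)
        k4 = bloch_rhs(t + dt, n + dt * k3, te)
        n = n + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if np.linalg.norm(n) > 1.0 + 1e-6:
            overshoot += 1
            if overshoot > 10:
                raise RuntimeError(
                    "Bloch vector escaped the unit ball persistently; refine the time step"
                )
        else:
            overshoot = 0
        out[i + 1] = n
    return BlochTrajectory(times=grid, n_av=out)
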