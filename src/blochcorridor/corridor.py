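"""Corridor analytics on the Bloch sphere.

The environment continuously "measures" the system through the dissipation
channels; the admissible quantum paths are confined to a time-dependent
corridor around the stochastic reference path.  Per Bloch component eta the
corridor width is

    delta_eta(t) = [ sum_mu S*_eta,mu  gamma_mu(t)  S_mu,eta ]^(-1/2)

(the harder the environment monitors a direction, the narrower the
corridor), and the quantum-to-classical crossover time is the earliest
time at which the width stops shrinking, |d delta_eta/dt| < eps, or
vanishes.  Displaced path families n(t) = n_ref(t) + kappa * dn/dt carry a
statistical weight

    w[n; xi] = prod_mu exp[- int_0^t (zeta_mu + chi_mu) dt' ]

with the measurement contraction zeta_mu = (gamma_mu/2)|L_mu(n) - l_mu|^2
evaluated through the Pauli decomposition L_mu(n) = L0_mu + Lvec_mu . n;
larger deviations are exponentially suppressed, which is the path picture
of decoherence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import Channel
from .redfield import BlochTrajectory

__all__ = [
    "CorridorWidth",
    "PathFamily",
    "WeightSeries",
    "CrossoverResult",
    "corridor_rates",
    "corridor_width",
    "crossover_time",
    "arbitrary_path",
    "weighting_functional",
    "containment_check",
    "stereographic",
    "stereographic_inverse",
    "reference_phase",
]

#: sentinel for an unconstrained (divergent) corridor width
WIDTH_INF = np.inf


@dataclass
class CorridorWidth:
    times: np.ndarray
    delta_eta: np.ndarray  # (nt, 3), np.inf where unconstrained


@dataclass
class PathFamily:
    """Reference path and its kappa-displaced companion.

    kappa is expressed in multiples of the grid step: the displacement is
    kappa_steps * dt * dn/dt.
    """

    times: np.ndarray
    base: np.ndarray  # (nt, 3)
    kappa: float  # in units of dt
    displaced: np.ndarray  # (nt, 3)
    dn: np.ndarray  # (nt, 3) time derivative of the base path


@dataclass
class WeightSeries:
    times: np.ndarray
    w_abs: np.ndarray  # (nt,)
    zeta: np.ndarray  # (nt, n_channels) real contraction integrand
    chi_im: np.ndarray  # (nt, n_channels) imaginary (phase) part of chi


@dataclass
class CrossoverResult:
    tau_c: np.ndarray  # (3,), np.nan where not reached
    epsilon_threshold: float

    def reached(self) -> np.ndarray:
        return np.isfinite(self.tau_c)


def corridor_rates(channels: Sequence[Channel], gammas: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Effective monitoring rate per eigenbasis axis, shape (3, nt).

    Each channel contributes its rate gamma_mu(t) weighted by twice the
    squared eigen-frame Pauli components of its operator (the transverse
    decay rate of a channel with vector a is 2 gamma |a|^2), accumulated
    on the axes the channel monitors.  ``S`` is the site-to-eigen rotation
    of the Pauli components.
    """
    gam = np.atleast_2d(np.asarray(gammas, dtype=float))
    nt = gam.shape[1]
    out = np.zeros((3, nt))
    for ch, g in zip(channels, gam):
        w = 2.0 * np.abs(np.asarray(S, dtype=float) @ ch.op.avec) ** 2
        out += np.outer(w, g)
    return out


def corridor_width(gammas: np.ndarray, S: np.ndarray, times: np.ndarray | None = None) -> CorridorWidth:
    """delta_eta(t) = [sum_mu S*_eta,mu gamma_mu(t) S_mu,eta]^(-1/2).

    ``gammas`` has one row per channel (aligned with the rows of S); where
    the monitored sum is <= 0 the width is the infinity sentinel.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3) or not np.allclose(S @ S.T, np.eye(3), atol=1e-10):
        raise ValueError("S must be a 3x3 unitary (orthogonal) matrix")
    gam = np.atleast_2d(np.asarray(gammas, dtype=float))
    weights = np.abs(S) ** 2  # |S_mu,eta|^2
    summed = weights.T @ gam  # (3, nt)
    delta = np.full_like(summed, WIDTH_INF)
    pos = summed > 0
    delta[pos] = summed[pos] ** -0.5
    if times is None:
        times = np.arange(gam.shape[1], dtype=float)
    return CorridorWidth(times=np.asarray(times, dtype=float), delta_eta=delta.T)


def crossover_time(width: CorridorWidth, epsilon: float | None = None) -> CrossoverResult:
    """Earliest time with |d delta_eta/dt| < eps or delta_eta = 0.

    Sentinel (infinite) widths are excluded.  The default eps is 1% of the
    largest finite |d delta/dt|; detection starts at that maximum so the
    pre-onset plateau does not trigger trivially.
    """
    t = width.times
    tau = np.full(3, np.nan)
    derivs = []
    for k in range(3):
        d = width.delta_eta[:, k]
        finite = np.isfinite(d)
        if finite.sum() < 3:
            derivs.append(None)
            continue
        derivs.append((t[finite], d[finite], np.gradient(d[finite], t[finite])))
    if epsilon is None:
        peak = max(
            (np.max(np.abs(dv[2])) for dv in derivs if dv is not None), default=0.0
        )
        epsilon = 0.01 * peak
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0 (is the width constant everywhere?)")
    for k, dv in enumerate(derivs):
        if dv is None:
            continue
        tf, df, deriv = dv
        # skip the pre-onset plateau only when the width actually moves
        start = int(np.argmax(np.abs(deriv))) if np.max(np.abs(deriv)) >= epsilon else 0
        hit = np.where((np.abs(deriv) < epsilon) | (df == 0.0))[0]
        hit = hit[hit >= start]
        if len(hit):
            tau[k] = tf[hit[0]]
    return CrossoverResult(tau_c=tau, epsilon_threshold=float(epsilon))


def arbitrary_path(base, kappa: float) -> PathFamily:
    """Displaced path n(t) = n_ref(t) + kappa*dt * dn_ref/dt.

    ``base`` is a BlochTrajectory or (times, path) pair on a uniform grid;
    kappa counts grid steps (the paper's {0, 1, 5, 10, 20} dt convention).
    """
    if isinstance(base, BlochTrajectory):
        times, path = base.times, base.n_av
    else:
        times, path = base
        times = np.asarray(times, dtype=float)
        path = np.asarray(path, dtype=float)
    if len(times) < 3:
        raise ValueError("grid must contain at least 3 points")
    dt = times[1] - times[0]
    dn = np.gradient(path, dt, axis=0)  # central differences, one-sided ends
    displaced = path + kappa * dt * dn
    return PathFamily(times=times, base=path, kappa=kappa, displaced=displaced, dn=dn)


def weighting_functional(
    path: PathFamily,
    channels: Sequence[Channel],
    gammas: np.ndarray,
    record: np.ndarray | None = None,
) -> WeightSeries:
    """|w[n(t); xi(t)]| accumulated along a displaced Bloch path.

    ``gammas`` holds gamma_mu(t) per channel, shape (n_channels, nt),
    clipped at zero while a transient rate is negative (the channel is then
    not monitoring).  ``record`` optionally supplies the stochastic
    measurement variable l_mu(t) per channel, shape (nt, n_channels);
    without it the noiseless record along the reference path is used, so
    the kappa = 0 member carries weight exactly 1.
    """
    t = path.times
    nt = len(t)
    gam = np.atleast_2d(np.asarray(gammas, dtype=float))
    if gam.shape[1] != nt:
        raise ValueError("gamma grid does not match the path grid")
    if record is not None and record.shape[0] != nt:
        raise ValueError("record grid does not match the path grid")
    nch = len(channels)
    zeta = np.zeros((nt, nch))
    chi_im = np.zeros((nt, nch))
    for k, ch in enumerate(channels):
        lv = ch.op.avec
        l0 = ch.op.a0
        l_path = l0 + path.displaced @ lv  # channel expectation along path
        if record is None:
            ell = l0 + path.base @ lv
        else:
            ell = record[:, k]
        g = np.clip(gam[k], 0.0, None)
        zeta[:, k] = 0.5 * g * np.abs(l_path - ell) ** 2
        chi_im[:, k] = g * np.imag(np.conj(l_path) * ell)
    dt = t[1] - t[0]
    integ = np.concatenate([[0.0], np.cumsum(0.5 * dt * (zeta[1:].sum(axis=1) + zeta[:-1].sum(axis=1)))])
    w_abs = np.exp(-integ)
    return WeightSeries(times=t, w_abs=w_abs, zeta=zeta, chi_im=chi_im)


def containment_check(path: PathFamily, width: CorridorWidth):
    """Flag grid points whose deviation exceeds the corridor width.

    Returns (contained, fraction): a boolean (nt, 3) array and the per
    component contained fraction.
    """
    if len(path.times) != len(width.times):
        raise ValueError("path and width grids differ")
    dev = np.abs(path.displaced - path.base)  # |(n - n_ref) . e_eta|
    contained = dev <= width.delta_eta
    return contained, contained.mean(axis=0)


def stereographic(n: np.ndarray) -> tuple[float, float]:
    """(x, y) = (nx/(1-nz), ny/(1-nz)); undefined at the north pole."""
    n = np.asarray(n, dtype=float)
    if abs(n[2] - 1.0) < 1e-12:
        raise ValueError("north pole maps to the point at infinity")
    return float(n[0] / (1.0 - n[2])), float(n[1] / (1.0 - n[2]))


def stereographic_inverse(x: float, y: float) -> np.ndarray:
    """Inverse projection onto the unit sphere."""
    r2 = x * x + y * y
    return np.array([2.0 * x, 2.0 * y, r2 - 1.0]) / (r2 + 1.0)


def reference_phase(path: BlochTrajectory, B0_field: np.ndarray, psi0: complex = 1.0) -> np.ndarray:
    """Coupling-free reference amplitude psi0 exp[-(i/2) int B0 . n dt'].

    ``B0_field`` is the coherent precession field, constant (3,) or per
    time (nt, 3).  The result has constant modulus |psi0|.
    """
    t = path.times
    B = np.asarray(B0_field, dtype=float)
    if B.ndim == 1:
        B = np.tile(B, (len(t), 1))
    integrand = np.einsum("ij,ij->i", B, path.n_av)
    dt = np.diff(t)
    phase = np.concatenate([[0.0], np.cumsum(0.5 * dt * (integrand[1:] + integrand[:-1]))])
    return psi0 * np.exp(-0.5j * phase)
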