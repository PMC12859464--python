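"""Stochastic Langevin-Ito (stochastic Schrodinger) unravelling.

Each trajectory is a normalized pure state |phi(t)> driven by complex
Wiener increments d_xi with M(d_xi* d_xi) = 2 dt.  Per channel mu the step
applies a continuous-measurement contraction and a feedback rotation,

    zeta_mu = (gamma_mu/2) |L_mu - l_mu|^2,
    chi_mu  = (gamma_mu/2) (L_mu+ l_mu - L_mu l_mu*),
    l_mu dt = <L_mu> dt + d_xi_mu / sqrt(2 gamma_mu),

together with the coherent evolution under H_S(t) plus the bath-induced
frequency shift sum_mu S_mu L_mu+ L_mu (Gamma_mu = gamma_mu/2 + i S_mu).
Scalar (identity) parts of the generator only rescale the ray and are
projected out before the Euler-Maruyama update; the state is renormalized
every step.  Averaging the pure-state projectors over the noise recovers
the Redfield master equation with channel rates gamma_mu, and the ensemble
mean of the Bloch vectors is the corridor path.

While a transient gamma_mu(omega, t) <= 0 the channel's noise is
suspended (l_mu = <L_mu>) and only its deterministic part acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Channel, PauliOp, SystemParams, drive_amplitude
from .redfield import BlochTrajectory, GammaCache

__all__ = [
    "StochasticState",
    "NoiseRecord",
    "Ensemble",
    "draw_wiener",
    "measurement_variable",
    "sse_step",
    "stochastic_bloch",
    "run_ensemble",
    "trajectory_seed",
]


@dataclass
class StochasticState:
    """Normalized pure state and its unit Bloch vector."""

    phi: np.ndarray  # (2,) complex, <phi|phi> = 1
    rho0_xi: float = 0.5  # diagnostic scalar weight (unit-trace convention)

    @property
    def n_xi(self) -> np.ndarray:
        return stochastic_bloch(self.phi)


@dataclass
class NoiseRecord:
    """Noise increments and measurement record of one trajectory.

    dxi : (nt-1, n_channels) complex Wiener increments
    ell : (nt-1, n_channels) complex measurement variable l_mu(t)
    """

    seed: int
    dxi: np.ndarray
    ell: np.ndarray


@dataclass
class Ensemble:
    """Streaming summary of a trajectory ensemble."""

    n_traj: int
    mean_path: BlochTrajectory
    spread: np.ndarray  # (nt, 3) componentwise std over trajectories
    master_seed: int
    n_failed: int = 0
    sample_paths: np.ndarray | None = None  # (n_keep, nt, 3) optional
    sample_records: list[NoiseRecord] = field(default_factory=list)


def draw_wiener(dt: float, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Complex increments a + i b, a and b ~ N(0, dt): M(dxi* dxi) = 2 dt."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    z = rng.normal(scale=np.sqrt(dt), size=(n_channels, 2))
    return z[:, 0] + 1j * z[:, 1]


def measurement_variable(phi: np.ndarray, L: np.ndarray, gamma_mu: float, dxi: complex, dt: float):
    """Measurement record l_mu = <L_mu> + dxi / (sqrt(2 gamma_mu) dt).

    Channels with gamma_mu <= 0 carry no record (noise suspended); the
    caller receives the bare expectation value.
    """
    expect = np.vdot(phi, L @ phi)
    if gamma_mu <= 0:
        return expect
    return expect + dxi / (np.sqrt(2.0 * gamma_mu) * dt)


def stochastic_bloch(phi: np.ndarray) -> np.ndarray:
    """Unit Bloch vector of a normalized pure state."""
    a, b = phi
    return np.array(
        [2.0 * np.real(np.conj(a) * b), 2.0 * np.imag(np.conj(a) * b), (abs(a) ** 2 - abs(b) ** 2)]
    )


def _hmat(t: float, p: SystemParams) -> np.ndarray:
    return PauliOp(0.0, np.array([0.5 * drive_amplitude(t, p), 0.0, 0.5 * p.epsilon])).to_matrix()


def sse_step(
    state: StochasticState,
    t: float,
    dt: float,
    noise: np.ndarray,
    channels: Sequence[Channel],
    gammas: np.ndarray,
    p: SystemParams,
) -> tuple[StochasticState, np.ndarray]:
    """One Euler-Maruyama step; returns the new state and the record l_mu.

    ``gammas`` holds the complex Gamma_mu(omega_mu, t) per channel; noise is
    one complex increment per channel.
    """
    phi = state.phi
    if not np.all(np.isfinite(phi)):
        raise RuntimeError(f"non-finite amplitudes entering step at t={t}")
    G = _hmat(t, p).astype(complex)  # accumulates i*(generator); start with H
    ells = np.empty(len(channels), dtype=complex)
    for k, (ch, Gam) in enumerate(zip(channels, gammas)):
        Lm = ch.op.to_matrix()
        gam, S = 2.0 * Gam.real, Gam.imag
        G = G + S * (Lm.conj().T @ Lm)  # bath-induced frequency shift
        dxi = noise[k] if gam > 0 else 0.0
        ell = measurement_variable(phi, Lm, gam, dxi, dt)
        ells[k] = ell
        half = 0.5 * gam
        D = Lm - ell * np.eye(2)
        zeta = half * (D.conj().T @ D)
        chi = half * (Lm.conj().T * ell - Lm * np.conj(ell))
        G = G + (zeta + chi) / 1j  # fold into i*generator: dphi = -i G phi dt
    # remove the scalar (identity) part: it only rescales the ray
    G = G - 0.5 * np.trace(G) * np.eye(2)
    phi_new = phi - 1j * dt * (G @ phi)
    nrm = np.linalg.norm(phi_new)
    if not np.isfinite(nrm) or nrm == 0:
        raise RuntimeError(f"state norm collapsed at t={t}")
    return StochasticState(phi_new / nrm, state.rho0_xi), ells


def trajectory_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic per-trajectory seed stream."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def _run_block(
    phis: np.ndarray,
    grid: np.ndarray,
    channels: Sequence[Channel],
    gam_nodes: np.ndarray,
    p: SystemParams,
    rngs: list[np.random.Generator],
    keep_paths: bool,
    keep_records: bool,
):
    """Vectorized Euler-Maruyama over a block of trajectories.

    phis: (M, 2).  gam_nodes: (nt-1, nch) complex Gamma at the step starts.
    Mathematically identical to iterating :func:`sse_step` per trajectory.
    """
    m = phis.shape[0]
    nt = len(grid)
    nch = len(channels)
    dt = grid[1] - grid[0]
    eye = np.eye(2, dtype=complex)
    Ls = [ch.op.to_matrix() for ch in channels]
    LdL = [Lm.conj().T @ Lm for Lm in Ls]
    # traceless images: scalar parts of the generator only rescale the ray
    Ls_tl = [Lm - 0.5 * np.trace(Lm) * eye for Lm in Ls]
    # per-trajectory noise drawn up front from its own generator (replayable)
    noise = np.empty((m, nt - 1, nch), dtype=complex)
    for i, rng in enumerate(rngs):
        z = rng.normal(scale=np.sqrt(dt), size=(nt - 1, nch, 2))
        noise[i] = z[..., 0] + 1j * z[..., 1]
    paths = np.empty((m, nt, 3)) if keep_paths else None
    records = np.empty((m, nt - 1, nch), dtype=complex) if keep_records else None

    bloch_sum = np.zeros((nt, 3))
    bloch_sq = np.zeros((nt, 3))

    def accumulate(j, phis):
        a, b = phis[:, 0], phis[:, 1]
        nb = np.stack(
            [2 * np.real(np.conj(a) * b), 2 * np.imag(np.conj(a) * b), np.abs(a) ** 2 - np.abs(b) ** 2],
            axis=1,
        )
        bloch_sum[j] += nb.sum(axis=0)
        bloch_sq[j] += (nb**2).sum(axis=0)
        if paths is not None:
            paths[:, j] = nb

    accumulate(0, phis)
    driven = p.B0 > 0
    H0 = _hmat(0.0, p)
    for j in range(nt - 1):
        t = grid[j]
        H = _hmat(t, p) if driven else H0
        Gam = gam_nodes[j]
        # traj-independent part of i*generator
        Gdet = H.astype(complex)
        for k in range(nch):
            S = Gam[k].imag
            gam = 2.0 * Gam[k].real
            Gdet = Gdet + S * LdL[k] - 0.5j * gam * LdL[k]
        Gdet = Gdet - 0.5 * np.trace(Gdet) * eye
        dphi = -1j * dt * (phis @ Gdet.T)
        for k in range(nch):
            gam = 2.0 * Gam[k].real
            Lphi = phis @ Ls[k].T
            expect = np.einsum("ij,ij->i", np.conj(phis), Lphi)
            if gam > 0:
                ell = expect + noise[:, j, k] / (np.sqrt(2.0 * gam) * dt)
            else:
                ell = expect
            if records is not None:
                records[:, j, k] = ell
            # operator part of -(zeta+chi)dt beyond -gam/2 L+L dt (in Gdet):
            # +gam ell* L dt, taken traceless like sse_step's trace removal
            coeff = gam * np.conj(ell) * dt
            dphi += coeff[:, None] * (phis @ Ls_tl[k].T)
        phis = phis + dphi
        phis = phis / np.linalg.norm(phis, axis=1)[:, None]
        if not np.all(np.isfinite(phis)):
            bad = np.where(~np.isfinite(phis).all(axis=1))[0]
            raise RuntimeError(f"non-finite amplitudes in trajectories {bad} at step {j}")
        accumulate(j + 1, phis)
    return bloch_sum, bloch_sq, paths, records, noise


def run_ensemble(
    n_traj: int,
    grid: np.ndarray,
    p: SystemParams,
    channels: Sequence[Channel],
    cache: GammaCache,
    master_seed: int,
    phi0: np.ndarray | None = None,
    block: int = 256,
    keep_paths: int = 0,
) -> Ensemble:
    """Propagate an ensemble and return the corridor path (ensemble mean).

    Per-trajectory seeds derive deterministically from ``master_seed``.
    ``keep_paths`` retains the first few individual Bloch paths and their
    noise records for corridor analysis.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]
    if not np.allclose(np.diff(grid), dt, rtol=1e-8):
        raise ValueError("grid must be uniform")
    if phi0 is None:
        phi0 = np.array([1.0, 0.0], dtype=complex)  # site |1>, Bloch north pole
    phi0 = np.asarray(phi0, dtype=complex)
    phi0 = phi0 / np.linalg.norm(phi0)

    gam_nodes = cache.gammas(grid[:-1]).T  # (nt-1, nch)
    nt = len(grid)
    total_sum = np.zeros((nt, 3))
    total_sq = np.zeros((nt, 3))
    kept_paths = []
    kept_records: list[NoiseRecord] = []
    n_failed = 0
    done = 0
    while done < n_traj:
        m = min(block, n_traj - done)
        rngs = [np.random.default_rng(trajectory_seed(master_seed, done + i)) for i in range(m)]
        keep = keep_paths > len(kept_paths)
        phis = np.tile(phi0, (m, 1))
        try:
            bsum, bsq, paths, records, noise = _run_block(
                phis, grid, channels, gam_nodes, p, rngs, keep, keep
            )
        except RuntimeError:
            n_failed += m
            if n_failed > max(1, 0.01 * n_traj):
                raise RuntimeError(f"{n_failed} failed trajectories (> 1% of ensemble)")
            done += m
            continue
        total_sum += bsum
        total_sq += bsq
        if keep:
            for i in range(min(m, keep_paths - len(kept_paths))):
                kept_paths.append(paths[i])
                kept_records.append(
                    NoiseRecord(seed=done + i, dxi=noise[i], ell=records[i])
                )
        done += m
    n_ok = n_traj - n_failed
    mean = total_sum / n_ok
    var = np.maximum(total_sq / n_ok - mean**2, 0.0)
    return Ensemble(
        n_traj=n_ok,
        mean_path=BlochTrajectory(times=grid, n_av=mean),
        spread=np.sqrt(var),
        master_seed=master_seed,
        n_failed=n_failed,
        sample_paths=np.array(kept_paths) if kept_paths else None,
        sample_records=kept_records,
    )
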