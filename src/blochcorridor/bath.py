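"""Underdamped Brownian bath: spectral density, correlation function,
time-dependent dissipation coefficients and the exponential decomposition
consumed by the HEOM.

The spectral density is

    J(w) = gamma lam^2 w / ((w^2 - w0^2)^2 + gamma^2 w^2)

with resonance w0, width gamma and coupling strength lam, and the finite
temperature bath correlation function

    C(tau) = int_0^inf dw J(w) [coth(beta w / 2) cos(w tau) - i sin(w tau)].

For gamma < 2 w0 (underdamped) the correlation function has the exact pole
expansion

    C(t) = a [ (coth(beta w1/2) + 1) e^{-i W0 t}
             + (coth(beta w1/2)* - 1) e^{+i W0 t} ] e^{-gamma t / 2}
         - sum_n (2 pi gamma lam^2 / beta) nu_n
             / ((nu_n^2 + w0^2)^2 - gamma^2 nu_n^2) e^{-nu_n t},

with a = pi lam^2 / (4 W0), W0 = sqrt(w0^2 - gamma^2/4), w1 = W0 - i gamma/2
and Matsubara frequencies nu_n = 2 pi n / beta.  The cumulative dissipation
coefficient Gamma(w, t) = int_0^t e^{i w tau} C(tau) dtau is then evaluated
term by term in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import integrate

__all__ = [
    "BathSpec",
    "CorrelationExpansion",
    "spectral_density",
    "reorganization_energy",
    "coupling_regime",
    "bath_correlation",
    "correlation_expansion",
    "dissipation_coefficient",
    "gamma_s_split",
    "terminator_coefficient",
]


@dataclass(frozen=True)
class BathSpec:
    """Bath parameters; energies in units of Delta (kB = hbar = 1).

    lam    : system-bath coupling strength (>= 0)
    gamma  : spectral width (> 0)
    omega0 : resonance frequency (> 0); gamma < 2*omega0 (underdamped)
    T      : temperature (> 0)
    """

    lam: float
    gamma: float
    omega0: float
    T: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.gamma <= 0 or self.omega0 <= 0 or self.T <= 0:
            raise ValueError("gamma, omega0 and T must be > 0")
        if self.gamma >= 2.0 * self.omega0:
            raise ValueError("overdamped bath (gamma >= 2*omega0) not supported")

    @property
    def beta(self) -> float:
        return 1.0 / self.T


@dataclass(frozen=True)
class CorrelationExpansion:
    """Exponential decomposition C_R(t) = sum cR e^{-gR t}, same for C_I.

    Amplitudes and rates may be complex (the two resonant terms come as a
    conjugate pair); each reconstructed component is real.
    """

    cR: np.ndarray
    gR: np.ndarray
    cI: np.ndarray
    gI: np.ndarray

    @property
    def NR(self) -> int:
        return len(self.cR)

    @property
    def NI(self) -> int:
        return len(self.cI)

    def real_part(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.sum(self.cR[:, None] * np.exp(-np.outer(self.gR, t)), axis=0)
        return np.real_if_close(out, tol=1e6).real

    def imag_part(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.sum(self.cI[:, None] * np.exp(-np.outer(self.gI, t)), axis=0)
        return np.real_if_close(out, tol=1e6).real

    def full(self, t) -> np.ndarray:
        return self.real_part(t) + 1j * self.imag_part(t)

    def terms(self) -> list[tuple[complex, complex, str]]:
        """All (amplitude, rate, kind) triples, kind in {"R", "I"}."""
        out = [(c, g, "R") for c, g in zip(self.cR, self.gR)]
        out += [(c, g, "I") for c, g in zip(self.cI, self.gI)]
        return out


def spectral_density(omega, b: BathSpec):
    """Underdamped Brownian J(w); vectorized over w >= 0."""
    w = np.asarray(omega, dtype=float)
    return b.gamma * b.lam**2 * w / ((w**2 - b.omega0**2) ** 2 + b.gamma**2 * w**2)


def reorganization_energy(b: BathSpec) -> float:
    """E_ren = int J(w)/w dw = pi lam^2 / (2 w0^2)."""
    return np.pi * b.lam**2 / (2.0 * b.omega0**2)


def coupling_regime(e_ren: float, omega: float) -> Literal["weak", "intermediate", "strong"]:
    """Classify by E_ren/Omega with cutoffs 0.1 and 1.0."""
    if omega <= 0:
        raise ValueError("Omega must be > 0")
    ratio = e_ren / omega
    if ratio < 0.1:
        return "weak"
    if ratio < 1.0:
        return "intermediate"
    return "strong"


def _coth(x):
    # series below ~1e-6 to avoid loss of precision at small argument
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 / np.where(small, x, 1.0) + x / 3.0, 1.0 / np.tanh(safe))
    return out


def bath_correlation(tau: float, b: BathSpec) -> complex:
    """C(tau) by adaptive quadrature of the defining frequency integral.

    Serves as the reference route; the pole expansion reproduces it and is
    used in propagation for speed.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    beta = b.beta
    wmax = b.omega0 + 40.0 * b.gamma
    pts = [max(b.omega0 - b.gamma, 0.0), b.omega0, b.omega0 + b.gamma]

    def re_integrand(w):
        if w < 1e-10 * b.omega0:
            # J(w) coth(beta w/2) -> 2 gamma lam^2 T / w0^4 as w -> 0
            return 2.0 * b.gamma * b.lam**2 * b.T / b.omega0**4
        return spectral_density(w, b) * _coth(0.5 * beta * w) * np.cos(w * tau)

    def im_integrand(w):
        return -spectral_density(w, b) * np.sin(w * tau)

    # subdivision limit grows with tau to resolve the oscillatory integrand
    limit = int(200 + 50 * tau * wmax / (2 * np.pi))
    re, re_err = integrate.quad(re_integrand, 0.0, wmax, points=pts, limit=limit)
    im, im_err = integrate.quad(im_integrand, 0.0, wmax, points=pts, limit=limit)
    # high-frequency tail (coth ~ 1 there); oscillatory weights for tau > 0
    def j_tail(w):
        return spectral_density(w, b)

    if tau == 0.0:
        tr, tr_err = integrate.quad(lambda w: j_tail(w) * _coth(0.5 * beta * w), wmax, np.inf)
        ti, ti_err = 0.0, 0.0
    else:
        tr, tr_err = integrate.quad(
            lambda w: j_tail(w) * _coth(0.5 * beta * w), wmax, np.inf, weight="cos", wvar=tau
        )
        ti, ti_err = integrate.quad(j_tail, wmax, np.inf, weight="sin", wvar=tau)
        ti = -ti
    re, im = re + tr, im + ti
    re_err, im_err = re_err + tr_err, im_err + ti_err
    scale = max(abs(re), abs(im), 1e-300)
    if max(re_err, im_err) > 1e-6 * scale + 1e-12:
        raise RuntimeError(
            f"bath correlation quadrature did not converge at tau={tau}: "
            f"err=({re_err:.2e}, {im_err:.2e}) vs value=({re:.2e}, {im:.2e})"
        )
    return re + 1j * im


def correlation_expansion(b: BathSpec, n_matsubara: int = 2) -> CorrelationExpansion:
    """Pole expansion of C(t): two resonant terms plus Matsubara terms."""
    if n_matsubara < 0:
        raise ValueError("n_matsubara must be >= 0")
    beta = b.beta
    W0 = np.sqrt(b.omega0**2 - b.gamma**2 / 4.0)
    a = np.pi * b.lam**2 / (4.0 * W0)
    w1 = W0 - 0.5j * b.gamma
    cth = 1.0 / np.tanh(0.5 * beta * w1)  # complex coth

    nu1 = 0.5 * b.gamma + 1j * W0
    nu2 = 0.5 * b.gamma - 1j * W0
    cR = [a * cth, a * np.conj(cth)]
    gR = [nu1, nu2]
    cI = [-1j * a, 1j * a]
    gI = [nu1, nu2]
    for n in range(1, n_matsubara + 1):
        nu = 2.0 * np.pi * n / beta
        amp = (
            -(2.0 * np.pi * b.gamma * b.lam**2 / beta)
            * nu
            / ((nu**2 + b.omega0**2) ** 2 - b.gamma**2 * nu**2)
        )
        cR.append(amp)
        gR.append(nu)
    return CorrelationExpansion(
        cR=np.asarray(cR, dtype=complex),
        gR=np.asarray(gR, dtype=complex),
        cI=np.asarray(cI, dtype=complex),
        gI=np.asarray(gI, dtype=complex),
    )


def terminator_coefficient(b: BathSpec, n_matsubara: int, n_tail: int = 20000) -> float:
    """Markovian closure for the truncated Matsubara tail.

    Gamma_T = sum_{n > n_matsubara} c_n / nu_n, folded into the Liouvillian
    as Gamma_T (2 L . L - {L L, .}).  Decays like n^-5, so a finite tail sum
    is converged to machine precision.
    """
    beta = b.beta
    n = np.arange(n_matsubara + 1, n_matsubara + 1 + n_tail, dtype=float)
    nu = 2.0 * np.pi * n / beta
    amp = (
        -(2.0 * np.pi * b.gamma * b.lam**2 / beta)
        * nu
        / ((nu**2 + b.omega0**2) ** 2 - b.gamma**2 * nu**2)
    )
    return float(np.sum(amp / nu))


def dissipation_coefficient(
    omega: float,
    t,
    b: BathSpec,
    expansion: CorrelationExpansion | None = None,
    n_matsubara: int = 4,
):
    """Cumulative half-Fourier transform Gamma(w, t) = int_0^t e^{iw tau} C(tau) dtau.

    Evaluated exactly from the exponential representation of C; ``t`` may be
    an array, and ``t = inf`` returns the Markovian (one-sided Fourier)
    limit.  Gamma = gamma/2 + i S with gamma = 2 Re Gamma.
    """
    if expansion is None:
        expansion = correlation_expansion(b, n_matsubara)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros(t_arr.shape, dtype=complex)
    for c, nu, kind in expansion.terms():
        if kind == "I":  # C(t) = C_R(t) + i C_I(t)
            c = 1j * c
        pole = nu - 1j * omega
        with np.errstate(over="ignore"):
            decay = np.where(np.isinf(t_arr), 0.0, np.exp(-pole * np.where(np.isinf(t_arr), 0.0, t_arr)))
        out += c * (1.0 - decay) / pole
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return complex(out[0])
    return out


def gamma_s_split(gamma_complex):
    """Split Gamma into (gamma, S) with Gamma = gamma/2 + i S."""
    g = np.asarray(gamma_complex)
    return 2.0 * g.real, g.imag
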