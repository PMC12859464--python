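"""Two-level system: Hamiltonian, drive, coupling operators and Pauli algebra.

The system is a spin-boson two-site model

    H_S = (epsilon/2) sigma_z + (Delta/2) sigma_x       (hbar = 1)

with site |1> at the Bloch north pole and |2> at the south pole.  Two
system-bath coupling operators are supported: the transition (dipole-like)
coupling c*sigma_x and the asymmetric local coupling c1|1><1| + c2|2><2|,
which in Pauli form is (c1+c2)/2 * I + (c1-c2)/2 * sigma_z.

Every operator is carried around as a :class:`PauliOp` -- a complex scalar
plus a complex 3-vector of Pauli components -- which is what the
Bloch-vector equation of motion consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SystemParams",
    "CouplingSpec",
    "PauliOp",
    "EigenBasis",
    "DipoleGeometry",
    "Channel",
    "SIGMA",
    "build_hamiltonian",
    "drive_amplitude",
    "dipole_coupling",
    "build_coupling_operator",
    "diagonalize",
    "eigen_lindblads",
]

_SX = np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
_SY = np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
_SZ = np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)
_ID = np.eye(2, dtype=complex)

#: Pauli matrices stacked as (3, 2, 2)
SIGMA = np.stack([_SX, _SY, _SZ])


@dataclass(frozen=True)
class SystemParams:
    """Static system parameters, energies in units of Delta (or cm^-1).

    epsilon : site energy bias between |1> and |2>
    delta   : tunnelling amplitude (electronic coupling), > 0
    B0      : drive amplitude of the time-dependent tunnelling modulation
    omegaB  : drive angular frequency
    """

    epsilon: float
    delta: float
    B0: float = 0.0
    omegaB: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.B0 < 0:
            raise ValueError("B0 must be >= 0")
        if self.omegaB < 0:
            raise ValueError("omegaB must be >= 0")


@dataclass(frozen=True)
class CouplingSpec:
    """System side of the system-bath coupling.

    kind="transition":       L = c * sigma_x
    kind="asymmetric_local":  L = c1 |1><1| + c2 |2><2|; if ``r`` is given
    and ``c2`` is not, c2 = r * c1.
    """

    kind: Literal["transition", "asymmetric_local"]
    c: float | None = None
    c1: float | None = None
    c2: float | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "transition":
            if self.c is None:
                raise ValueError("transition coupling requires c")
            if self.c1 is not None or self.c2 is not None:
                raise ValueError("c1/c2 are not valid for transition coupling")
        elif self.kind == "asymmetric_local":
            if self.c is not None:
                raise ValueError("c is not valid for asymmetric_local coupling")
            if self.c1 is None:
                raise ValueError("asymmetric_local coupling requires c1")
            if self.c2 is None and self.r is None:
                raise ValueError("asymmetric_local coupling requires c2 or r")
            if self.c2 is None:
                object.__setattr__(self, "c2", self.r * self.c1)
        else:  # pragma: no cover - pydantic layer rejects earlier
            raise ValueError(f"unknown coupling kind {self.kind!r}")


@dataclass(frozen=True)
class PauliOp:
    """A 2x2 operator as a0 * I + avec . sigma."""

    a0: complex
    avec: np.ndarray  # shape (3,), complex

    def __post_init__(self) -> None:
        object.__setattr__(self, "avec", np.asarray(self.avec, dtype=complex))
        if self.avec.shape != (3,):
            raise ValueError("avec must be a 3-vector")

    def to_matrix(self) -> np.ndarray:
        return self.a0 * _ID + np.einsum("i,ijk->jk", self.avec, SIGMA)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "PauliOp":
        m = np.asarray(m, dtype=complex)
        if m.shape != (2, 2):
            raise ValueError("expected a 2x2 matrix")
        a0 = 0.5 * np.trace(m)
        avec = 0.5 * np.array([np.trace(s @ m) for s in SIGMA])
        return cls(a0, avec)

    def dagger(self) -> "PauliOp":
        return PauliOp(np.conj(self.a0), np.conj(self.avec))

    @property
    def is_hermitian(self) -> bool:
        return bool(
            abs(np.imag(self.a0)) < 1e-12 and np.all(np.abs(np.imag(self.avec)) < 1e-12)
        )


@dataclass(frozen=True)
class DipoleGeometry:
    """Two point dipoles and their separation (4*pi*eps0 = 1)."""

    d1: Sequence[float]
    d2: Sequence[float]
    r12: Sequence[float]

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "r12"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.linalg.norm(self.r12) == 0:
            raise ValueError("dipole separation |r12| must be > 0")


@dataclass(frozen=True)
class EigenBasis:
    """Eigen decomposition of the static system Hamiltonian.

    Omega   : Bohr frequency sqrt(epsilon^2 + delta^2)
    theta   : mixing angle, tan(theta) = delta/epsilon, theta in (0, pi)
    S       : 3x3 orthogonal matrix mapping site-basis Pauli components to
              eigenbasis components, a' = S a
    eigvecs : columns |+>, |->
    """

    Omega: float
    theta: float
    S: np.ndarray
    eigvecs: np.ndarray


@dataclass(frozen=True)
class Channel:
    """One eigenbasis dissipation channel of the coupling operator.

    mu is "+" (lowering, Bohr frequency +Omega), "-" (raising, -Omega) or
    "z" (diagonal, 0).  ``op`` is the channel operator expressed back in the
    site basis; the three channels sum to the traceless part of L.
    """

    mu: str
    omega: float
    op: PauliOp


def build_hamiltonian(p: SystemParams) -> PauliOp:
    """Static system Hamiltonian (epsilon/2) sigma_z + (delta/2) sigma_x."""
    return PauliOp(0.0, np.array([p.delta / 2.0, 0.0, p.epsilon / 2.0]))


def drive_amplitude(t, p: SystemParams):
    """Time-dependent tunnelling Delta(t) = Delta + B0 cos(omegaB t)."""
    return p.delta + p.B0 * np.cos(p.omegaB * np.asarray(t))


def dipole_coupling(g: DipoleGeometry) -> float:
    """Static dipole-dipole coupling energy with 1/(4 pi eps0) = 1."""
    r = np.linalg.norm(g.r12)
    return float(
        np.dot(g.d1, g.d2) / r**3
        - 3.0 * np.dot(g.d1, g.r12) * np.dot(g.d2, g.r12) / r**5
    )


def build_coupling_operator(spec: CouplingSpec) -> PauliOp:
    """Pauli form of the system coupling operator."""
    if spec.kind == "transition":
        return PauliOp(0.0, np.array([spec.c, 0.0, 0.0]))
    # local projectors: |1><1| = (I + sigma_z)/2, |2><2| = (I - sigma_z)/2
    a0 = (spec.c1 + spec.c2) / 2.0
    az = (spec.c1 - spec.c2) / 2.0
    return PauliOp(a0, np.array([0.0, 0.0, az]))


def diagonalize(p: SystemParams) -> EigenBasis:
    """Eigenbasis of the static Hamiltonian, H_S |+-> = +-(Omega/2)|+->."""
    eps, dlt = p.epsilon, p.delta
    omega = float(np.hypot(eps, dlt))
    if omega == 0:
        raise ValueError("epsilon = delta = 0: degenerate system")
    theta = float(np.arctan2(dlt, eps))  # in (0, pi) for delta > 0
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    eigvecs = np.array([[c, -s], [s, c]], dtype=complex)  # columns |+>, |->
    # Pauli components rotate about y by -theta under U = exp(-i theta sy/2)
    smat = np.array(
        [
            [np.cos(theta), 0.0, -np.sin(theta)],
            [0.0, 1.0, 0.0],
            [np.sin(theta), 0.0, np.cos(theta)],
        ]
    )
    return EigenBasis(Omega=omega, theta=theta, S=smat, eigvecs=eigvecs)


def eigen_lindblads(L: PauliOp, basis: EigenBasis) -> list[Channel]:
    """Decompose a Hermitian coupling operator into eigenbasis channels.

    Returns the three eigenoperators of L with respect to H_S: the lowering
    component |-><+| at Bohr frequency +Omega, the raising component at
    -Omega and the traceless diagonal component at 0.  The identity part of
    L is discarded (it generates no dissipation through these channels).
    """
    if not L.is_hermitian:
        raise ValueError("coupling operator must be Hermitian")
    a_eig = basis.S @ L.avec  # Pauli components in the eigen frame
    ax, ay, az = a_eig
    st = basis.S.T  # inverse rotation back to the site frame
    # sigma_- = (sigma_x - i sigma_y)/2 carries the lowering channel
    amp_low = ax + 1j * ay  # coefficient of sigma_- in L'
    low_eig = amp_low * np.array([0.5, -0.5j, 0.0])
    high_eig = np.conj(amp_low) * np.array([0.5, 0.5j, 0.0])
    z_eig = np.array([0.0, 0.0, az])
    return [
        Channel("+", +basis.Omega, PauliOp(0.0, st @ low_eig)),
        Channel("-", -basis.Omega, PauliOp(0.0, st @ high_eig)),
        Channel("z", 0.0, PauliOp(0.0, st @ z_eig)),
    ]
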