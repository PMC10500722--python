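"""Spin operators, physical constants, and two-spin Hamiltonians.

Unit conventions for the whole package:

* interface frequencies are ordinary frequencies in **MHz** (``nu`` names),
* interface times are **µs** (nanoseconds accepted where noted, converted),
* internal Hamiltonians are **angular frequencies in rad/µs** so that
  ``U = expm(-1j * H * t_us)`` propagates directly.

Since 1 MHz = 1/µs, the conversion is a bare factor of 2π with no power of
ten, which keeps the 2π bookkeeping of mixed frequency/angular-frequency
formulas auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "SpinPairParams",
    "SpinOperatorSet",
    "single_spin_ops",
    "two_spin_ops",
    "dipolar_constant_d",
    "omega_dd",
    "build_two_spin_hamiltonian",
    "MAGIC_ANGLE",
]

#: θ with 1 - 3cos²θ = 0; the dipolar coupling vanishes here.
MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values used by the dipolar coupling prefactor.

    All SI; ``g_free`` is the free-electron g factor.
    """

    mu0_over_4pi: float = 1.00000000055e-7  # T·m/A
    muB: float = 9.2740100783e-24  # J/T
    hbar: float = 1.054571817e-34  # J·s
    g_free: float = 2.00232

    def __post_init__(self) -> None:
        for name in ("mu0_over_4pi", "muB", "hbar", "g_free"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 2.0 <= self.g_free <= 2.01:
            raise ValueError("g_free outside the physical window [2.0, 2.01]")


CONSTANTS = PhysicalConstants()


@dataclass
class SpinPairParams:
    """Physical description of one dipolar-coupled electron-spin pair.

    Parameters
    ----------
    r : float
        Inter-spin distance in nm.
    theta : float
        Angle between the static field and the inter-spin vector, rad,
        restricted to [0, π/2] (the powder problem is symmetric).
    omega1_nu : float
        Drive (Rabi) frequency ν1 in MHz.
    offset1_nu, offset2_nu : float
        Bare resonance offsets Ω1/2π, Ω2/2π in MHz.
    g1, g2 : float
        g factors of the two electrons.
    J_nu : float
        Isotropic exchange coupling J/2π in MHz.
    """

    r: float
    theta: float = math.pi / 2
    omega1_nu: float = 0.0
    offset1_nu: float = 0.0
    offset2_nu: float = 0.0
    g1: float = CONSTANTS.g_free
    g2: float = CONSTANTS.g_free
    J_nu: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.r, self.theta, self.omega1_nu, self.offset1_nu,
                self.offset2_nu, self.g1, self.g2, self.J_nu]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("SpinPairParams fields must be finite")
        if self.r <= 0:
            raise ValueError("inter-spin distance r must be > 0")
        if not 0.0 <= self.theta <= math.pi / 2 + 1e-12:
            raise ValueError("theta must lie in [0, pi/2]")
        if self.omega1_nu < 0:
            raise ValueError("omega1_nu must be >= 0")


# ---------------------------------------------------------------------------
# Operators.  Everything is generated from one Pauli kernel so that sign
# conventions cannot drift between modules.
# ---------------------------------------------------------------------------

_SIGMA = {
    "x": np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
    "y": np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex),
    "z": np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex),
    "e": np.eye(2, dtype=complex),
}


@dataclass(frozen=True)
class SpinOperatorSet:
    """Cartesian spin operators for one or two spin-1/2 particles.

    For two spins the product basis is |αα⟩, |αβ⟩, |βα⟩, |ββ⟩ with spin 1
    as the left Kronecker factor.  ``S1*``/``S2*`` are per-spin operators,
    ``Sx``/``Sy``/``Sz`` the totals.
    """

    dim: int
    S1x: np.ndarray
    S1y: np.ndarray
    S1z: np.ndarray
    S2x: np.ndarray = field(default=None)  # type: ignore[assignment]
    S2y: np.ndarray = field(default=None)  # type: ignore[assignment]
    S2z: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def Sx(self) -> np.ndarray:
        return self.S1x if self.S2x is None else self.S1x + self.S2x

    @property
    def Sy(self) -> np.ndarray:
        return self.S1y if self.S2y is None else self.S1y + self.S2y

    @property
    def Sz(self) -> np.ndarray:
        return self.S1z if self.S2z is None else self.S1z + self.S2z


@lru_cache(maxsize=1)
def single_spin_ops() -> SpinOperatorSet:
    """2×2 operators for an isolated spin-1/2 (cached; do not mutate)."""
    return SpinOperatorSet(
        dim=2,
        S1x=_SIGMA["x"] / 2,
        S1y=_SIGMA["y"] / 2,
        S1z=_SIGMA["z"] / 2,
    )


@lru_cache(maxsize=1)
def two_spin_ops() -> SpinOperatorSet:
    """4×4 product-basis operators for two spin-1/2 particles (cached).

    Also serves the electron–nucleus demonstration system, with the
    electron as spin 1 and the nucleus as spin 2.
    """
    def op(axis: str, which: int) -> np.ndarray:
        a = _SIGMA[axis] / 2
        return np.kron(a, _SIGMA["e"]) if which == 1 else np.kron(_SIGMA["e"], a)

    return SpinOperatorSet(
        dim=4,
        S1x=op("x", 1), S1y=op("y", 1), S1z=op("z", 1),
        S2x=op("x", 2), S2y=op("y", 2), S2z=op("z", 2),
    )


# ---------------------------------------------------------------------------
# Dipolar coupling
# ---------------------------------------------------------------------------

def dipolar_constant_d(r: float, g1: float = CONSTANTS.g_free,
                       g2: float = CONSTANTS.g_free,
                       constants: PhysicalConstants = CONSTANTS) -> float:
    """Dipolar splitting prefactor d in MHz for distance ``r`` in nm.

    d = (1/2π)(μ0/4π)(μB² g1 g2 / ħ) r⁻³, i.e. the ordinary-frequency
    point-dipole coupling constant.  For free-electron g factors this is
    52.04 MHz · (nm/r)³.
    """
    if not (math.isfinite(r) and r > 0):
        raise ValueError("distance r must be finite and > 0")
    r_m = r * 1e-9
    d_rad_per_s = (constants.mu0_over_4pi * constants.muB ** 2 * g1 * g2
                   / constants.hbar / r_m ** 3)
    return d_rad_per_s / TWO_PI * 1e-6  # Hz → MHz


def omega_dd(r: float, theta: float, g1: float = CONSTANTS.g_free,
             g2: float = CONSTANTS.g_free) -> float:
    """Orientation-dependent secular dipolar coupling ωdd in rad/µs.

    ωdd = 2π · d(r) · (1 − 3cos²θ); zero at the magic angle, −2·(2π d)
    at θ = 0 and +2π d at θ = π/2.
    """
    d = dipolar_constant_d(r, g1, g2)
    return TWO_PI * d * (1.0 - 3.0 * math.cos(theta) ** 2)


def build_two_spin_hamiltonian(params: SpinPairParams, drive_nu: float = 0.0,
                               drive_phase: float = 0.0) -> np.ndarray:
    """Rotating-frame Hamiltonian of the driven pair, rad/µs, 4×4.

    H' = Ω1 S1z + Ω2 S2z
         + ωdd (S1z S2z − ½(S1x S2x + S1y S2y))
         + J S1·S2
         + 2π ν1 (cos φ (S1x+S2x) + sin φ (S1y+S2y))

    ``drive_nu`` is a *signed* Rabi frequency in MHz so the phase-inversion
    trick ν1 → −ν1 is a plain sign flip of the drive term.
    """
    if not (math.isfinite(drive_nu) and math.isfinite(drive_phase)):
        raise ValueError("drive parameters must be finite")
    ops = two_spin_ops()
    wdd = omega_dd(params.r, params.theta, params.g1, params.g2)
    H = TWO_PI * params.offset1_nu * ops.S1z
    H = H + TWO_PI * params.offset2_nu * ops.S2z
    H = H + wdd * (ops.S1z @ ops.S2z
                   - 0.5 * (ops.S1x @ ops.S2x + ops.S1y @ ops.S2y))
    if params.J_nu:
        H = H + TWO_PI * params.J_nu * (ops.S1x @ ops.S2x
                                        + ops.S1y @ ops.S2y
                                        + ops.S1z @ ops.S2z)
    if drive_nu:
        H = H + TWO_PI * drive_nu * (math.cos(drive_phase) * ops.Sx
                                     + math.sin(drive_phase) * ops.Sy)
    return H
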