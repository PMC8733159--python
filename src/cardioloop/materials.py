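"""Passive and active constitutive laws for the myocardial wall.

The ventricular wall is a transversely isotropic hyperelastic material
(Guccione): the strain energy is

    W = C/2 (exp(Q) - 1) + K/2 (det F - 1)^2
    Q = b_f E11^2 + b_t (E22^2 + E33^2 + E23^2 + E32^2)
        + b_ft (E12^2 + E21^2 + E13^2 + E31^2)

with E the Green strain in fiber/sheet/normal axes and the quadratic penalty
enforcing near-incompressibility.  Atrial and surrounding tissue use a
compressible Neo-Hooke law in the isochoric-split form

    W = C/2 (I1_bar - 3) + K/2 (J - 1)^2 .

The wall solver works with a one-degree-of-freedom membrane reduction: the
fiber runs circumferentially, the wall is a plane-strain incompressible
membrane, so a circumferential stretch ``lam`` fixes the whole strain state
(E11 = (lam^2-1)/2, E22 = 0, E33 = (lam^-2-1)/2, J = 1) and the passive
tension per unit length follows from T = h0 * lam * dW/dlam.

Active contraction is the classic two-sigmoid ("double Hill") drive: a
rising Hill curve opens the twitch, a falling one closes it, periodic with
the heart period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import KinematicsError

__all__ = [
    "GuccioneParams",
    "NeoHookeParams",
    "StrainState",
    "ActivationParams",
    "MATERIAL_PRESETS",
    "green_strain",
    "guccione_energy",
    "neo_hooke_energy",
    "membrane_tension",
    "active_tension",
    "MMHG_TO_PA",
]

#: Conversion factor: 1 mmHg in Pa.
MMHG_TO_PA = 133.322

#: Argument above which exp(Q) would overflow a float64; the energy is then
#: evaluated at the clipped exponent and flagged.
_Q_CLIP = 700.0


@dataclass(frozen=True)
class GuccioneParams:
    """Guccione law constants.

    C      : shear modulus (Pa)
    b_f    : fiber exponent (dimensionless)
    b_t    : transverse exponent (dimensionless)
    b_ft   : fiber/transverse shear exponent (dimensionless)
    K      : incompressibility penalty modulus (Pa)
    rho0   : tissue density (kg/m^3)
    """

    C: float = 278.0
    b_f: float = 12.0
    b_t: float = 4.8
    b_ft: float = 8.4
    K: float = 200e3
    rho0: float = 1082.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.K <= 0:
            raise ValueError("Guccione moduli C and K must be positive")
        if min(self.b_f, self.b_t, self.b_ft) < 0:
            raise ValueError("Guccione exponents must be non-negative")


@dataclass(frozen=True)
class NeoHookeParams:
    """Neo-Hooke law constants: stiffness C (Pa) and penalty K (Pa)."""

    C: float = 7450.0
    K: float = 200e3
    rho0: float = 1082.0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.K <= 0:
            raise ValueError("Neo-Hooke moduli C and K must be positive")


#: Named parameter rows for the tissue regions of the mechanical model.
#: Only "ventricle" (and, for completeness, "atrium") are used by the wall
#: solver; the remaining rows are carried as presets.
MATERIAL_PRESETS: dict[str, GuccioneParams | NeoHookeParams] = {
    "ventricle": GuccioneParams(C=278.0, b_f=12.0, b_t=4.8, b_ft=8.4,
                                K=200e3, rho0=1082.0),
    "atrium": NeoHookeParams(C=7450.0, K=200e3),
    "pericardium": NeoHookeParams(C=10000.0, K=1000e3),
    "fat": NeoHookeParams(C=3725.0, K=1000e3),
    "vein": NeoHookeParams(C=14900.0, K=200e3),
    "artery": NeoHookeParams(C=14900.0, K=200e3),
    "valve_plane": NeoHookeParams(C=200000.0, K=200e3),
}


@dataclass(frozen=True)
class StrainState:
    """Green strain tensor E (3x3, fiber/sheet/normal axes) and J = det F."""

    E: np.ndarray
    J: float

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        if E.shape != (3, 3):
            raise KinematicsError(f"Green strain must be 3x3, got {E.shape}")
        if self.J <= 0:
            raise KinematicsError(f"non-positive Jacobian J={self.J}")
        object.__setattr__(self, "E", E)


@dataclass(frozen=True)
class ActivationParams:
    """Double-Hill active stress drive.

    T_peak  : peak active fiber stress scale (Pa); the emitted stress is
              T_peak * g1(tau) * g2(tau), whose maximum is below T_peak
              because the two sigmoids overlap only partially.
    alpha1  : phase center of the rising sigmoid (fraction of cycle)
    alpha2  : phase center of the falling sigmoid (fraction of cycle)
    n1, n2  : Hill exponents
    T_cycle : heart period (s), default 1.247
    t_onset : activation delay within the cycle (s)
    """

    T_peak: float = 70e3
    alpha1: float = 0.303
    alpha2: float = 0.508
    n1: float = 1.32
    n2: float = 21.9
    T_cycle: float = 1.247
    t_onset: float = 0.0

    def __post_init__(self) -> None:
        if self.T_cycle <= 0:
            raise ValueError("T_cycle must be positive")
        if not (0 < self.alpha1 < self.alpha2 < 1):
            raise ValueError("need 0 < alpha1 < alpha2 < 1")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("Hill exponents must be >= 1")


def green_strain(F: np.ndarray) -> StrainState:
    """Green strain E = (F^T F - I)/2 and Jacobian J = det F.

    Raises :class:`KinematicsError` when det F <= 0.
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (3, 3):
        raise KinematicsError(f"deformation gradient must be 3x3, got {F.shape}")
    J = float(np.linalg.det(F))
    if J <= 0:
        raise KinematicsError(f"non-positive det(F) = {J}")
    E = 0.5 * (F.T @ F - np.eye(3))
    return StrainState(E=E, J=J)


def _guccione_Q(E: np.ndarray, p: GuccioneParams) -> float:
    return float(
        p.b_f * E[0, 0] ** 2
        + p.b_t * (E[1, 1] ** 2 + E[2, 2] ** 2 + E[1, 2] ** 2 + E[2, 1] ** 2)
        + p.b_ft * (E[0, 1] ** 2 + E[1, 0] ** 2 + E[0, 2] ** 2 + E[2, 0] ** 2)
    )


def guccione_energy(strain: StrainState, p: GuccioneParams,
                    *, return_flags: bool = False):
    """Guccione strain-energy density W (Pa).

    W = C/2 (e^Q - 1) + K/2 (J - 1)^2 with Q the anisotropic quadratic form
    of the Green strain.  If Q exceeds the float overflow bound it is clipped
    and (with ``return_flags=True``) the result carries ``clipped=True``.
    """
    Q = _guccione_Q(strain.E, p)
    clipped = Q > _Q_CLIP
    W = 0.5 * p.C * math.expm1(min(Q, _Q_CLIP)) + 0.5 * p.K * (strain.J - 1.0) ** 2
    if return_flags:
        return W, clipped
    return W


def neo_hooke_energy(strain: StrainState, p: NeoHookeParams) -> float:
    """Isochoric-split Neo-Hooke energy density W (Pa).

    W = C/2 (I1_bar - 3) + K/2 (J - 1)^2 where I1_bar = J^(-2/3) tr(F^T F)
    = J^(-2/3) (tr(2E) + 3).
    """
    I1 = 2.0 * float(np.trace(strain.E)) + 3.0
    I1_bar = strain.J ** (-2.0 / 3.0) * I1
    return 0.5 * p.C * (I1_bar - 3.0) + 0.5 * p.K * (strain.J - 1.0) ** 2


def _membrane_strain(lam: float) -> tuple[float, float]:
    """E11 and E33 of the plane-strain incompressible membrane at stretch lam."""
    return 0.5 * (lam * lam - 1.0), 0.5 * (lam ** -2 - 1.0)


def membrane_energy(lam, p: GuccioneParams):
    """Energy density W(lam) of the membrane reduction (J = 1 exactly).

    Vectorized over ``lam``; used by :func:`membrane_tension` and the
    finite-difference cross-checks.
    """
    lam = np.asarray(lam, dtype=float)
    E11 = 0.5 * (lam * lam - 1.0)
    E33 = 0.5 * (lam ** -2.0 - 1.0)
    Q = p.b_f * E11 ** 2 + p.b_t * E33 ** 2
    return 0.5 * p.C * np.expm1(np.minimum(Q, _Q_CLIP))


def membrane_tension(lam, p: GuccioneParams, h0: float = 0.01):
    """Passive circumferential tension per unit length T(lam) (N/m).

    Constrained kinematics: fiber circumferential, E11 = (lam^2-1)/2,
    E22 = 0, E33 = (lam^-2-1)/2, J = 1.  T = h0 * lam * dW/dlam with the
    derivative taken analytically:

        dW/dlam = C/2 e^Q (2 b_f E11 lam - 2 b_t E33 lam^-3).

    T(1) = 0 by construction.  Vectorized over ``lam``.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise KinematicsError("stretch lam must be positive")
    E11 = 0.5 * (lam_arr * lam_arr - 1.0)
    E33 = 0.5 * (lam_arr ** -2.0 - 1.0)
    Q = p.b_f * E11 ** 2 + p.b_t * E33 ** 2
    dWdlam = 0.5 * p.C * np.exp(np.minimum(Q, _Q_CLIP)) * (
        2.0 * p.b_f * E11 * lam_arr - 2.0 * p.b_t * E33 * lam_arr ** -3.0
    )
    T = h0 * lam_arr * dWdlam
    if np.isscalar(lam) or np.ndim(lam) == 0:
        return float(T)
    return T


def active_tension(t, p: ActivationParams):
    """Active fiber stress a(t) (Pa) of the double-Hill drive.

    a(tau) = T_peak * g1(tau) * g2(tau),
    g1 = (tau/a1)^n1 / (1 + (tau/a1)^n1),  g2 = 1 / (1 + (tau/a2)^n2),
    tau = ((t - t_onset) mod T_cycle) / T_cycle.

    Periodic with period T_cycle; zero at tau = 0.  Vectorized over ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    tau = np.mod(t_arr - p.t_onset, p.T_cycle) / p.T_cycle
    r1 = (tau / p.alpha1) ** p.n1
    g1 = r1 / (1.0 + r1)
    g2 = 1.0 / (1.0 + (tau / p.alpha2) ** p.n2)
    a = p.T_peak * g1 * g2
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(a)
    return a


def with_peak(p: ActivationParams, T_peak: float) -> ActivationParams:
    """Copy of activation parameters with a different stress scale."""
    return replace(p, T_peak=T_peak)
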