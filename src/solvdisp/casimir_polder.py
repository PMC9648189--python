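"""Second-order perturbation-theory machinery for dispersion energies.

Brute-force, dipole-level implementations of the sum-over-states
dispersion energy, the Casimir-Polder imaginary-frequency integral, the
London closed form, and their Omega-shifted generalizations for an excited
reference state.  These routines are deliberately independent of the
field-fluctuation pipeline: they serve as oracles that pin down every
closed-form constant used there, but they are a public API in their own
right for discrete-level model systems.

Conventions: energies in Hartree, dipoles in atomic units.  For a system
with reference state |ref> and levels x, the orientation-averaged exact
C6 between two ground-state systems is

    C6 = (2/3) sum_{x,y} |mu_x|^2 |mu_y|^2 / (u_x + v_y)
       = (3/pi) Integral_0^inf alpha_A(i w) alpha_B(i w) dw,

with alpha(i w) = (2/3) sum_x |mu_x|^2 u_x / (u_x^2 + w^2).  For an
excited reference of A, de-excitation channels have u_x < 0; with the
auxiliary shift Omega such that every u_x + Omega > 0 and every solvent
denominator v_y - Omega > 0, the same integral transform applies to the
shifted polarizabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad

from ._tables import transition_system_table


@dataclass(frozen=True)
class Level:
    energy: float                 # Hartree, absolute
    dipole: np.ndarray            # <ref| mu |level>, a.u., 3-vector

    def __post_init__(self):
        object.__setattr__(self, "dipole", np.asarray(self.dipole, float))
        if self.dipole.shape != (3,):
            raise ValueError("dipole must be a 3-vector")


@dataclass(frozen=True)
class TransitionSystem:
    """Discrete electronic levels with dipole couplings to one reference."""

    levels: tuple
    reference_state: int = 0

    def __post_init__(self):
        e = [lv.energy for lv in self.levels]
        if len(set(np.round(e, 12))) != len(e):
            raise ValueError("level energies must be distinct")
        if not 0 <= self.reference_state < len(self.levels):
            raise ValueError("reference_state out of range")

    @property
    def transition_energies(self) -> np.ndarray:
        """u_x = E_x - E_ref for x != ref (negative for de-excitations)."""
        ref = self.levels[self.reference_state].energy
        return np.array([lv.energy - ref for i, lv in enumerate(self.levels)
                         if i != self.reference_state])

    @property
    def dipole_strengths(self) -> np.ndarray:
        """|mu_x|^2 for x != ref."""
        return np.array([float(lv.dipole @ lv.dipole)
                         for i, lv in enumerate(self.levels)
                         if i != self.reference_state])

    @property
    def dipoles(self) -> np.ndarray:
        return np.array([lv.dipole for i, lv in enumerate(self.levels)
                         if i != self.reference_state])

    @property
    def is_ground_reference(self) -> bool:
        return bool(np.all(self.transition_energies > 0))

    def static_polarizability(self) -> float:
        u = self.transition_energies
        return float(2.0 / 3.0 * np.sum(self.dipole_strengths / u))


def load_transition_system(name: str) -> TransitionSystem:
    """Packaged discrete-level fixtures (documented dipoles, deterministic)."""
    df = transition_system_table()
    rows = df[df.system == name]
    if rows.empty:
        raise KeyError(f"unknown transition system {name!r}; "
                       f"known: {sorted(df.system.unique())}")
    rows = rows.sort_values("level")
    levels = tuple(Level(float(r.energy_hartree),
                         np.array([r.mux, r.muy, r.muz]))
                   for r in rows.itertuples())
    return TransitionSystem(levels, int(rows.iloc[0].reference_index))


@dataclass(frozen=True)
class C6Coefficient:
    value: float
    method: str  # exact-sum | cp-quadrature | london | modified-omega


# ---------------------------------------------------------------------------
# exact second-order sum
# ---------------------------------------------------------------------------

def dispersion_sum(A: TransitionSystem, B: TransitionSystem, R: float,
                   orientation_averaged: bool = True) -> float:
    """Second-order dipole-dipole dispersion energy at separation R (bohr).

    Exact double sum over simultaneous transitions of A and B (reference
    states excluded).  With orientation averaging each pair contributes
    -(2/3)|mu_A|^2 |mu_B|^2 / (u+v) / R^6; without it the molecules sit on
    the z axis and the full dipole-interaction tensor is contracted.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    uA, uB = A.transition_energies, B.transition_energies
    denom = uA[:, None] + uB[None, :]
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("resonance: a simultaneous transition-energy sum is zero")
    if orientation_averaged:
        num = (2.0 / 3.0) * np.outer(A.dipole_strengths, B.dipole_strengths)
    else:
        dA, dB = A.dipoles, B.dipoles
        # dipole-dipole coupling for separation along z: x.x + y.y - 2 z.z
        m = (dA[:, None, 0] * dB[None, :, 0] + dA[:, None, 1] * dB[None, :, 1]
             - 2.0 * dA[:, None, 2] * dB[None, :, 2])
        num = m * m
    return float(-np.sum(num / denom) / R**6)


# ---------------------------------------------------------------------------
# Casimir-Polder integrals
# ---------------------------------------------------------------------------

def cp_quadrature(u: float, v: float) -> float:
    """(2/pi) Integral_0^inf u v / ((u^2+w^2)(v^2+w^2)) dw, numerically.

    The analytic value of this kernel is 1/(u+v); the adaptive quadrature
    here is the independent check of that identity.
    """
    if u <= 0 or v <= 0:
        raise ValueError("u and v must be positive")
    val, _ = quad(lambda w: u * v / ((u * u + w * w) * (v * v + w * w)),
                  0.0, np.inf, epsabs=1e-14, epsrel=1e-13)
    return 2.0 / math.pi * val


def polarizability_iw(system: TransitionSystem, omega_imag: float,
                      shift: float = 0.0) -> float:
    """Sum-over-states dynamic polarizability at imaginary frequency.

    alpha(i w) = (2/3) sum_x |mu_x|^2 (u_x + shift)/((u_x + shift)^2 + w^2).
    `shift` is the Omega offset applied to every transition energy (0 for
    the plain polarizability).  At w = 0 this is the (shifted) static sum.
    """
    u = system.transition_energies + shift
    s = system.dipole_strengths
    return float(2.0 / 3.0 * np.sum(s * u / (u * u + omega_imag**2)))


def polarizability_real(system: TransitionSystem, omega: float) -> float:
    """alpha(Omega) at real frequency (ground reference, below resonance)."""
    u = system.transition_energies
    s = system.dipole_strengths
    return float(2.0 / 3.0 * np.sum(s * u / (u * u - omega**2)))


def drude_polarizability(alpha0: float, I: float, omega_imag: float) -> float:
    """One-pole model alpha(i w) = alpha(0) * I^2/(I^2 + w^2)."""
    if alpha0 <= 0 or I <= 0:
        raise ValueError("alpha0 and I must be positive")
    return alpha0 * I * I / (I * I + omega_imag**2)


def c6_quadrature(alpha_A: Callable[[float], float],
                  alpha_B: Callable[[float], float]) -> C6Coefficient:
    """C6 = (3/pi) Integral alpha_A(i w) alpha_B(i w) dw by adaptive quadrature."""
    val, _ = quad(lambda w: alpha_A(w) * alpha_B(w), 0.0, np.inf,
                  epsabs=1e-13, epsrel=1e-12, limit=400)
    return C6Coefficient(3.0 / math.pi * val, "cp-quadrature")


def c6_exact_sum(A: TransitionSystem, B: TransitionSystem) -> C6Coefficient:
    """Orientation-averaged exact C6 from the double sum over transitions."""
    uA, uB = A.transition_energies, B.transition_energies
    denom = uA[:, None] + uB[None, :]
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("resonance: a simultaneous transition-energy sum is zero")
    num = np.outer(A.dipole_strengths, B.dipole_strengths)
    return C6Coefficient(float(2.0 / 3.0 * np.sum(num / denom)), "exact-sum")


def london_c6(alphaA: float, IA: float, alphaB: float, IB: float) -> C6Coefficient:
    """London's closed form C6 = (3/2) aA aB IA IB / (IA + IB)."""
    if min(alphaA, IA, alphaB, IB) <= 0:
        raise ValueError("all London inputs must be positive")
    return C6Coefficient(1.5 * alphaA * alphaB * IA * IB / (IA + IB), "london")


def gamma_factor_quadrature(W_A: float, W_B: float) -> float:
    """Numerical (2/pi) Integral W_A/(W_A^2+w^2) * W_B^2/(W_B^2+w^2) dw.

    Equals W_B/(W_A + W_B) analytically; this is the frequency factor of
    the solvation prefactor, exposed for cross-checking the closed form.
    """
    if W_A <= 0 or W_B <= 0:
        raise ValueError("W_A and W_B must be positive")
    val, _ = quad(lambda w: W_A / (W_A**2 + w * w) * W_B**2 / (W_B**2 + w * w),
                  0.0, np.inf, epsabs=1e-14, epsrel=1e-13)
    return 2.0 / math.pi * val


# ---------------------------------------------------------------------------
# Omega-shifted (excited-reference) C6
# ---------------------------------------------------------------------------

def modified_alpha_static(alpha0: float, alpha_omega: float, I_B: float,
                          omega: float) -> float:
    """Modified static solvent polarizability
    abar_B(0) = 2 alpha_B(Omega) - alpha_B(0) I_B/(I_B + Omega).

    Follows from 1/(v-Omega) = 2v/(v^2-Omega^2) - 1/(v+Omega) with the
    average-energy closure applied only to the regular second term.
    Energies in Hartree.
    """
    return 2.0 * alpha_omega - alpha0 * I_B / (I_B + omega)


def modified_c6(A, B: tuple, omega: float) -> C6Coefficient:
    """Omega-shifted van der Waals coefficient for an excited solute A.

    A is either a TransitionSystem whose reference may be an excited state,
    or a pair (abar_A0, W_A) of a modified static polarizability and its
    effective frequency.  B is always the pair (abar_B0, W_B).  `omega` is
    the auxiliary shift in Hartree; it must exceed every de-excitation
    energy of A (so all shifted denominators are positive) and satisfy
    W_B > 0.

    Closed forms (single-pole B):
      - model A:  C6 = (3/2) abar_A0 abar_B0 W_A W_B / (W_A + W_B)
      - exact A:  C6 = sum_x |mu_x|^2 abar_B0 W_B / (u_x + Omega + W_B)
    Both are the exact Casimir-Polder integrals of the corresponding
    shifted polarizability models, and reduce to London's formula at
    Omega = 0 for a ground-state reference.
    """
    abar_B0, W_B = B
    if abar_B0 <= 0:
        raise ValueError("modified solvent polarizability must be positive")
    if W_B <= 0:
        raise ValueError("W_B = I_B - Omega must be positive")
    if isinstance(A, TransitionSystem):
        u = A.transition_energies
        if np.any(u + omega <= 0):
            raise ValueError(
                "Omega too small: a de-excitation of A could excite B "
                "(a shifted transition energy is non-positive)")
        s = A.dipole_strengths
        value = float(np.sum(s * abar_B0 * W_B / (u + omega + W_B)))
    else:
        abar_A0, W_A = A
        if abar_A0 <= 0 or W_A <= 0:
            raise ValueError("modified solute polarizability inputs must be positive")
        value = 1.5 * abar_A0 * abar_B0 * W_A * W_B / (W_A + W_B)
    return C6Coefficient(value, "modified-omega")
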