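"""Solvent model: refractive-index dispersion, Clausius-Mossotti response,
the auxiliary frequency Omega, and the Casimir-Polder prefactor Gamma.

A solvent B is characterized by its static refractive index eta(0), the
Cauchy-type coefficients A2, A4 of the frequency-dependent index

    eta(Omega) = eta(0) + A2*Omega^2 + A4*Omega^4     (Omega in eV),

its ionization potential I_B (Hartree) and the onset of its first
electronic absorption (eV).  The number density of solvent polarizability
enters only through the Clausius-Mossotti factor
CM(eta) = (eta^2 - 1)/(eta^2 + 2).

For a solute excited state the Casimir-Polder integration over imaginary
frequency requires an auxiliary energy Omega strictly between the solute
vertical transition energy and the solvent absorption onset (so that no
de-excitation of the solute can excite the solvent).  The effective
oscillator frequencies are then shifted in opposite directions,

    W_A = I_A + Omega,    W_B = I_B - Omega,

and the prefactor multiplying the exterior integral of S^2 becomes

    Gamma(Omega) = (3/8pi) * [2*CM(eta(Omega)) - CM(eta(0))*I_B/(I_B+Omega)]
                   * W_B / (W_A + W_B),

which at Omega = 0 reduces exactly to the ground-state prefactor
(3/8pi) * CM(eta(0)) * I_B/(I_A + I_B).  The bracket is the modified
solvent response: the dynamic (real-frequency) Clausius-Mossotti term is
kept exact because it can be resonantly enhanced as Omega approaches the
solvent absorption onset, and the average-energy (Unsold) closure is
applied only to the regular remainder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from ._tables import solvent_table
from .model_systems import ElectronicState
from .units import HARTREE_TO_EV


@dataclass(frozen=True)
class SolventModel:
    """Optical and ionization data of one solvent."""

    name: str
    eta0: float
    A2: float       # per eV^2
    A4: float       # per eV^4
    ionization_potential: float  # Hartree
    first_absorption: float | None = None  # eV, onset of solvent absorption

    def __post_init__(self):
        if self.eta0 <= 1.0:
            raise ValueError("eta0 must exceed 1")
        if self.ionization_potential <= 0:
            raise ValueError("ionization potential must be positive")
        if self.first_absorption is not None and self.first_absorption <= 0:
            raise ValueError("first_absorption must be positive (eV)")

    @classmethod
    def from_table(cls, name: str, *, first_absorption: float | None = None
                   ) -> "SolventModel":
        tab = solvent_table()
        if name not in tab.index:
            raise KeyError(f"unknown solvent {name!r}; known: {list(tab.index)}")
        row = tab.loc[name]
        onset = first_absorption
        if onset is None and not np.isnan(row.first_absorption_ev):
            onset = float(row.first_absorption_ev)
        return cls(name=name, eta0=float(row.eta0), A2=float(row.A2),
                   A4=float(row.A4),
                   ionization_potential=float(row.ionization_hartree),
                   first_absorption=onset)


def available_solvents() -> list[str]:
    return list(solvent_table().index)


def refractive_index(solvent: SolventModel, omega_ev: float) -> float:
    """eta(Omega) from the even-polynomial dispersion fit (Omega in eV)."""
    if omega_ev < 0:
        raise ValueError("frequency must be non-negative")
    if solvent.first_absorption is not None and omega_ev > solvent.first_absorption:
        warnings.warn(f"{solvent.name}: eta evaluated above the absorption onset "
                      f"({omega_ev} > {solvent.first_absorption} eV); the "
                      "transparent-region fit is extrapolated", stacklevel=2)
    w2 = omega_ev * omega_ev
    return solvent.eta0 + solvent.A2 * w2 + solvent.A4 * w2 * w2


def clausius_mossotti(eta: float) -> float:
    """(eta^2 - 1)/(eta^2 + 2): polarizability density of the medium."""
    if eta < 1.0:
        raise ValueError("refractive index must be >= 1")
    e2 = eta * eta
    return (e2 - 1.0) / (e2 + 2.0)


@dataclass(frozen=True)
class OmegaChoice:
    """A validated auxiliary frequency (eV) with its admissible interval."""

    omega: float
    valid_interval: tuple  # (solute vertical energy, solvent onset), eV

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("Omega must be >= 0 (eV)")


def validate_omega(omega_ev: float, solute_state: ElectronicState,
                   solvent: SolventModel) -> OmegaChoice:
    """Check the admissibility of Omega for a solute state in a solvent.

    Ground state: only Omega = 0.  Excited state: the solute vertical
    transition energy must satisfy DeltaE_A < Omega < solvent onset, so the
    de-excitation of the solute cannot excite the solvent and every shifted
    transition energy stays positive.
    """
    if solute_state.label == "ground":
        if omega_ev != 0.0:
            raise ValueError("ground-state calculations require Omega = 0")
        return OmegaChoice(0.0, (0.0, 0.0))
    de = solute_state.vertical_transition_energy
    onset = solvent.first_absorption
    if onset is None:
        raise ValueError(
            f"solvent {solvent.name!r} has no packaged absorption onset; "
            "supply first_absorption= when constructing the SolventModel")
    if not (de < omega_ev < onset):
        raise ValueError(
            f"Omega = {omega_ev} eV outside the admissible interval "
            f"({de} eV, {onset} eV) for this solute state in {solvent.name}")
    return OmegaChoice(float(omega_ev), (float(de), float(onset)))


@dataclass(frozen=True)
class GammaPrefactor:
    """The assembled prefactor and its components.

    value has units such that value * integral(S^2 d^3r) is in Hartree.
    """

    value: float
    cm_static: float
    cm_omega: float
    W_A: float   # Hartree
    W_B: float   # Hartree
    omega_A: float  # Hartree (solute characteristic frequency, = I_A)
    omega_B: float  # Hartree (solvent characteristic frequency, = I_B)
    omega_ev: float
    eta_omega: float
    solvent_name: str


def gamma_prefactor(solute_state: ElectronicState, solvent: SolventModel,
                    omega: OmegaChoice, *, eta_omega_override: float | None = None
                    ) -> GammaPrefactor:
    """Casimir-Polder prefactor Gamma_A(B)(Omega).

    `eta_omega_override` substitutes the polynomial eta(Omega) when the
    dispersion fit does not reach Omega (deep-UV extrapolations).
    """
    i_a = solute_state.ionization_potential
    i_b = solvent.ionization_potential
    om = omega.omega / HARTREE_TO_EV  # Hartree
    w_a = i_a + om
    w_b = i_b - om
    if w_a <= 0 or w_b <= 0:
        raise ValueError(
            f"shifted frequencies must stay positive (W_A={w_a:.4f}, "
            f"W_B={w_b:.4f} Hartree): the method is inapplicable at this Omega")
    eta_om = (eta_omega_override if eta_omega_override is not None
              else refractive_index(solvent, omega.omega))
    cm0 = clausius_mossotti(solvent.eta0)
    cmw = clausius_mossotti(eta_om)
    bracket = 2.0 * cmw - cm0 * i_b / (i_b + om)
    value = 3.0 / (8.0 * math.pi) * bracket * w_b / (w_a + w_b)
    return GammaPrefactor(value=value, cm_static=cm0, cm_omega=cmw,
                          W_A=w_a, W_B=w_b, omega_A=i_a, omega_B=i_b,
                          omega_ev=omega.omega, eta_omega=eta_om,
                          solvent_name=solvent.name)
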