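"""Physical constants and unit conversions.

All internal quantities are in Hartree atomic units (lengths in bohr,
energies in Hartree).  Conversions happen only at the I/O boundary.
Constants are CODATA-2018 and are deliberately frozen here so that
reported numbers are reproducible independent of the scipy version.
"""

from __future__ import annotations

HARTREE_TO_EV = 27.211386245988
EV_TO_WAVENUMBER = 8065.543937  # 1 eV in cm^-1
EV_NM = 1239.841984332  # h*c in eV*nm
BOHR_TO_ANGSTROM = 0.529177210903

_ENERGY_TO_EV = {
    "hartree": HARTREE_TO_EV,
    "ev": 1.0,
    "cm-1": 1.0 / EV_TO_WAVENUMBER,
}

_ALIASES = {
    "hartree": "hartree",
    "ha": "hartree",
    "au": "hartree",
    "ev": "ev",
    "cm-1": "cm-1",
    "cm^-1": "cm-1",
    "1/cm": "cm-1",
    "wavenumber": "cm-1",
    "nm": "nm",
}


def _canonical(unit: str) -> str:
    try:
        return _ALIASES[unit.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown unit {unit!r}; expected one of "
                         "Hartree, eV, cm-1, nm") from None


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy (or wavelength-equivalent) between units.

    Supported units: Hartree, eV, cm-1, nm.  Wavelength (nm) is the
    reciprocal of energy through E[eV] = 1239.841984.../lambda[nm]; the
    sign of an energy is carried through linear conversions unchanged.
    """
    src, dst = _canonical(from_unit), _canonical(to_unit)
    if src == dst:
        return float(value)
    # to eV
    if src == "nm":
        ev = EV_NM / value
    else:
        ev = value * _ENERGY_TO_EV[src]
    # from eV
    if dst == "nm":
        return EV_NM / ev
    return ev / _ENERGY_TO_EV[dst]
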