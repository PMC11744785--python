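"""Physical constants and unit conversions (CODATA via scipy).

All internal math is done in Hartree atomic units; this module is the single
place where conversions to/from experimental units (Å, eV, cm⁻¹, nm,
L mol⁻¹ cm⁻¹) are defined.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _c

# --- fundamental (SI) ---
AVOGADRO = _c.N_A
SPEED_OF_LIGHT = _c.c  # m/s
PLANCK = _c.h  # J s
HBAR = _c.hbar  # J s
ELEMENTARY_CHARGE = _c.e  # C
ELECTRON_MASS = _c.m_e  # kg
EPSILON_0 = _c.epsilon_0  # F/m
BOHR_MAGNETON = _c.physical_constants["Bohr magneton"][0]  # J/T

# --- atomic units ---
BOHR_RADIUS = _c.physical_constants["Bohr radius"][0]  # m
HARTREE = _c.physical_constants["Hartree energy"][0]  # J
HARTREE_EV = _c.physical_constants["Hartree energy in eV"][0]
FINE_STRUCTURE = _c.fine_structure
SPEED_OF_LIGHT_AU = 1.0 / FINE_STRUCTURE  # ≈ 137.036

# 1 Å = 1/0.52917721 Bohr
ANGSTROM_TO_BOHR = 1e-10 / BOHR_RADIUS
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

# --- energy-scale conversions ---
EV_TO_HARTREE = 1.0 / HARTREE_EV
# E [J] = h c ν̃ [1/m]; wavenumbers conventionally in cm⁻¹
CM1_TO_HARTREE = PLANCK * SPEED_OF_LIGHT * 100.0 / HARTREE
EV_TO_CM1 = EV_TO_HARTREE / CM1_TO_HARTREE
# λ [nm] · E [eV] = hc in eV·nm
HC_EV_NM = PLANCK * SPEED_OF_LIGHT / ELEMENTARY_CHARGE * 1e9


def ev_to_nm(energy_ev: float | np.ndarray) -> float | np.ndarray:
    return HC_EV_NM / np.asarray(energy_ev, dtype=float)


def nm_to_hartree(wavelength_nm: float | np.ndarray) -> float | np.ndarray:
    return HC_EV_NM / np.asarray(wavelength_nm, dtype=float) * EV_TO_HARTREE


_DAMPING_UNITS = {
    "ev": 1.0,
    "cm-1": 1.0 / EV_TO_CM1,
    "hartree": HARTREE_EV,
}


def convert_damping(value: float, unit: str, to: str = "ev") -> float:
    """Convert a damping / HWHM parameter between eV, cm⁻¹ and Hartree.

    ``convert_damping(1000.0, "cm-1")`` → 0.1240 eV (4 s.f.), the default
    finite-lifetime broadening used throughout.
    """
    u, t = unit.lower(), to.lower()
    if u not in _DAMPING_UNITS:
        raise ValueError(f"unsupported damping unit {unit!r}")
    if t not in _DAMPING_UNITS:
        raise ValueError(f"unsupported damping unit {to!r}")
    return value * _DAMPING_UNITS[u] / _DAMPING_UNITS[t]


# --- ECD intensity conversion --------------------------------------------
# Rotatory strengths are accumulated in atomic units as products of an
# electric-dipole moment (e·a0) and a magnetic-dipole moment expressed in
# units of 2·μ_B (the "L/2c" form in Hartree a.u.).  The experimental
# convention reports R in cgs (esu·cm·erg/G = erg·cm³); 1 a.u. of rotatory
# strength is then e·a0 · (eħ/m_e), i.e. ≈ 471.44×10⁻⁴⁰ cgs.
_E_ESU = ELEMENTARY_CHARGE * SPEED_OF_LIGHT * 10.0  # statC
_A0_CM = BOHR_RADIUS * 100.0
_MU_B_CGS = BOHR_MAGNETON * 1e3  # erg/G
ROTATORY_AU_TO_CGS = _E_ESU * _A0_CM * 2.0 * _MU_B_CGS  # ≈ 4.7144e-38

# Broadened-spectrum prefactor: with a lineshape f(ν̃) normalized to unit
# area on the wavenumber (cm⁻¹) axis,
#   Δε(ν̃) = (32 π³ N_A / (3000 ln10 h c)) · ν̃ · Σ_n R_n f_n(ν̃)
# in L mol⁻¹ cm⁻¹ with R in cgs (the familiar 1/(2.296×10⁻³⁹) factor).
_H_CGS = PLANCK * 1e7  # erg s
_C_CGS = SPEED_OF_LIGHT * 1e2  # cm/s
DELTA_EPS_PREFACTOR_CGS = (
    32.0 * np.pi**3 * AVOGADRO / (3000.0 * np.log(10.0) * _H_CGS * _C_CGS)
)
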