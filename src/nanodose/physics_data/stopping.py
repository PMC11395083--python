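"""Electronic stopping powers and CSDA ranges for protons and electrons.

Protons use the Bethe formula (no density-effect or shell corrections;
both are at the few-percent level in the 0.5-250 MeV validity window).
Electrons use the Moller (Berger-Seltzer) collision stopping power above
1 keV; below 1 keV, where the Bethe-type logarithm turns over, the
stopping power is extended with a gentle power-law taper so that tracks
can be followed down to the 50 eV transport cutoff without divergence.
"""

from __future__ import annotations

import math
import numpy as np

from .constants import CONSTANTS
from .materials import Material

__all__ = [
    "proton_stopping_power",
    "proton_csda_range",
    "proton_energy_from_range",
    "bohr_straggling_variance",
    "electron_stopping_power",
    "electron_csda_range",
    "ELECTRON_CUTOFF_EV",
    "PROTON_ENERGY_WINDOW_MEV",
]

#: electrons below this kinetic energy are absorbed locally
ELECTRON_CUTOFF_EV = 50.0
#: validity window of the proton Bethe implementation
PROTON_ENERGY_WINDOW_MEV = (0.5, 250.0)

_MEC2_MEV = CONSTANTS.electron_rest_energy_keV / 1e3
_MP_MEV = 938.27209
# 4 pi N_A r_e^2 m_e c^2 = 0.307075 MeV cm^2 / mol
_K_MEV_CM2_PER_MOL = 0.307075
_ELECTRON_TAPER_KEV = 1.0
_ELECTRON_TAPER_EXPONENT = -0.35


def _beta2_gamma(kinetic_mev: float, rest_mev: float) -> tuple[float, float]:
    gamma = 1.0 + kinetic_mev / rest_mev
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    return beta2, gamma


def proton_stopping_power(material: Material, energy_MeV: float) -> float:
    """Electronic stopping power -dE/dx for protons, in MeV/mm.

    Raises for energies outside the validity window; callers terminate the
    track by local deposition below it.
    """
    lo, hi = PROTON_ENERGY_WINDOW_MEV
    if not (lo <= energy_MeV <= hi):
        raise ValueError(
            f"proton energy {energy_MeV} MeV outside validity window {lo}-{hi} MeV"
        )
    beta2, gamma = _beta2_gamma(energy_MeV, _MP_MEV)
    i_mev = material.mean_excitation_energy_eV * 1e-6
    arg = 2.0 * _MEC2_MEV * beta2 * gamma * gamma / i_mev
    ln_term = math.log(arg) - beta2
    s_mass = _K_MEV_CM2_PER_MOL * material.z_over_a / beta2 * ln_term  # MeV cm^2/g
    return s_mass * material.density_g_cm3 / 10.0  # MeV/mm


_PROTON_RANGE_CACHE: dict = {}


def _proton_range_interp(material: Material) -> tuple[np.ndarray, np.ndarray]:
    key = (material.name, material.density_g_cm3,
           material.mean_excitation_energy_eV)
    if key in _PROTON_RANGE_CACHE:
        return _PROTON_RANGE_CACHE[key]
    e_grid = np.geomspace(PROTON_ENERGY_WINDOW_MEV[0], PROTON_ENERGY_WINDOW_MEV[1], 400)
    inv_s = 1.0 / np.array([proton_stopping_power(material, e) for e in e_grid])
    ranges = np.concatenate(([0.0], np.cumsum(
        0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(e_grid))))
    _PROTON_RANGE_CACHE[key] = (e_grid, ranges)
    return e_grid, ranges


def proton_csda_range(material: Material, energy_MeV: float) -> float:
    """CSDA range in mm: integral of 1/(dE/dx) from 0.5 MeV to the energy.

    The residual sub-0.5 MeV path (a few hundredths of a mm) is neglected.
    """
    e_grid, ranges = _proton_range_interp(material)
    return float(np.interp(energy_MeV, e_grid, ranges))


def proton_energy_from_range(material: Material, range_mm: float) -> float:
    """Inverse of :func:`proton_csda_range` (energy in MeV at given residual range)."""
    e_grid, ranges = _proton_range_interp(material)
    return float(np.interp(range_mm, ranges, e_grid))


def bohr_straggling_variance(material: Material, step_mm: float) -> float:
    """Bohr energy-loss straggling variance over a step, in MeV^2.

    d(Omega^2)/dx = 4 pi N_A r_e^2 (m_e c^2)^2 (Z/A) rho x for z=1, i.e.
    0.1569 (Z/A) rho MeV^2/cm.
    """
    return 0.1569 * material.z_over_a * material.density_g_cm3 * step_mm / 10.0


# ---------------------------------------------------------------------------
# Electrons

def electron_stopping_power(material: Material, energy_keV: float) -> float:
    """Collision stopping power for electrons, in eV/nm.

    Moller (Berger-Seltzer) formula above 1 keV; power-law taper below,
    frozen at its 100 eV value under 100 eV.
    """
    if energy_keV <= 0:
        raise ValueError("electron energy must be positive")
    if energy_keV < _ELECTRON_TAPER_KEV:
        e_eff = max(energy_keV, 0.1)
        s1 = electron_stopping_power(material, _ELECTRON_TAPER_KEV)
        return s1 * (e_eff / _ELECTRON_TAPER_KEV) ** _ELECTRON_TAPER_EXPONENT
    tau = energy_keV / CONSTANTS.electron_rest_energy_keV
    beta2, _ = _beta2_gamma(energy_keV / 1e3, _MEC2_MEV)
    i_ratio = material.mean_excitation_energy_eV / (
        CONSTANTS.electron_rest_energy_keV * 1e3)
    f_tau = (1.0 - beta2
             + (tau * tau / 8.0 - (2.0 * tau + 1.0) * math.log(2.0))
             / (tau + 1.0) ** 2)
    ln_term = math.log(tau * tau * (tau + 2.0) / (2.0 * i_ratio * i_ratio))
    s_mass = (0.5 * _K_MEV_CM2_PER_MOL * material.z_over_a / beta2
              * (ln_term + f_tau))  # MeV cm^2/g
    # 1 MeV/cm = 1e6 eV / 1e7 nm = 0.1 eV/nm
    return s_mass * material.density_g_cm3 * 0.1


_ELECTRON_RANGE_CACHE: dict = {}


def _electron_range_interp(material: Material) -> tuple[np.ndarray, np.ndarray]:
    key = (material.name, material.density_g_cm3,
           material.mean_excitation_energy_eV)
    if key in _ELECTRON_RANGE_CACHE:
        return _ELECTRON_RANGE_CACHE[key]
    e_grid_kev = np.geomspace(ELECTRON_CUTOFF_EV / 1e3, 1e4, 700)
    inv_s = 1.0 / np.array(
        [electron_stopping_power(material, e) for e in e_grid_kev])  # nm/eV
    de_ev = np.diff(e_grid_kev) * 1e3
    ranges_nm = np.concatenate(([0.0], np.cumsum(
        0.5 * (inv_s[1:] + inv_s[:-1]) * de_ev)))
    _ELECTRON_RANGE_CACHE[key] = (e_grid_kev, ranges_nm)
    return e_grid_kev, ranges_nm


def electron_csda_range(material: Material, energy_keV: float) -> float:
    """Electron CSDA range in nm (0 below the 50 eV tracking cutoff)."""
    if energy_keV * 1e3 < ELECTRON_CUTOFF_EV:
        return 0.0
    e_grid, ranges = _electron_range_interp(material)
    if energy_keV > e_grid[-1]:
        raise ValueError(f"electron energy {energy_keV} keV above range table")
    return float(np.interp(energy_keV, e_grid, ranges))
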