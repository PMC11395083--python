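"""Photon interaction coefficients.

Incoherent scattering is computed analytically from the Klein-Nishina
cross-section (free-electron approximation).  Photoelectric, coherent and
pair-production coefficients come from compact elemental log-log tables
embedded in the package (``data/photon_coefficients.csv``); the tables are
anchored to standard reference values at the energies that dominate the
simulated beams and carry the gold L3/L2/L1/K absorption edges explicitly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .constants import THOMSON_CROSS_SECTION_BARN, CONSTANTS
from .materials import Material, get_element

__all__ = [
    "CoefficientTable",
    "compton_cross_section",
    "klein_nishina_differential",
    "sample_compton_scatter",
    "incoherent_mu_over_rho",
    "photoelectric_mu_over_rho",
    "coherent_mu_over_rho",
    "pair_mu_over_rho",
    "total_mu_over_rho",
]

_BARN_CM2 = 1e-24


@dataclass
class CoefficientTable:
    """Log-log interpolated coefficient versus photon energy.

    ``edges`` lists absorption-edge energies (keV); the table stores the
    discontinuity as two rows at (nearly) the same energy, so plain log-log
    interpolation reproduces the step.
    """

    energy_keV: np.ndarray
    values_cm2_per_g: np.ndarray
    edges_keV: tuple[float, ...] = ()
    _log_e: np.ndarray = field(init=False, repr=False)
    _log_v: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_keV, dtype=float)
        v = np.asarray(self.values_cm2_per_g, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("coefficients must be non-negative")
        self.energy_keV = e
        self.values_cm2_per_g = v
        self._log_e = np.log(e)
        with np.errstate(divide="ignore"):
            self._log_v = np.log(np.maximum(v, 1e-300))

    def __call__(self, energy_keV: float, extrapolate: bool = False) -> float:
        e = float(energy_keV)
        lo, hi = self.energy_keV[0], self.energy_keV[-1]
        if not extrapolate and not (lo <= e <= hi):
            raise ValueError(
                f"energy {e} keV outside table range [{lo}, {hi}] keV"
            )
        e = min(max(e, lo), hi)
        return float(np.exp(np.interp(math.log(e), self._log_e, self._log_v)))


def _load_tables() -> dict[tuple[str, str], CoefficientTable]:
    text = (
        resources.files("nanodose.data")
        .joinpath("photon_coefficients.csv")
        .read_text()
    )
    raw: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in csv.DictReader(text.splitlines()):
        key = (row["element"], row["process"])
        raw.setdefault(key, []).append(
            (float(row["energy_keV"]), float(row["mu_over_rho_cm2_per_g"]))
        )
    gold_edges = (11.919, 13.734, 14.353, 80.725)
    tables = {}
    for (sym, proc), pairs in raw.items():
        pairs.sort()
        edges = gold_edges if (sym == "Au" and proc == "photoelectric") else ()
        tables[(sym, proc)] = CoefficientTable(
            np.array([p[0] for p in pairs]),
            np.array([p[1] for p in pairs]),
            edges,
        )
    return tables


_TABLES = _load_tables()


def element_table(symbol: str, process: str) -> CoefficientTable:
    try:
        return _TABLES[(symbol, process)]
    except KeyError:
        raise KeyError(f"no embedded table for {symbol!r}/{process!r}") from None


# ---------------------------------------------------------------------------
# Klein-Nishina (incoherent)

def compton_cross_section(energy_keV: float) -> float:
    """Total Klein-Nishina cross-section per free electron, in barn.

    Tends to the Thomson cross-section at low energy and decreases
    monotonically above ~1 keV.
    """
    if energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    a = energy_keV / CONSTANTS.electron_rest_energy_keV
    if a < 1e-4:
        # second-order low-energy expansion avoids cancellation
        return THOMSON_CROSS_SECTION_BARN * (1.0 - 2.0 * a + 26.0 / 5.0 * a * a)
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - math.log(1.0 + 2.0 * a) / a)
    t2 = math.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    # 2*pi*r_e^2 = (3/4) * sigma_Thomson
    return 0.75 * THOMSON_CROSS_SECTION_BARN * (t1 + t2 - t3)


def klein_nishina_differential(energy_keV: float, cos_theta: float) -> float:
    """d(sigma)/d(Omega) per electron in barn/sr at scattering angle theta."""
    a = energy_keV / CONSTANTS.electron_rest_energy_keV
    ratio = 1.0 / (1.0 + a * (1.0 - cos_theta))
    re2_barn = (CONSTANTS.classical_electron_radius_m * 1e2) ** 2 / _BARN_CM2
    return 0.5 * re2_barn * ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos_theta**2))


def sample_compton_scatter(energy_keV: float, rng) -> tuple[float, float]:
    """Sample (scattered photon energy keV, cos theta) from Klein-Nishina.

    Rejection sampling with a uniform proposal in cos(theta); adequate for
    the sub-10 MeV energies transported here.
    """
    a = energy_keV / CONSTANTS.electron_rest_energy_keV
    # envelope: maximum of the differential over cos(theta) is at theta=0
    fmax = klein_nishina_differential(energy_keV, 1.0)
    while True:
        ct = rng.uniform(-1.0, 1.0)
        if rng.uniform(0.0, fmax) <= klein_nishina_differential(energy_keV, ct):
            return energy_keV / (1.0 + a * (1.0 - ct)), ct


def incoherent_mu_over_rho(material: Material, energy_keV: float) -> float:
    """Incoherent (Compton) mass attenuation coefficient, cm^2/g."""
    sigma_cm2 = compton_cross_section(energy_keV) * _BARN_CM2
    return sigma_cm2 * material.electrons_per_gram


# ---------------------------------------------------------------------------
# Table-driven processes (mixture rule: mass-fraction-weighted sum)

def _mixture(material: Material, energy_keV: float, process: str,
             extrapolate: bool) -> float:
    total = 0.0
    for sym, w in material.composition.items():
        total += w * element_table(sym, process)(energy_keV, extrapolate)
    return total


def photoelectric_mu_over_rho(material: Material, energy_keV: float,
                              extrapolate: bool = False) -> float:
    if energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    return _mixture(material, energy_keV, "photoelectric", extrapolate)


def coherent_mu_over_rho(material: Material, energy_keV: float,
                         extrapolate: bool = False) -> float:
    return _mixture(material, energy_keV, "coherent", extrapolate)


def pair_mu_over_rho(material: Material, energy_keV: float,
                     extrapolate: bool = False) -> float:
    if energy_keV <= 1022.0:
        return 0.0
    return _mixture(material, energy_keV, "pair", extrapolate)


def total_mu_over_rho(material: Material, energy_keV: float,
                      include_coherent: bool = True,
                      include_pair: bool = True,
                      extrapolate: bool = False) -> float:
    """Total mass attenuation = photoelectric + incoherent (+coherent +pair)."""
    mu = photoelectric_mu_over_rho(material, energy_keV, extrapolate)
    mu += incoherent_mu_over_rho(material, energy_keV)
    if include_coherent:
        mu += coherent_mu_over_rho(material, energy_keV, extrapolate)
    if include_pair:
        mu += pair_mu_over_rho(material, energy_keV, extrapolate)
    return mu
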