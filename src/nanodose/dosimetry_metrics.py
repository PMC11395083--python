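"""Derived dosimetric quantities.

* DEF_SE(r): the spatial energy-density enhancement factor, the ratio of
  the radial energy density with the gold nanoparticle to the water
  baseline at the same fluence.  Outside the nanoparticle it equals the
  conventional dose enhancement factor; inside, the energy-density ratio
  already contains the gold/water density factor of the piecewise dose
  form, so a single ratio serves both branches (the plain dose ratio is
  exported alongside).
* Enhancement-zone radius: where the profile settles onto its pedestal.
* ADR / ADR_LT: the additional relative dose from nanoparticle loading at
  a mass concentration, with the "living tissue" variant excluding the
  nanoparticle volumes.
* Mean inter-nanoparticle spacing at a concentration (inverse cube root
  of the number density).
* Coulomb surface potential of a charged nanoparticle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .micro_transport import NanoparticleSpec, ShellTally
from .physics_data import CONSTANTS, get_material

__all__ = [
    "DEFProfile",
    "ADRResult",
    "def_se_profile",
    "enhancement_zone_radius",
    "adr_from_runs",
    "adr_lt_estimate",
    "mean_np_spacing",
    "surface_potential",
]

DENSITY_RATIO_AU_WATER = 19.32


@dataclass
class DEFProfile:
    """Radial dose-enhancement profile on the shell grid.

    ``def_se`` is the energy-density ratio per shell (NaN where the
    baseline shell recorded no energy); ``dose_ratio`` divides out the
    gold/water density ratio inside the nanoparticle.
    """

    shell_mid_radii: np.ndarray
    def_se: np.ndarray
    stderr: np.ndarray
    np_radius_nm: float
    density_ratio: float = DENSITY_RATIO_AU_WATER
    shell_edges: np.ndarray | None = None

    @property
    def dose_ratio(self) -> np.ndarray:
        inside = self.shell_mid_radii < self.np_radius_nm
        out = self.def_se.copy()
        out[inside] = out[inside] / self.density_ratio
        return out

    def first_outer_shell_def(self) -> float:
        """DEF in the first scoring shell outside the nanoparticle surface."""
        idx = np.nonzero(self.shell_mid_radii > self.np_radius_nm)[0][0]
        return float(self.def_se[idx])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "r_mid_nm": self.shell_mid_radii,
            "def_se": self.def_se,
            "stderr": self.stderr,
            "dose_ratio": self.dose_ratio,
        }).to_csv(path, index=False)


@dataclass
class ADRResult:
    d_gnp: float                 # dose with nanoparticles (per-fluence units)
    d_w: float                   # baseline water dose (same units)
    adr: float
    adr_lt: float
    lt_fraction: float
    concentration_mg_per_L: float
    np_diameter_nm: float
    adr_stderr: float = 0.0
    adr_lt_stderr: float = 0.0


def def_se_profile(tally_gnp: ShellTally, tally_wnp: ShellTally) -> DEFProfile:
    """Eq.-style shell-by-shell enhancement: U_GNP(r) / U_WNP(r).

    Both tallies must share the shell grid and the per-unit-fluence
    normalization (paired runs).  Shells where the baseline is zero are
    flagged NaN.
    """
    eg, ew = tally_gnp.shell_edges, tally_wnp.shell_edges
    if len(eg) != len(ew) or not np.allclose(eg, ew):
        raise ValueError("tallies have different shell grids")
    r_gnp = tally_gnp.np_spec.radius_nm if tally_gnp.np_spec else 0.0
    r_wnp = tally_wnp.np_spec.radius_nm if tally_wnp.np_spec else r_gnp
    if abs(r_gnp - r_wnp) > 1e-9:
        raise ValueError("tallies have different nanoparticle radii")
    ug = tally_gnp.energy_per_shell
    uw = tally_wnp.energy_per_shell
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(uw > 0, np.clip(ug, 0.0, None) / np.where(uw > 0, uw, 1.0),
                         np.nan)
        rel_var = np.where(
            (uw > 0) & (ug > 0),
            tally_gnp.variance_per_shell / np.where(ug > 0, ug, 1.0) ** 2
            + tally_wnp.variance_per_shell / np.where(uw > 0, uw, 1.0) ** 2,
            np.inf)
    stderr = np.abs(ratio) * np.sqrt(rel_var)
    return DEFProfile(
        shell_mid_radii=tally_gnp.shell_mid_radii,
        def_se=ratio,
        stderr=stderr,
        np_radius_nm=r_gnp,
        shell_edges=np.asarray(eg),
    )


def enhancement_zone_radius(profile: DEFProfile, rel_threshold: float = 0.05,
                            pedestal_window: tuple[float, float] = (800.0, 1000.0),
                            ) -> float:
    """Radius beyond which the profile stays within ``rel_threshold`` of
    its pedestal (the mean over ``pedestal_window``).

    Returns the nanoparticle radius for a flat profile and the maximum
    tallied radius (as a beyond-range sentinel) if the profile never
    settles.
    """
    r = profile.shell_mid_radii
    if r[-1] < pedestal_window[0]:
        raise ValueError("profile does not reach the pedestal window")
    in_window = (r >= pedestal_window[0]) & (r <= pedestal_window[1])
    window_vals = profile.def_se[in_window]
    window_vals = window_vals[np.isfinite(window_vals)]
    if len(window_vals) == 0:
        raise ValueError("no finite shells in the pedestal window")
    pedestal = float(window_vals.mean())
    dev = np.abs(profile.def_se - pedestal) / max(abs(pedestal), 1e-300)
    dev = np.where(np.isfinite(dev), dev, 0.0)
    outside = r > profile.np_radius_nm
    settled = dev <= rel_threshold
    edges = profile.shell_edges
    for j in range(len(r)):
        if not outside[j]:
            continue
        if np.all(settled[j:]):
            return float(edges[j] if edges is not None else r[j])
    return float(edges[-1] if edges is not None else r[-1])


def adr_from_runs(d_gnp: float, d_w: float) -> float:
    """Additional relative dose (D_GNP - D_W) / D_W."""
    if d_w == 0:
        raise ZeroDivisionError("baseline dose is zero; ADR undefined")
    return (d_gnp - d_w) / d_w


def np_number_density_per_nm3(concentration_mg_per_L: float, diameter_nm: float,
                              material_density_g_cm3: float) -> float:
    """Nanoparticles per nm^3 at a mass concentration."""
    mass_per_np_g = (material_density_g_cm3 * math.pi / 6.0
                     * (diameter_nm * 1e-7) ** 3)
    per_cm3 = (concentration_mg_per_L * 1e-6) / mass_per_np_g
    return per_cm3 / 1e21


def adr_lt_estimate(np_spec: NanoparticleSpec,
                    concentration_mg_per_L: float,
                    tally_gnp: ShellTally,
                    tally_wnp: ShellTally,
                    baseline: ShellTally,
                    r_max_nm: float | None = None) -> ADRResult:
    """Macroscopic additional relative dose at a gold concentration.

    ``tally_gnp`` / ``tally_wnp`` are the forced-interaction tallies for
    the nanoparticle and the same-size water sphere; ``baseline`` is the
    flat water-cube pedestal whose energy density is the non-enhanced dose
    D_W.  The per-nanoparticle extra energy in living tissue is the
    difference of the tallies summed over shells outside the nanoparticle
    up to ``r_max_nm`` (default: the full radial tally), scaled by the
    nanoparticle number density.  The in-nanoparticle difference gives the
    total ADR and the living-tissue fraction.
    """
    if concentration_mg_per_L <= 0:
        raise ValueError("concentration must be positive")
    eg = tally_gnp.shell_edges
    if len(eg) != len(tally_wnp.shell_edges) or not np.allclose(
            eg, tally_wnp.shell_edges):
        raise ValueError("forced tallies have different shell grids")
    vols = baseline.shell_volumes_nm3
    u0 = float(baseline.energy_per_shell[-1] / vols[-1])
    u0_var = float(baseline.variance_per_shell[-1] / vols[-1] ** 2)
    if u0 <= 0:
        raise ValueError("baseline dose is zero; ADR undefined")
    r_np = np_spec.radius_nm
    if r_max_nm is None:
        r_max_nm = float(eg[-1])
    outer = (eg[1:] > r_np + 1e-9) & (eg[1:] <= r_max_nm + 1e-9)
    de = tally_gnp.energy_per_shell - tally_wnp.energy_per_shell
    dvar = tally_gnp.variance_per_shell + tally_wnp.variance_per_shell
    de_out = float(de[outer].sum())
    de_out_var = float(dvar[outer].sum())
    de_in = float(tally_gnp.inside_np_ev - tally_wnp.inside_np_ev)
    de_in_var = float(tally_gnp.inside_np_var + tally_wnp.inside_np_var)
    density = get_material(np_spec.material).density_g_cm3
    n_np = np_number_density_per_nm3(concentration_mg_per_L,
                                     np_spec.diameter_nm, density)
    adr_lt = n_np * de_out / u0
    adr = n_np * (de_out + de_in) / u0
    rel_u0 = u0_var / u0**2

    def _rel_err(value, var):
        if value == 0.0:
            return 0.0
        return abs(value) * math.sqrt(var / value**2 + rel_u0)

    adr_lt_err = _rel_err(adr_lt, (n_np / u0) ** 2 * de_out_var)
    adr_err = _rel_err(adr, (n_np / u0) ** 2 * (de_out_var + de_in_var))
    return ADRResult(
        d_gnp=u0 * (1.0 + adr),
        d_w=u0,
        adr=adr,
        adr_lt=adr_lt,
        lt_fraction=adr_lt / adr if adr != 0 else float("nan"),
        concentration_mg_per_L=concentration_mg_per_L,
        np_diameter_nm=np_spec.diameter_nm,
        adr_stderr=adr_err,
        adr_lt_stderr=adr_lt_err,
    )


def mean_np_spacing(concentration_mg_per_L: float, diameter_nm: float,
                    material_density_g_cm3: float = 19.32) -> float:
    """Mean inter-nanoparticle distance in micrometers.

    The inverse cube root of the number density: each particle occupies on
    average a cube of side equal to the spacing.
    """
    if concentration_mg_per_L <= 0 or diameter_nm <= 0:
        raise ValueError("concentration and diameter must be positive")
    if material_density_g_cm3 <= 0:
        raise ValueError("material density must be positive")
    n_per_nm3 = np_number_density_per_nm3(concentration_mg_per_L, diameter_nm,
                                          material_density_g_cm3)
    return n_per_nm3 ** (-1.0 / 3.0) / 1e3


def surface_potential(charge_e: float, r_nm: float) -> float:
    """Coulomb potential Q / (4 pi eps0 r) of a charged sphere, in mV."""
    if r_nm <= 0:
        raise ValueError("distance must be positive")
    q = charge_e * CONSTANTS.elementary_charge_C
    phi_v = q / (4.0 * math.pi * CONSTANTS.vacuum_permittivity_F_per_m
                 * r_nm * 1e-9)
    return phi_v * 1e3
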