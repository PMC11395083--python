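"""Stage 1: condensed-history beam transport through the 20 cm tissue phantom.

Photons are transported analogically (photoelectric, Compton, optional
Rayleigh, pair production) under the kerma approximation: secondary
electrons deposit their energy at the interaction point, which is adequate
because this stage only needs cm-scale depth-dose curves and the energy
spectra of primaries crossing the tumor-layer boundaries at 50 mm and
70 mm.  Protons are transported with CSDA stepping plus Gaussian (Bohr)
energy-loss straggling; nuclear interactions are not modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beam_models import EnergySpectrum, sample_energies
from .physics_data import (
    PROTON_ENERGY_WINDOW_MEV,
    bohr_straggling_variance,
    coherent_mu_over_rho,
    get_material,
    incoherent_mu_over_rho,
    pair_mu_over_rho,
    photoelectric_mu_over_rho,
    proton_stopping_power,
    sample_compton_scatter,
)

__all__ = [
    "DepthDoseCurve",
    "MacroRunResult",
    "run_macro_photons",
    "run_macro_protons",
    "extract_spectrum_at_depth",
]

PHANTOM_SIDE_MM = 200.0
_DEPTH_BIN_MM = 1.0
_PAIR_THRESHOLD_KEV = 1022.0
_E511 = 511.0


@dataclass
class DepthDoseCurve:
    """Energy deposited per 1 mm depth bin per primary (arbitrary dose units).

    The phantom is laterally uniform, so energy per depth bin is
    proportional to dose.  ``variance_per_bin`` is the history-by-history
    variance of the per-primary bin dose.
    """

    depth_edges_mm: np.ndarray
    dose_per_primary: np.ndarray
    variance_per_bin: np.ndarray

    @property
    def depth_centers_mm(self) -> np.ndarray:
        return 0.5 * (self.depth_edges_mm[:-1] + self.depth_edges_mm[1:])

    @property
    def stderr_per_bin(self) -> np.ndarray:
        return np.sqrt(self.variance_per_bin)

    def peak_depth_mm(self) -> float:
        return float(self.depth_centers_mm[int(np.argmax(self.dose_per_primary))])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "depth_mm": self.depth_centers_mm,
            "dose": self.dose_per_primary,
            "stderr": self.stderr_per_bin,
        }).to_csv(path, index=False)


@dataclass
class MacroRunResult:
    depth_dose: DepthDoseCurve
    plane_crossings: dict[float, list[tuple[float, float]]]  # depth -> (E, w)
    species: str
    source_spectrum: EnergySpectrum
    n_primaries: int
    energy_injected_keV: float
    energy_deposited_keV: float
    energy_escaped_keV: float
    max_history_imbalance: float  # relative, over all histories

    def spectrum_at(self, depth_mm: float) -> EnergySpectrum:
        return extract_spectrum_at_depth(self, depth_mm)


class _PhotonMuTable:
    """Log-log interpolated linear attenuation components for one material."""

    def __init__(self, material, e_max_kev: float, include_coherent: bool,
                 include_pair: bool):
        # linear attenuation in 1/mm (mass coefficients are cm^2/g)
        rho = material.density_g_cm3 / 10.0
        grid = np.geomspace(1.0, max(e_max_kev * 1.001, 20.0), 300)
        self.log_e = np.log(grid)
        self.pe = np.array([photoelectric_mu_over_rho(material, e, extrapolate=True)
                            for e in grid]) * rho
        self.inc = np.array([incoherent_mu_over_rho(material, e)
                             for e in grid]) * rho
        if include_coherent:
            self.coh = np.array([coherent_mu_over_rho(material, e, extrapolate=True)
                                 for e in grid]) * rho
        else:
            self.coh = np.zeros_like(grid)
        if include_pair:
            self.pair = np.array([pair_mu_over_rho(material, e, extrapolate=True)
                                  for e in grid]) * rho
        else:
            self.pair = np.zeros_like(grid)

    def components(self, e_kev: float) -> tuple[float, float, float, float]:
        x = math.log(e_kev)
        pe = float(np.interp(x, self.log_e, self.pe))
        inc = float(np.interp(x, self.log_e, self.inc))
        coh = float(np.interp(x, self.log_e, self.coh))
        pr = float(np.interp(x, self.log_e, self.pair))
        return pe, inc, coh, pr


def _register_planes(depth_planes_mm):
    return {float(d): [] for d in (depth_planes_mm or (50.0, 70.0))}


def _cross_planes(planes, z0, z1, uz, energy, weight):
    for depth, rec in planes.items():
        if z0 < depth <= z1 and uz > 0:
            rec.append((energy, weight))


def run_macro_photons(spectrum: EnergySpectrum, n_primaries: int, seed: int,
                      material_name: str = "soft_tissue",
                      include_coherent: bool = True,
                      depth_planes_mm=(50.0, 70.0)) -> MacroRunResult:
    """Analog photon transport through the phantom (kerma approximation).

    Returns the depth-dose curve and the fluence spectra of photons
    crossing the registered depth planes in the forward hemisphere.
    """
    if spectrum.species != "photon":
        raise ValueError(f"photon run requires a photon spectrum, got {spectrum.species}")
    if n_primaries < 1000:
        raise ValueError("n_primaries must be >= 1e3 for meaningful tallies")
    material = get_material(material_name)
    e_max = spectrum.max_energy_keV
    include_pair = e_max > _PAIR_THRESHOLD_KEV
    mu_tab = _PhotonMuTable(material, max(e_max, _E511 * 1.2), include_coherent,
                            include_pair)
    n_bins = int(round(PHANTOM_SIDE_MM / _DEPTH_BIN_MM))
    edges = np.linspace(0.0, PHANTOM_SIDE_MM, n_bins + 1)
    dose_sum = np.zeros(n_bins)
    dose_sq = np.zeros(n_bins)
    planes = _register_planes(depth_planes_mm)
    half = PHANTOM_SIDE_MM / 2.0

    rng = np.random.default_rng((seed, 0xA17))
    energies = sample_energies(spectrum, n_primaries, rng)

    injected = float(np.sum(energies))
    deposited = 0.0
    escaped = 0.0
    max_imbalance = 0.0
    kill_kev = 1.0  # photons below this deposit locally

    for e0 in energies:
        stack = [(float(e0), np.zeros(3), np.array([0.0, 0.0, 1.0]))]
        h_dep = 0.0
        h_esc = 0.0
        bins_hit: dict[int, float] = {}
        while stack:
            e, pos, u = stack.pop()
            while True:
                pe, inc, coh, pr = mu_tab.components(e)
                mu = pe + inc + coh + pr
                path = -math.log(1.0 - rng.random()) / mu if mu > 0 else math.inf
                new = pos + path * u
                # distance to cube exit along u
                t_exit = _distance_to_cube_exit(pos, u, half)
                if path >= t_exit:
                    exit_pos = pos + t_exit * u
                    _cross_planes(planes, pos[2], exit_pos[2], u[2], e, 1.0)
                    h_esc += e
                    break
                _cross_planes(planes, pos[2], new[2], u[2], e, 1.0)
                pos = new
                xi = rng.random() * mu
                if xi < pe:
                    _score_depth(bins_hit, pos[2], e, n_bins)
                    h_dep += e
                    break
                elif xi < pe + inc:
                    e_sc, ct = sample_compton_scatter(e, rng)
                    _score_depth(bins_hit, pos[2], e - e_sc, n_bins)
                    h_dep += e - e_sc
                    u = _rotate(u, ct, rng)
                    e = e_sc
                    if e < kill_kev:
                        _score_depth(bins_hit, pos[2], e, n_bins)
                        h_dep += e
                        break
                elif xi < pe + inc + coh:
                    # Rayleigh: elastic, mildly forward-peaked (Thomson shape)
                    ct = _sample_thomson_cos(rng)
                    u = _rotate(u, ct, rng)
                else:
                    # pair production: local kerma deposit, two 511 keV photons
                    _score_depth(bins_hit, pos[2], e - _PAIR_THRESHOLD_KEV, n_bins)
                    h_dep += e - _PAIR_THRESHOLD_KEV
                    u_ann = _isotropic(rng)
                    stack.append((_E511, pos.copy(), u_ann))
                    stack.append((_E511, pos.copy(), -u_ann))
                    break
        for b, de in bins_hit.items():
            dose_sum[b] += de
            dose_sq[b] += de * de
        deposited += h_dep
        escaped += h_esc
        # pair production balances exactly: the local deposit is E-1022 keV
        # and the two annihilation photons carry the remaining 1022 keV
        max_imbalance = max(max_imbalance, abs(h_dep + h_esc - e0) / max(e0, 1e-12))

    return _finalize(dose_sum, dose_sq, edges, planes, "photon", spectrum,
                     n_primaries, injected, deposited, escaped, max_imbalance)


def run_macro_protons(energy_MeV: float, n_primaries: int, seed: int,
                      material_name: str = "soft_tissue",
                      depth_planes_mm=(50.0, 70.0)) -> MacroRunResult:
    """CSDA proton transport with Bohr straggling; returns Bragg curve and
    plane-crossing spectra."""
    if n_primaries < 1000:
        raise ValueError("n_primaries must be >= 1e3 for meaningful tallies")
    material = get_material(material_name)
    n_bins = int(round(PHANTOM_SIDE_MM / _DEPTH_BIN_MM))
    edges = np.linspace(0.0, PHANTOM_SIDE_MM, n_bins + 1)
    dose_sum = np.zeros(n_bins)
    dose_sq = np.zeros(n_bins)
    planes = _register_planes(depth_planes_mm)
    e_floor = PROTON_ENERGY_WINDOW_MEV[0]

    rng = np.random.default_rng((seed, 0xB0))
    injected = 0.0
    deposited = 0.0
    max_imbalance = 0.0

    from .physics_data import proton_csda_range

    for _ in range(n_primaries):
        e = energy_MeV  # MeV
        z = 0.0
        injected += e * 1e3
        h_dep = 0.0
        bins_hit: dict[int, float] = {}
        while e > e_floor and z < PHANTOM_SIDE_MM:
            residual = proton_csda_range(material, e)
            step = max(0.1, min(0.01 * residual, 1.0))
            step = min(step, PHANTOM_SIDE_MM - z)
            s = proton_stopping_power(material, e)
            de_mean = s * step
            if de_mean >= e - e_floor:
                # end of track: shrink step to the remaining range
                step = min(step, max(residual, 1e-3))
                de_mean = e - e_floor
            sigma = math.sqrt(bohr_straggling_variance(material, step))
            de = de_mean + sigma * rng.standard_normal()
            de = min(max(de, 0.0), e)
            z1 = z + step
            for depth, rec in planes.items():
                if z < depth <= z1:
                    frac = (depth - z) / step
                    rec.append(((e - de * frac) * 1e3, 1.0))
            _score_depth_segment(bins_hit, z, z1, de * 1e3, n_bins)
            e -= de
            z = z1
        if e > 0 and z < PHANTOM_SIDE_MM:
            _score_depth(bins_hit, z, e * 1e3, n_bins)
            e = 0.0
        h_dep = sum(bins_hit.values())
        escaped_e = e * 1e3
        for b, de_b in bins_hit.items():
            dose_sum[b] += de_b
            dose_sq[b] += de_b * de_b
        deposited += h_dep
        max_imbalance = max(max_imbalance, abs(h_dep + escaped_e - energy_MeV * 1e3)
                            / (energy_MeV * 1e3))

    return _finalize(dose_sum, dose_sq, edges, planes, "proton",
                     EnergySpectrum(np.array([energy_MeV * 1e3 - 250.0,
                                              energy_MeV * 1e3 + 250.0]),
                                    np.array([1.0]), species="proton"),
                     n_primaries, injected, deposited, injected - deposited,
                     max_imbalance)


def extract_spectrum_at_depth(result: MacroRunResult, depth_mm: float) -> EnergySpectrum:
    """Normalized forward-crossing spectrum at a registered depth plane."""
    depth = float(depth_mm)
    if depth == 0.0:
        return result.source_spectrum
    if depth not in result.plane_crossings:
        raise KeyError(f"depth plane {depth_mm} mm was not registered before the run")
    rec = result.plane_crossings[depth]
    if not rec:
        raise ValueError(f"no particles crossed the plane at {depth_mm} mm")
    energies = np.array([e for e, _ in rec])
    weights = np.array([w for _, w in rec])
    if result.species == "proton":
        bin_w = 500.0
    elif result.source_spectrum.max_energy_keV > 1000:
        bin_w = 50.0
    else:
        bin_w = 1.0
    top = max(energies.max() * 1.001, bin_w)
    edges = np.arange(0.0, top + bin_w, bin_w)
    hist, _ = np.histogram(energies, bins=edges, weights=weights)
    return EnergySpectrum(edges, hist, species=result.species,
                          depth_label=f"{depth_mm:g}")


# ---------------------------------------------------------------------------
# helpers

def _finalize(dose_sum, dose_sq, edges, planes, species, spectrum, n,
              injected, deposited, escaped, max_imbalance) -> MacroRunResult:
    mean = dose_sum / n
    var = (dose_sq / n - mean**2) / max(n - 1, 1)
    curve = DepthDoseCurve(edges, mean, np.clip(var, 0.0, None))
    return MacroRunResult(curve, planes, species, spectrum, n, injected,
                          deposited, escaped, max_imbalance)


def _score_depth(bins: dict, z_mm: float, e_kev: float, n_bins: int) -> None:
    b = min(max(int(z_mm / _DEPTH_BIN_MM), 0), n_bins - 1)
    bins[b] = bins.get(b, 0.0) + e_kev


def _score_depth_segment(bins: dict, z0: float, z1: float, e_kev: float,
                         n_bins: int) -> None:
    """Distribute a segment's energy across the depth bins it overlaps."""
    if z1 <= z0:
        _score_depth(bins, z0, e_kev, n_bins)
        return
    b0 = int(z0 / _DEPTH_BIN_MM)
    b1 = int(min(z1, PHANTOM_SIDE_MM - 1e-9) / _DEPTH_BIN_MM)
    if b0 == b1:
        _score_depth(bins, z0, e_kev, n_bins)
        return
    total = z1 - z0
    for b in range(b0, b1 + 1):
        lo = max(z0, b * _DEPTH_BIN_MM)
        hi = min(z1, (b + 1) * _DEPTH_BIN_MM)
        if hi > lo:
            _score_depth(bins, lo + 1e-12, e_kev * (hi - lo) / total, n_bins)


def _distance_to_cube_exit(pos: np.ndarray, u: np.ndarray, half: float) -> float:
    """Distance along u to the boundary of the cube [-half,half]^2 x [0,2*half]."""
    t = math.inf
    bounds = ((-half, half), (-half, half), (0.0, 2 * half))
    for k in range(3):
        if u[k] > 1e-12:
            t = min(t, (bounds[k][1] - pos[k]) / u[k])
        elif u[k] < -1e-12:
            t = min(t, (bounds[k][0] - pos[k]) / u[k])
    return max(t, 0.0)


def _rotate(u: np.ndarray, cos_theta: float, rng) -> np.ndarray:
    """Rotate direction u by polar angle theta and a uniform azimuth."""
    st = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    phi = 2.0 * math.pi * rng.random()
    # build orthonormal basis around u
    if abs(u[2]) < 0.99:
        a = np.array([0.0, 0.0, 1.0])
    else:
        a = np.array([1.0, 0.0, 0.0])
    v1 = np.cross(u, a)
    v1 /= np.linalg.norm(v1)
    v2 = np.cross(u, v1)
    new = cos_theta * u + st * (math.cos(phi) * v1 + math.sin(phi) * v2)
    return new / np.linalg.norm(new)


def _sample_thomson_cos(rng) -> float:
    """Sample cos(theta) from the Thomson shape (1 + cos^2)."""
    while True:
        ct = rng.uniform(-1.0, 1.0)
        if rng.random() * 2.0 <= 1.0 + ct * ct:
            return ct


def _isotropic(rng) -> np.ndarray:
    ct = rng.uniform(-1.0, 1.0)
    st = math.sqrt(1.0 - ct * ct)
    phi = 2.0 * math.pi * rng.random()
    return np.array([st * math.cos(phi), st * math.sin(phi), ct])
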