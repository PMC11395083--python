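"""Synthetic source spectra for the three study beams and primary sampling.

The study's irradiation fields are a 140 kVp filtered tube spectrum, a 6 MV
linac spectrum and a monoenergetic 95 MeV proton beam.  Since no tabulated
clinical spectra ship with the package, the photon sources are smooth
surrogates: a Kramers bremsstrahlung shape hardened by aluminum-equivalent
filtration for the tube, and a truncated log-normal fluence shape for the
linac.  Characteristic tungsten lines are omitted; both surrogates keep the
features that drive nanoparticle dose enhancement (the photoelectric
dominance window at kVp energies and the low-energy tail of the MV beam).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .particles import ParticleState
from .physics_data import get_material, total_mu_over_rho

__all__ = [
    "EnergySpectrum",
    "make_kvp_spectrum",
    "make_6mv_spectrum",
    "make_proton_spectrum",
    "sample_primaries",
]

_NORM_TOL = 1e-9


@dataclass
class EnergySpectrum:
    """Binned, fluence-weighted energy distribution of a beam.

    ``bin_edges`` are in keV (strictly increasing); ``fluence`` holds one
    non-negative relative weight per bin summing to one.  ``depth_label``
    records where the spectrum was scored ("source" or a depth in mm).
    """

    bin_edges: np.ndarray
    fluence: np.ndarray
    species: str = "photon"
    depth_label: str = "source"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.bin_edges.ndim != 1 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.fluence) != len(self.bin_edges) - 1:
            raise ValueError("need one fluence value per bin")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        total = self.fluence.sum()
        if total <= 0:
            raise ValueError("spectrum has no fluence (zero-width support)")
        if abs(total - 1.0) > _NORM_TOL:
            self.fluence = self.fluence / total
        if self.species not in ("photon", "proton"):
            raise ValueError(f"unknown species {self.species!r}")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def max_energy_keV(self) -> float:
        populated = np.nonzero(self.fluence > 0)[0]
        return float(self.bin_edges[populated[-1] + 1])

    def mean_energy_keV(self) -> float:
        return float(np.sum(self.fluence * self.bin_centers))

    def variance_keV2(self) -> float:
        m = self.mean_energy_keV()
        return float(np.sum(self.fluence * (self.bin_centers - m) ** 2))

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"bin_upper_edge_keV": self.bin_edges[1:], "fluence": self.fluence}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str = "photon",
                 depth_label: str = "source") -> "EnergySpectrum":
        import pandas as pd

        df = pd.read_csv(path)
        upper = df["bin_upper_edge_keV"].to_numpy(dtype=float)
        width = np.diff(upper, prepend=max(upper[0] - (upper[1] - upper[0]), 0.0))
        edges = np.concatenate(([upper[0] - width[0]], upper))
        return cls(edges, df["fluence"].to_numpy(dtype=float),
                   species=species, depth_label=depth_label)


def make_kvp_spectrum(tube_potential_kV: float = 140.0,
                      filtration_mm_al: float = 2.5,
                      cutoff_keV: float = 10.0,
                      bin_width_keV: float = 1.0) -> EnergySpectrum:
    """Kramers bremsstrahlung spectrum hardened by Al filtration.

    Unfiltered fluence is proportional to (E_max - E); filtration
    multiplies by exp(-mu_Al(E) * t).  Support is (cutoff, tube potential].
    """
    if tube_potential_kV <= 0:
        raise ValueError("tube potential must be positive")
    if filtration_mm_al < 0:
        raise ValueError("filtration must be non-negative")
    edges = np.arange(cutoff_keV, tube_potential_kV + bin_width_keV,
                      bin_width_keV)
    edges = edges[edges <= tube_potential_kV + 1e-12]
    if edges[-1] < tube_potential_kV:
        edges = np.append(edges, tube_potential_kV)
    if len(edges) < 2:
        raise ValueError("zero-width support after filtering")
    centers = 0.5 * (edges[:-1] + edges[1:])
    fluence = np.clip(tube_potential_kV - centers, 0.0, None)
    if filtration_mm_al > 0:
        al = get_material("aluminum")
        mu_lin = np.array([
            total_mu_over_rho(al, e, include_pair=False) * al.density_g_cm3
            for e in centers
        ])  # 1/cm
        fluence = fluence * np.exp(-mu_lin * filtration_mm_al / 10.0)
    if fluence.sum() <= 0:
        raise ValueError("zero-width support after filtering")
    return EnergySpectrum(edges, fluence, species="photon")


def make_6mv_spectrum(median_MeV: float = 0.95,
                      sigma_log: float = 0.85,
                      bin_width_keV: float = 50.0) -> EnergySpectrum:
    """Two-parameter log-normal surrogate for a 6 MV linac spectrum.

    Support (10 keV, 6 MeV].  The defaults mimic published 6 MV photon
    fluence spectra: modal energy near 0.5 MeV, mean in the 1.2-2.2 MeV
    window, and a few percent of the fluence below 200 keV (the component
    that dominates photoelectric interactions with gold).
    """
    edges = np.arange(10.0, 6000.0 + bin_width_keV, bin_width_keV)
    edges = edges[edges <= 6000.0 + 1e-9]
    centers = 0.5 * (edges[:-1] + edges[1:])
    fluence = np.exp(-0.5 * ((np.log(centers) - np.log(median_MeV * 1e3))
                             / sigma_log) ** 2) / centers
    return EnergySpectrum(edges, fluence, species="photon")


def make_proton_spectrum(energy_MeV: float = 95.0,
                         bin_width_keV: float = 500.0) -> EnergySpectrum:
    """Monoenergetic proton source: all fluence in the bin containing the energy."""
    e_kev = energy_MeV * 1e3
    edges = np.array([e_kev - 0.5 * bin_width_keV, e_kev + 0.5 * bin_width_keV])
    return EnergySpectrum(edges, np.array([1.0]), species="proton")


def sample_primaries(spectrum: EnergySpectrum, n: int, seed: int,
                     entry_face_mm: float = 200.0) -> list[ParticleState]:
    """Draw ``n`` primaries by inverse-CDF from the spectrum histogram.

    Positions are uniform on the z=0 entry face (x, y in mm), directions
    along +z, statistical weight one.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(spectrum.fluence.sum() - 1.0) > 1e-6:
        raise ValueError("spectrum is not normalized")
    rng = np.random.default_rng(seed)
    energies = sample_energies(spectrum, n, rng)
    xy = rng.uniform(-entry_face_mm / 2.0, entry_face_mm / 2.0, size=(n, 2))
    return [
        ParticleState(
            species=spectrum.species,
            energy_keV=float(e),
            position=np.array([x, y, 0.0]),
            direction=np.array([0.0, 0.0, 1.0]),
            weight=1.0,
        )
        for e, (x, y) in zip(energies, xy)
    ]


def sample_energies(spectrum: EnergySpectrum, n: int, rng) -> np.ndarray:
    """Vectorized inverse-CDF energy sampling (uniform within each bin).

    A single-bin spectrum degenerates to its bin's midpoint energy so that
    monoenergetic sources stay exactly monoenergetic.
    """
    if len(spectrum.fluence) == 1:
        return np.full(n, spectrum.bin_centers[0])
    cdf = np.cumsum(spectrum.fluence)
    cdf = cdf / cdf[-1]
    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="right")
    lo = spectrum.bin_edges[idx]
    hi = spectrum.bin_edges[idx + 1]
    frac = rng.random(n)
    return lo + frac * (hi - lo)
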