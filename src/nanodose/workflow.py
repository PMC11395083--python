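"""Two-stage pipeline orchestration: configuration, reproducibility, outputs.

A single :class:`SimulationConfig` drives beam construction, stage-1
transport to tumor depth, stage-2 paired nanoparticle/baseline micro
runs, and the derived metrics.  Every output is a CSV or JSON document in
the run directory plus a manifest with the configuration snapshot, seeds
and file digests; identical configurations and seeds reproduce all
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .beam_models import (
    EnergySpectrum,
    make_6mv_spectrum,
    make_kvp_spectrum,
    make_proton_spectrum,
)
from .dosimetry_metrics import (
    adr_lt_estimate,
    def_se_profile,
    enhancement_zone_radius,
)
from .macro_transport import run_macro_photons, run_macro_protons
from .micro_transport import (
    NanoparticleSpec,
    ShellTally,
    combine_tallies,
    forced_interaction_estimate,
    make_shell_grid,
    proton_np_perturbation_estimate,
    proton_pedestal_tally,
    run_micro,
    water_baseline_tally,
)

__all__ = [
    "SimulationConfig",
    "RunManifest",
    "run_pipeline",
    "make_source_spectrum",
    "generate_fixture_tallies",
]

BEAMS = ("kvp140", "mv6", "proton95")


@dataclass
class SimulationConfig:
    beam: str = "kvp140"
    phantom_side_mm: float = 200.0
    tumor_depth_range_mm: tuple[float, float] = (50.0, 70.0)
    micro_cube_side_mm: float = 1.0
    np_diameter_nm: float = 20.0
    np_material: str = "gold"
    concentration_mg_per_L: float = 10.0
    n_macro: int = 20000
    n_micro: int = 20000
    seed: int = 42
    variance_reduction: bool = True
    depth_for_micro: str = "distal"   # frontal (50 mm) | distal (70 mm)
    proton_adr_override: bool = False

    def __post_init__(self) -> None:
        if self.beam not in BEAMS:
            raise ValueError(f"unknown beam {self.beam!r}; choose from {BEAMS}")
        lo, hi = self.tumor_depth_range_mm
        if not (0 <= lo < hi <= self.phantom_side_mm):
            raise ValueError("tumor depth range must lie inside the phantom")
        if not (0 < self.micro_cube_side_mm <= hi - lo):
            raise ValueError("micro cube must fit inside the tumor layer")
        if not (0 < self.np_diameter_nm < self.micro_cube_side_mm * 1e6):
            raise ValueError(
                "nanoparticle must be smaller than the micro cube")
        if self.depth_for_micro not in ("frontal", "distal"):
            raise ValueError("depth_for_micro must be 'frontal' or 'distal'")
        if self.beam != "proton95" and self.depth_for_micro == "frontal":
            raise ValueError(
                "X-ray micro runs use the distal (70 mm) spectrum only")
        if self.concentration_mg_per_L <= 0:
            raise ValueError("concentration must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tumor_depth_range_mm"] = list(self.tumor_depth_range_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "tumor_depth_range_mm" in d:
            d["tumor_depth_range_mm"] = tuple(d["tumor_depth_range_mm"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    package_version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started_utc: str = ""
    finished_utc: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True))


def make_source_spectrum(beam: str) -> EnergySpectrum:
    if beam == "kvp140":
        return make_kvp_spectrum(140.0)
    if beam == "mv6":
        return make_6mv_spectrum()
    if beam == "proton95":
        return make_proton_spectrum(95.0)
    raise ValueError(f"unknown beam {beam!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: SimulationConfig, out_dir) -> dict:
    """Execute the full two-stage study for one configuration.

    Returns a summary dict; writes depth-dose, spectra, shell tallies,
    the DEF profile, the ADR summary and the manifest under ``out_dir``.
    """
    out = Path(out_dir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "tallies").mkdir(exist_ok=True)
    (out / "metrics").mkdir(exist_ok=True)
    manifest = RunManifest(config=config.to_dict(),
                           package_version=__version__, seed=config.seed,
                           started_utc=_utc())

    source = make_source_spectrum(config.beam)
    source.to_csv(out / "spectra" / "source.csv")

    if config.beam == "proton95":
        macro = run_macro_protons(95.0, config.n_macro, config.seed)
    else:
        macro = run_macro_photons(source, config.n_macro, config.seed)
    macro.depth_dose.to_csv(out / "metrics" / "depth_dose.csv")
    depth = 50.0 if config.depth_for_micro == "frontal" else 70.0
    spectrum = macro.spectrum_at(depth)
    spectrum.to_csv(out / "spectra" / f"depth_{int(depth)}mm.csv")

    np_spec = NanoparticleSpec(config.np_diameter_nm, config.np_material)
    wnp_spec = NanoparticleSpec(config.np_diameter_nm, "water")
    summary: dict = {
        "beam": config.beam,
        "depth_mm": depth,
        "depth_spectrum_mean_keV": spectrum.mean_energy_keV(),
        "bragg_or_peak_depth_mm": macro.depth_dose.peak_depth_mm(),
    }

    if spectrum.species == "photon" and config.variance_reduction:
        forced_np = forced_interaction_estimate(
            spectrum, np_spec, config.n_micro, config.seed)
        forced_w = forced_interaction_estimate(
            spectrum, wnp_spec, config.n_micro, config.seed)
        baseline = water_baseline_tally(
            spectrum, np_spec, max(config.n_micro // 2, 1000), config.seed)
        tally_gnp = combine_tallies(baseline, add=[forced_np], sub=[forced_w])
        tally_wnp = baseline
        forced_np.to_csv(out / "tallies" / "forced_np.csv")
        forced_w.to_csv(out / "tallies" / "forced_water.csv")
        adr = adr_lt_estimate(np_spec, config.concentration_mg_per_L,
                              forced_np, forced_w, baseline)
        summary["adr"] = adr.adr
        summary["adr_lt"] = adr.adr_lt
        summary["lt_fraction"] = adr.lt_fraction
        (out / "metrics" / "adr.json").write_text(
            json.dumps(dataclasses.asdict(adr), indent=2, sort_keys=True))
    elif spectrum.species == "proton" and config.variance_reduction:
        pedestal = proton_pedestal_tally(spectrum, np_spec,
                                         max(config.n_micro, 2000), config.seed)
        aimed_np = proton_np_perturbation_estimate(
            spectrum, np_spec, config.n_micro, config.seed)
        aimed_w = proton_np_perturbation_estimate(
            spectrum, wnp_spec, config.n_micro, config.seed)
        tally_gnp = combine_tallies(pedestal, add=[aimed_np], sub=[aimed_w])
        tally_wnp = pedestal
        if config.proton_adr_override:
            adr = adr_lt_estimate(np_spec, config.concentration_mg_per_L,
                                  aimed_np, aimed_w, pedestal)
            summary["adr"] = adr.adr
            summary["adr_lt"] = adr.adr_lt
            (out / "metrics" / "adr.json").write_text(
                json.dumps(dataclasses.asdict(adr), indent=2, sort_keys=True))
    else:
        tally_gnp = run_micro(spectrum, np_spec, config.n_micro, config.seed)
        tally_wnp = run_micro(spectrum, wnp_spec, config.n_micro, config.seed)
        if spectrum.species == "proton" and config.proton_adr_override:
            baseline = _flat_from_analog(tally_wnp, np_spec)
            adr = adr_lt_estimate(np_spec, config.concentration_mg_per_L,
                                  tally_gnp, tally_wnp, baseline)
            summary["adr"] = adr.adr
            summary["adr_lt"] = adr.adr_lt
            (out / "metrics" / "adr.json").write_text(
                json.dumps(dataclasses.asdict(adr), indent=2, sort_keys=True))

    tally_gnp.to_csv(out / "tallies" / "tally_np.csv")
    tally_wnp.to_csv(out / "tallies" / "tally_baseline.csv")

    profile = def_se_profile(tally_gnp, tally_wnp)
    profile.to_csv(out / "metrics" / "def_profile.csv")
    summary["first_shell_def"] = profile.first_outer_shell_def()
    try:
        summary["enhancement_zone_radius_nm"] = enhancement_zone_radius(profile)
    except ValueError:
        summary["enhancement_zone_radius_nm"] = float("nan")

    (out / "metrics" / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))

    for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json")):
        if p.name != "manifest.json":
            manifest.outputs[str(p.relative_to(out))] = _sha256(p)
    manifest.finished_utc = _utc()
    manifest.write(out / "manifest.json")
    return summary


def _utc() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())


def _flat_from_analog(tally: ShellTally, np_spec: NanoparticleSpec) -> ShellTally:
    """Flat pedestal at the far-shell mean density of an analog tally."""
    dens = tally.energy_density()
    mids = tally.shell_mid_radii
    window = (mids >= 800.0) & (mids <= 1000.0)
    u0 = float(dens[window].mean())
    vols = tally.shell_volumes_nm3
    return dataclasses.replace(
        tally, energy_per_shell=u0 * vols,
        variance_per_shell=np.full_like(vols, (0.1 * u0) ** 2) * vols**2,
        mode="baseline")


# ---------------------------------------------------------------------------
# synthetic fixtures for metric unit tests

def generate_fixture_tallies(seed: int = 0, shape: str = "exponential",
                             np_diameter_nm: float = 20.0,
                             amplitude: float = 9.0,
                             length_nm: float = 30.0,
                             step_radius_nm: float = 100.0,
                             u0: float = 1e-4) -> tuple[ShellTally, ShellTally]:
    """Analytic (GNP, WNP) tally pairs with a known DEF profile.

    Shapes: ``flat`` (DEF = 1 everywhere), ``exponential``
    (DEF(r) = 1 + A exp(-(r - R)/lambda) outside the nanoparticle) and
    ``step`` (DEF = 1 + A up to ``step_radius_nm``, 1 beyond).  Inside the
    nanoparticle DEF is set to the density ratio times 1 (flat) for
    simplicity.  Variances are zero: the profiles are exact.
    """
    spec = NanoparticleSpec(np_diameter_nm, "gold")
    edges = make_shell_grid(spec.radius_nm)
    vols = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    mids = 0.5 * (edges[:-1] + edges[1:])
    r = spec.radius_nm
    base = u0 * vols
    if shape == "flat":
        def_vals = np.ones_like(mids)
    elif shape == "exponential":
        def_vals = np.where(mids > r,
                            1.0 + amplitude * np.exp(-(mids - r) / length_nm),
                            1.0)
    elif shape == "step":
        def_vals = np.where((mids > r) & (edges[1:] <= step_radius_nm + 1e-9),
                            1.0 + amplitude, 1.0)
    else:
        raise ValueError(f"unknown fixture shape {shape!r}")
    inside = mids < r
    def_vals = np.where(inside, 19.32, def_vals) if shape != "flat" else def_vals
    gnp = ShellTally(edges, base * def_vals, np.zeros_like(base), 1, spec,
                     beam_label=f"fixture-{shape}", mode="fixture")
    wnp = ShellTally(edges, base.copy(), np.zeros_like(base), 1,
                     NanoparticleSpec(np_diameter_nm, "water"),
                     beam_label=f"fixture-{shape}", mode="fixture")
    return gnp, wnp
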