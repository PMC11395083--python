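"""Stage 2: event-by-event transport in the 1 mm water cube with a central
nanoparticle, scored in concentric radial shells.

Electrons are transported with a hybrid scheme: condensed steps with
continuous energy loss and Highland multiple scattering above 10 keV, and
discrete inelastic events (free paths from the stopping power divided by
the mean event loss) below, down to a 50 eV cutoff.  Photoabsorption
triggers the full fluorescence/Auger relaxation cascade.  Protons slow
continuously and produce explicit delta rays from a Rutherford-type free
electron cross-section.

Three estimators produce ShellTally objects on a common radial grid:

* :func:`run_micro` - analog transport of beam primaries;
* :func:`forced_interaction_estimate` - every photon is forced through the
  nanoparticle and interacts inside it with weight equal to the chord
  interaction probability (unbiased for the NP-interaction contribution);
* :func:`water_baseline_tally` - the non-enhanced far field: the analog
  dose of the standalone water cube under a full-face beam, represented as
  a flat radial pedestal (a homogeneous medium under broad uniform
  irradiation has a uniform energy density by translation symmetry);
* :func:`equilibrium_field_tally` - a fast collision-kerma pedestal used
  as a cross-check at kVp energies, where charged-particle equilibrium
  holds inside the cube.

All tallies are normalized per unit fluence (photons/nm^2) so they can be
added and subtracted; a run with a gold nanoparticle is reconstructed as
``baseline + forced(gold) - forced(water)``.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, replace

import numpy as np

from .beam_models import EnergySpectrum, sample_energies
from .particles import ParticleState
from .physics_data import (
    CONSTANTS,
    coherent_mu_over_rho,
    electron_stopping_power,
    get_material,
    incoherent_mu_over_rho,
    pair_mu_over_rho,
    photoelectric_mu_over_rho,
    proton_stopping_power,
    sample_compton_scatter,
)
from .physics_data.stopping import (
    ELECTRON_CUTOFF_EV,
    _electron_range_interp,
)
from .relaxation import get_relaxation_model

__all__ = [
    "NanoparticleSpec",
    "ShellTally",
    "make_shell_grid",
    "run_micro",
    "forced_interaction_estimate",
    "equilibrium_field_tally",
    "water_baseline_tally",
    "proton_pedestal_tally",
    "proton_np_perturbation_estimate",
    "combine_tallies",
    "transport_electron",
    "MicroGeometry",
]

CUBE_SIDE_MM = 1.0
_CUBE_HALF_NM = CUBE_SIDE_MM * 1e6 / 2.0
GRID_MAX_NM = 5000.0
_E_CONDENSED_EV = 1e4          # condensed-history / discrete-event boundary
_DELTA_SPAWN_EV = 500.0        # discrete losses above this spawn a secondary
_W_MIN_EV = 50.0               # floor of the discrete loss spectrum
_PROTON_DELTA_TMIN_EV = 50.0
_MEC2_EV = CONSTANTS.electron_rest_energy_keV * 1e3
_X0_NM = {"water": 3.608e8, "gold": 3.344e6, "soft_tissue": 3.55e8}
_PAIR_THRESHOLD_KEV = 1022.0


@dataclass(frozen=True)
class NanoparticleSpec:
    """Central nanosphere: diameter in nm and registry material name."""

    diameter_nm: float
    material: str = "gold"

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        get_material(self.material)  # raises for unknown materials

    @property
    def radius_nm(self) -> float:
        return self.diameter_nm / 2.0


def make_shell_grid(radius_nm: float, n_inner: int = 5,
                    fine_width_nm: float = 5.0,
                    fine_extent_nm: float = 1000.0,
                    coarse_width_nm: float = 50.0,
                    coarse_extent_nm: float = GRID_MAX_NM) -> np.ndarray:
    """Radial shell edges: equal-volume bins inside the nanoparticle, 5 nm
    shells to 1 um, then 50 nm shells to 5 um.  One edge sits exactly at
    the nanoparticle radius."""
    inner = radius_nm * (np.arange(n_inner + 1) / n_inner) ** (1.0 / 3.0)
    fine = np.arange(radius_nm + fine_width_nm,
                     fine_extent_nm + fine_width_nm / 2, fine_width_nm)
    start_coarse = fine[-1] if len(fine) else radius_nm
    coarse = np.arange(start_coarse + coarse_width_nm,
                       coarse_extent_nm + coarse_width_nm / 2, coarse_width_nm)
    edges = np.concatenate((inner, fine, coarse))
    return edges


@dataclass
class ShellTally:
    """Per-shell energy deposition normalized per unit fluence (photons/nm^2).

    ``energy_per_shell`` is in eV per nanoparticle per unit fluence;
    ``variance_per_shell`` is the squared standard error of those values.
    ``beyond_grid_ev`` is energy deposited inside the cube but outside the
    radial grid; ``escaped_ev`` left the cube.  ``inside_np_ev`` /
    ``outside_np_ev`` split the in-cube total at the nanoparticle surface
    (outside includes beyond-grid).
    """

    shell_edges: np.ndarray
    energy_per_shell: np.ndarray
    variance_per_shell: np.ndarray
    n_primaries: int
    np_spec: NanoparticleSpec | None
    beam_label: str = ""
    mode: str = "analog"
    beyond_grid_ev: float = 0.0
    escaped_ev: float = 0.0
    inside_np_ev: float = 0.0
    inside_np_var: float = 0.0
    outside_np_ev: float = 0.0
    outside_np_var: float = 0.0
    np_interactions: float = 0.0
    max_history_imbalance: float = 0.0

    @property
    def shell_mid_radii(self) -> np.ndarray:
        return 0.5 * (self.shell_edges[:-1] + self.shell_edges[1:])

    @property
    def shell_volumes_nm3(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * np.diff(self.shell_edges ** 3)

    @property
    def stderr_per_shell(self) -> np.ndarray:
        return np.sqrt(self.variance_per_shell)

    def energy_density(self) -> np.ndarray:
        """eV per nm^3 per unit fluence."""
        return self.energy_per_shell / self.shell_volumes_nm3

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "r_inner_nm": self.shell_edges[:-1],
            "r_outer_nm": self.shell_edges[1:],
            "energy_eV": self.energy_per_shell,
            "stderr_eV": self.stderr_per_shell,
            "n_primaries": self.n_primaries,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, np_spec: NanoparticleSpec | None = None,
                 beam_label: str = "") -> "ShellTally":
        import pandas as pd

        df = pd.read_csv(path)
        edges = np.concatenate((df["r_inner_nm"].to_numpy(),
                                [float(df["r_outer_nm"].iloc[-1])]))
        return cls(edges, df["energy_eV"].to_numpy(dtype=float),
                   df["stderr_eV"].to_numpy(dtype=float) ** 2,
                   int(df["n_primaries"].iloc[0]), np_spec, beam_label,
                   mode="loaded")


def combine_tallies(base: ShellTally, add=(), sub=()) -> ShellTally:
    """Linear combination base + sum(add) - sum(sub); variances add."""
    tallies = [base, *add, *sub]
    for t in tallies[1:]:
        if len(t.shell_edges) != len(base.shell_edges) or not np.allclose(
                t.shell_edges, base.shell_edges):
            raise ValueError("tallies have incompatible shell grids")
    e = base.energy_per_shell.copy()
    v = base.variance_per_shell.copy()
    beyond = base.beyond_grid_ev
    esc = base.escaped_ev
    i_np, i_var = base.inside_np_ev, base.inside_np_var
    o_np, o_var = base.outside_np_ev, base.outside_np_var
    nint = base.np_interactions
    for t in add:
        e = e + t.energy_per_shell
        v = v + t.variance_per_shell
        beyond += t.beyond_grid_ev
        esc += t.escaped_ev
        i_np += t.inside_np_ev
        i_var += t.inside_np_var
        o_np += t.outside_np_ev
        o_var += t.outside_np_var
        nint += t.np_interactions
    for t in sub:
        e = e - t.energy_per_shell
        v = v + t.variance_per_shell
        beyond -= t.beyond_grid_ev
        esc -= t.escaped_ev
        i_np -= t.inside_np_ev
        i_var += t.inside_np_var
        o_np -= t.outside_np_ev
        o_var += t.outside_np_var
        nint -= t.np_interactions
    return replace(
        base, energy_per_shell=e, variance_per_shell=v, mode="combined",
        beyond_grid_ev=beyond, escaped_ev=esc, inside_np_ev=i_np,
        inside_np_var=i_var, outside_np_ev=o_np, outside_np_var=o_var,
        np_interactions=nint)


# ---------------------------------------------------------------------------
# fast lookup tables

class _ElectronTables:
    def __init__(self, material):
        grid, ranges = _electron_range_interp(material)
        self.log_e = np.log(grid * 1e3)  # eV
        self.log_range = np.log(np.maximum(ranges, 1e-6))
        s = np.array([electron_stopping_power(material, e) for e in grid])
        self.log_s = np.log(s)

    def stopping(self, e_ev: float) -> float:
        return math.exp(np.interp(math.log(e_ev), self.log_e, self.log_s))

    def csda_range(self, e_ev: float) -> float:
        return math.exp(np.interp(math.log(e_ev), self.log_e, self.log_range))


class _PhotonTables:
    """Linear attenuation components in 1/nm on a log grid."""

    def __init__(self, material, e_max_kev):
        rho = material.density_g_cm3 / 1e7  # cm^2/g -> nm^-1 factor
        grid = np.geomspace(1.0, max(e_max_kev * 1.05, 600.0), 400)
        self.log_e = np.log(grid)
        self.pe = np.array([photoelectric_mu_over_rho(material, e, extrapolate=True)
                            for e in grid]) * rho
        self.inc = np.array([incoherent_mu_over_rho(material, e)
                             for e in grid]) * rho
        self.coh = np.array([coherent_mu_over_rho(material, e, extrapolate=True)
                             for e in grid]) * rho
        self.pair = np.array([pair_mu_over_rho(material, e, extrapolate=True)
                              for e in grid]) * rho

    def components(self, e_kev):
        x = math.log(e_kev)
        return (float(np.interp(x, self.log_e, self.pe)),
                float(np.interp(x, self.log_e, self.inc)),
                float(np.interp(x, self.log_e, self.coh)),
                float(np.interp(x, self.log_e, self.pair)))

    def total(self, e_kev):
        return sum(self.components(e_kev))


@dataclass
class MicroGeometry:
    """1 mm water cube with a central nanosphere."""

    np_spec: NanoparticleSpec
    cube_half_nm: float = _CUBE_HALF_NM

    def __post_init__(self) -> None:
        if self.np_spec.radius_nm >= self.cube_half_nm:
            raise ValueError("nanoparticle does not fit inside the micro cube")
        self.water = get_material("water")
        self.np_material = get_material(self.np_spec.material)
        self.e_water = _ElectronTables(self.water)
        self.e_np = (self.e_water if self.np_spec.material == "water"
                     else _ElectronTables(self.np_material))

    def material_at(self, pos) -> str:
        r2 = pos[0] * pos[0] + pos[1] * pos[1] + pos[2] * pos[2]
        return "np" if r2 < self.np_spec.radius_nm ** 2 else "water"

    def electron_tables(self, region: str) -> _ElectronTables:
        return self.e_np if region == "np" else self.e_water

    def inside_cube(self, pos) -> bool:
        h = self.cube_half_nm
        return (-h <= pos[0] <= h and -h <= pos[1] <= h and -h <= pos[2] <= h)

    def dist_to_cube(self, pos, u) -> float:
        t = math.inf
        h = self.cube_half_nm
        for k in range(3):
            if u[k] > 1e-12:
                t = min(t, (h - pos[k]) / u[k])
            elif u[k] < -1e-12:
                t = min(t, (-h - pos[k]) / u[k])
        return max(t, 0.0)

    def dist_to_sphere(self, pos, u) -> float:
        """Distance to the nanosphere surface along u (inf if missed)."""
        r = self.np_spec.radius_nm
        b = pos[0] * u[0] + pos[1] * u[1] + pos[2] * u[2]
        c = (pos[0] ** 2 + pos[1] ** 2 + pos[2] ** 2) - r * r
        disc = b * b - c
        if disc < 0:
            return math.inf
        sq = math.sqrt(disc)
        t1 = -b - sq
        t2 = -b + sq
        if c < 0:       # inside: exit at t2
            return max(t2, 0.0)
        if t1 > 1e-9:   # outside, sphere ahead
            return t1
        return math.inf


# ---------------------------------------------------------------------------
# tally accumulation

class _Accumulator:
    def __init__(self, edges: np.ndarray, np_radius: float):
        self.edges = list(edges)
        self.np_radius = np_radius
        n = len(edges) - 1
        self.sum = np.zeros(n)
        self.sumsq = np.zeros(n)
        self.beyond = 0.0
        self.escaped = 0.0
        self.in_sum = self.in_sq = 0.0
        self.out_sum = self.out_sq = 0.0
        self.nint_sum = 0.0
        self.n_hist = 0
        self.max_imbalance = 0.0
        self._h: dict[int, float] = {}
        self._h_beyond = 0.0
        self._h_escape = 0.0
        self._h_nint = 0.0

    # -- scoring callbacks used by the transport kernels
    def score(self, r_nm: float, e_ev: float) -> None:
        if e_ev <= 0.0:
            return
        if r_nm >= self.edges[-1]:
            self._h_beyond += e_ev
            return
        b = bisect.bisect_right(self.edges, r_nm) - 1
        self._h[b] = self._h.get(b, 0.0) + e_ev

    def score_escape(self, e_ev: float) -> None:
        self._h_escape += e_ev

    def score_np_interaction(self, w: float = 1.0) -> None:
        self._h_nint += w

    def flush_history(self, weight: float = 1.0, injected_ev: float | None = None):
        dep = sum(self._h.values()) + self._h_beyond
        if injected_ev is not None and injected_ev > 0:
            imbalance = abs(dep + self._h_escape - injected_ev) / injected_ev
            self.max_imbalance = max(self.max_imbalance, imbalance)
        h_in = h_out = 0.0
        for b, e in self._h.items():
            we = weight * e
            self.sum[b] += we
            self.sumsq[b] += we * we
            if self.edges[b + 1] <= self.np_radius + 1e-9:
                h_in += we
            else:
                h_out += we
        h_out += weight * self._h_beyond
        self.beyond += weight * self._h_beyond
        self.escaped += weight * self._h_escape
        self.in_sum += h_in
        self.in_sq += h_in * h_in
        self.out_sum += h_out
        self.out_sq += h_out * h_out
        self.nint_sum += weight * self._h_nint
        self.n_hist += 1
        self._h = {}
        self._h_beyond = 0.0
        self._h_escape = 0.0
        self._h_nint = 0.0

    def finalize(self, fluence_norm: float, np_spec, beam_label: str,
                 mode: str) -> ShellTally:
        """``fluence_norm`` = total fluence (photons/nm^2) represented by
        the accumulated histories."""
        n = max(self.n_hist, 1)
        f2 = fluence_norm * fluence_norm
        var = np.clip(self.sumsq - self.sum ** 2 / n, 0.0, None) / f2
        var_in = max(self.in_sq - self.in_sum ** 2 / n, 0.0) / f2
        var_out = max(self.out_sq - self.out_sum ** 2 / n, 0.0) / f2
        return ShellTally(
            shell_edges=np.asarray(self.edges),
            energy_per_shell=self.sum / fluence_norm,
            variance_per_shell=var,
            n_primaries=self.n_hist,
            np_spec=np_spec,
            beam_label=beam_label,
            mode=mode,
            beyond_grid_ev=self.beyond / fluence_norm,
            escaped_ev=self.escaped / fluence_norm,
            inside_np_ev=self.in_sum / fluence_norm,
            inside_np_var=var_in,
            outside_np_ev=self.out_sum / fluence_norm,
            outside_np_var=var_out,
            np_interactions=self.nint_sum / fluence_norm,
            max_history_imbalance=self.max_imbalance,
        )


# ---------------------------------------------------------------------------
# electron transport kernel

def _rotate(u, cos_theta, rng):
    st = math.sqrt(max(0.0, 1.0 - cos_theta * cos_theta))
    phi = 2.0 * math.pi * rng.random()
    ux, uy, uz = u
    if abs(uz) < 0.99:
        ax, ay, az = 0.0, 0.0, 1.0
    else:
        ax, ay, az = 1.0, 0.0, 0.0
    v1x = uy * az - uz * ay
    v1y = uz * ax - ux * az
    v1z = ux * ay - uy * ax
    norm = math.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
    v1x, v1y, v1z = v1x / norm, v1y / norm, v1z / norm
    v2x = uy * v1z - uz * v1y
    v2y = uz * v1x - ux * v1z
    v2z = ux * v1y - uy * v1x
    cp, sp = math.cos(phi), math.sin(phi)
    nx = cos_theta * ux + st * (cp * v1x + sp * v2x)
    ny = cos_theta * uy + st * (cp * v1y + sp * v2y)
    nz = cos_theta * uz + st * (cp * v1z + sp * v2z)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return (nx / norm, ny / norm, nz / norm)


def _isotropic(rng):
    ct = rng.uniform(-1.0, 1.0)
    st = math.sqrt(1.0 - ct * ct)
    phi = 2.0 * math.pi * rng.random()
    return (st * math.cos(phi), st * math.sin(phi), ct)


def _hg_cos(g: float, rng) -> float:
    """Henyey-Greenstein angular sample (isotropic for g -> 0)."""
    if g < 1e-3:
        return rng.uniform(-1.0, 1.0)
    s = (1.0 - g * g) / (1.0 + g - 2.0 * g * rng.random())
    return max(-1.0, min(1.0, (1.0 + g * g - s * s) / (2.0 * g)))


def _transport_electron_kernel(pos, u, e_ev, geom: MicroGeometry, rng,
                               score, score_escape, depth: int = 0) -> None:
    """Transport one electron (and its knock-on secondaries) to absorption.

    ``score(r, e)`` receives every energy deposit; ``score_escape(e)``
    energy leaving the cube.
    """
    x, y, z = pos
    ux, uy, uz = u
    cutoff = ELECTRON_CUTOFF_EV
    r_np = geom.np_spec.radius_nm
    half = geom.cube_half_nm
    secondaries = []
    while e_ev > cutoff:
        r_now = math.sqrt(x * x + y * y + z * z)
        region = "np" if r_now < r_np else "water"
        tab = geom.electron_tables(region)
        # early exit: the electron can no longer reach the radial grid or
        # the cube boundary -> the rest of its energy stays beyond the grid
        res_range = tab.csda_range(e_ev)
        if (r_now - res_range > GRID_MAX_NM
                and half - max(abs(x), abs(y), abs(z)) > res_range):
            score(r_now, e_ev)
            e_ev = 0.0
            break
        if e_ev > _E_CONDENSED_EV:
            # condensed step with continuous loss
            step = 0.08 * res_range
            d_sph = geom.dist_to_sphere((x, y, z), (ux, uy, uz))
            if d_sph < step:
                step = max(d_sph + 1e-3, 1e-3)
            d_cube = geom.dist_to_cube((x, y, z), (ux, uy, uz))
            exit_after = step >= d_cube
            if exit_after:
                step = d_cube
            s_val = tab.stopping(e_ev)
            de = s_val * step
            if de > e_ev - _E_CONDENSED_EV:
                de = e_ev - _E_CONDENSED_EV + 1.0
                step = min(step, de / s_val)
            de = min(de, e_ev)
            _score_segment((x, y, z), (ux, uy, uz), step, de, score, rng)
            e_ev -= de
            x += step * ux
            y += step * uy
            z += step * uz
            if exit_after:
                score_escape(e_ev)
                e_ev = 0.0
                break
            # Highland multiple-scattering angle for the step
            x0 = _X0_NM["gold" if region == "np" and
                        geom.np_spec.material == "gold" else "water"]
            pc = math.sqrt(e_ev * (e_ev + 2.0 * _MEC2_EV))
            beta_pc = pc * pc / (e_ev + _MEC2_EV)
            theta0 = 13.6e6 / beta_pc * math.sqrt(step / x0) * (
                1.0 + 0.038 * max(math.log(step / x0), -20.0))
            theta = abs(rng.standard_normal()) * max(theta0, 1e-6)
            ux, uy, uz = _rotate((ux, uy, uz), math.cos(min(theta, math.pi)), rng)
        else:
            # discrete inelastic events
            if e_ev <= 2.0 * _W_MIN_EV:
                score(r_now, e_ev)
                e_ev = 0.0
                break
            mean_eps = _W_MIN_EV * math.log(e_ev / (2.0 * _W_MIN_EV)) / (
                1.0 - 2.0 * _W_MIN_EV / e_ev)
            lam = mean_eps / tab.stopping(e_ev)
            path = -math.log(1.0 - rng.random()) * lam
            d_sph = geom.dist_to_sphere((x, y, z), (ux, uy, uz))
            d_cube = geom.dist_to_cube((x, y, z), (ux, uy, uz))
            bound = min(d_sph, d_cube)
            if path >= bound:
                # move to the boundary and resample in the new region
                x += (bound + 1e-3) * ux
                y += (bound + 1e-3) * uy
                z += (bound + 1e-3) * uz
                if not geom.inside_cube((x, y, z)):
                    score_escape(e_ev)
                    e_ev = 0.0
                    break
                continue
            x += path * ux
            y += path * uy
            z += path * uz
            r_ev = math.sqrt(x * x + y * y + z * z)
            umax = 1.0 - 2.0 * _W_MIN_EV / e_ev
            eps = _W_MIN_EV / (1.0 - rng.random() * umax)
            eps = min(eps, e_ev)
            if eps > _DELTA_SPAWN_EV and eps > cutoff and depth < 8:
                ct_s = math.sqrt(min(eps / e_ev, 1.0))
                sdir = _rotate((ux, uy, uz), ct_s, rng)
                secondaries.append(((x, y, z), sdir, eps))
            else:
                score(r_ev, eps)
            e_ev -= eps
            g = e_ev / (e_ev + 5e3)
            ux, uy, uz = _rotate((ux, uy, uz), _hg_cos(g, rng), rng)
    if e_ev > 0.0:
        score(math.sqrt(x * x + y * y + z * z), e_ev)
    for spos, sdir, se in secondaries:
        _transport_electron_kernel(spos, sdir, se, geom, rng, score,
                                   score_escape, depth + 1)


def _score_segment(pos, u, step, de, score, rng):
    """Deposit continuous loss along a segment.

    If the segment passes near the radial grid the deposit is distributed
    over several points for smoother shell tallies; otherwise a single
    random point preserves the mean.
    """
    x, y, z = pos
    ux, uy, uz = u
    # closest approach of the segment to the origin
    t_ca = -(x * ux + y * uy + z * uz)
    t_ca = min(max(t_ca, 0.0), step)
    cx, cy, cz = x + t_ca * ux, y + t_ca * uy, z + t_ca * uz
    d_min = math.sqrt(cx * cx + cy * cy + cz * cz)
    if d_min < GRID_MAX_NM * 1.2:
        k = int(min(max(step / 25.0, 1.0), 40.0))
    else:
        k = 1
    for i in range(k):
        t = (i + rng.random()) / k * step
        score(math.sqrt((x + t * ux) ** 2 + (y + t * uy) ** 2
                        + (z + t * uz) ** 2), de / k)


def transport_electron(state: ParticleState, geometry: MicroGeometry,
                       rng) -> list[tuple[np.ndarray, float]]:
    """Public electron-transport API: returns [(position_nm, deposit_eV)].

    Deposits plus any energy escaping the cube always sum to the initial
    kinetic energy.
    """
    deposits: list[tuple[np.ndarray, float]] = []
    pos0 = np.asarray(state.position, dtype=float)

    # the kernel scores by radius; for the list API we track the last
    # scoring call's position via a wrapper that re-runs with positions
    class _Recorder:
        def __init__(self):
            self.items = []
            self.escaped = 0.0

    rec = _Recorder()

    def score(r, e):
        rec.items.append((r, e))

    def score_escape(e):
        rec.escaped += e

    _transport_electron_kernel(tuple(pos0), tuple(state.direction),
                               state.energy_keV * 1e3, geometry, rng,
                               score, score_escape)
    for r, e in rec.items:
        deposits.append((r, e))
    return deposits


# ---------------------------------------------------------------------------
# photon interactions

def _photo_absorb(pos, e_kev, region, geom, rng, score, photon_stack):
    """Photoabsorption: photoelectron plus the full relaxation cascade."""
    element = "Au" if (region == "np" and geom.np_spec.material == "gold") else "O"
    model = get_relaxation_model(element)
    e_ev = e_kev * 1e3
    min_b = min(model.binding_eV[s] for s in model.shells)
    if e_ev <= min_b:
        # below all inner shells: valence ionization, full transfer
        if e_ev > ELECTRON_CUTOFF_EV:
            _transport_electron_kernel(pos, _isotropic(rng), e_ev, geom, rng,
                                       score, photon_stack.score_escape)
        else:
            score(math.sqrt(pos[0] ** 2 + pos[1] ** 2 + pos[2] ** 2), e_ev)
        return
    shell = model.select_shell(e_ev, rng)
    binding = model.binding_eV[shell]
    pe_energy = e_ev - binding
    if pe_energy > ELECTRON_CUTOFF_EV:
        _transport_electron_kernel(pos, _isotropic(rng), pe_energy, geom, rng,
                                   score, photon_stack.score_escape)
    else:
        score(math.sqrt(pos[0] ** 2 + pos[1] ** 2 + pos[2] ** 2), pe_energy)
    for q in model.relax(shell, rng):
        if q.kind == "photon":
            photon_stack.push(pos, _isotropic(rng), q.energy_eV / 1e3)
        elif q.energy_eV > ELECTRON_CUTOFF_EV:
            _transport_electron_kernel(pos, _isotropic(rng), q.energy_eV,
                                       geom, rng, score,
                                       photon_stack.score_escape)
        else:
            score(math.sqrt(pos[0] ** 2 + pos[1] ** 2 + pos[2] ** 2),
                  q.energy_eV)


class _PhotonStack:
    def __init__(self, score_escape):
        self.stack = []
        self.score_escape = score_escape

    def push(self, pos, u, e_kev):
        if e_kev * 1e3 > ELECTRON_CUTOFF_EV:
            self.stack.append((tuple(pos), tuple(u), e_kev))


def _transport_photon(pos, u, e_kev, geom, mu_water, mu_np, rng, score,
                      score_escape, score_np_interaction) -> None:
    """Analog photon transport in the two-region cube."""
    stack = _PhotonStack(score_escape)
    stack.push(pos, u, e_kev)
    while stack.stack:
        (pos, u, e_kev) = stack.stack.pop()
        x, y, z = pos
        ux, uy, uz = u
        while True:
            r2 = x * x + y * y + z * z
            region = "np" if r2 < geom.np_spec.radius_nm ** 2 else "water"
            tab = mu_np if region == "np" else mu_water
            pe, inc, coh, pair = tab.components(e_kev)
            mu = pe + inc + coh + pair
            path = -math.log(1.0 - rng.random()) / mu if mu > 0 else math.inf
            d_sph = geom.dist_to_sphere((x, y, z), (ux, uy, uz))
            d_cube = geom.dist_to_cube((x, y, z), (ux, uy, uz))
            bound = min(d_sph, d_cube)
            if path >= bound:
                x += (bound + 1e-3) * ux
                y += (bound + 1e-3) * uy
                z += (bound + 1e-3) * uz
                if not geom.inside_cube((x, y, z)):
                    score_escape(e_kev * 1e3)
                    break
                continue
            x += path * ux
            y += path * uy
            z += path * uz
            if region == "np":
                score_np_interaction(1.0)
            xi = rng.random() * mu
            if xi < pe:
                _photo_absorb((x, y, z), e_kev, region, geom, rng, score, stack)
                break
            elif xi < pe + inc:
                e_sc, ct = sample_compton_scatter(e_kev, rng)
                e_el_ev = (e_kev - e_sc) * 1e3
                # electron direction from momentum conservation
                new_u = _rotate((ux, uy, uz), ct, rng)
                px = e_kev * ux - e_sc * new_u[0]
                py = e_kev * uy - e_sc * new_u[1]
                pz = e_kev * uz - e_sc * new_u[2]
                pn = math.sqrt(px * px + py * py + pz * pz)
                el_u = (px / pn, py / pn, pz / pn) if pn > 0 else (ux, uy, uz)
                if e_el_ev > ELECTRON_CUTOFF_EV:
                    _transport_electron_kernel((x, y, z), el_u, e_el_ev, geom,
                                               rng, score, score_escape)
                else:
                    score(math.sqrt(x * x + y * y + z * z), e_el_ev)
                ux, uy, uz = new_u
                e_kev = e_sc
                if e_kev * 1e3 <= ELECTRON_CUTOFF_EV:
                    score(math.sqrt(x * x + y * y + z * z), e_kev * 1e3)
                    break
            elif xi < pe + inc + coh:
                ct = _thomson_cos(rng)
                ux, uy, uz = _rotate((ux, uy, uz), ct, rng)
            else:
                # pair production: electron and positron share E - 2 m_e c^2;
                # the positron annihilates at rest into two 511 keV photons
                avail = (e_kev - _PAIR_THRESHOLD_KEV) * 1e3
                frac = rng.random()
                for part_e in (avail * frac, avail * (1.0 - frac)):
                    if part_e > ELECTRON_CUTOFF_EV:
                        _transport_electron_kernel(
                            (x, y, z), (ux, uy, uz), part_e, geom, rng,
                            score, score_escape)
                    else:
                        score(math.sqrt(x * x + y * y + z * z), part_e)
                ann = _isotropic(rng)
                stack.push((x, y, z), ann, 511.0)
                stack.push((x, y, z), (-ann[0], -ann[1], -ann[2]), 511.0)
                break


def _thomson_cos(rng) -> float:
    while True:
        ct = rng.uniform(-1.0, 1.0)
        if rng.random() * 2.0 <= 1.0 + ct * ct:
            return ct


# ---------------------------------------------------------------------------
# drivers

def _history_rng(seed: int, index: int):
    return np.random.default_rng((int(seed), int(index)))


def run_micro(spectrum: EnergySpectrum, np_spec: NanoparticleSpec,
              n_primaries: int, seed: int, variance_reduction: bool = False,
              beam_radius_nm: float | None = None,
              full_face: bool = False,
              cube_half_nm: float = _CUBE_HALF_NM) -> ShellTally:
    """Transport beam primaries through the micro cube.

    Analog mode aims a parallel beam (disk of ``beam_radius_nm``) along +z
    at the cube; paired nanoparticle/water-baseline runs with the same seed
    share identical per-history random streams, so histories that never
    touch the nanosphere cancel exactly in dose-enhancement ratios.

    With ``variance_reduction=True`` (photons only) the returned tally is
    the combined estimate ``equilibrium + forced(np) - forced(water)``.
    """
    if n_primaries < 1:
        raise ValueError("n_primaries must be positive")
    if np_spec.radius_nm >= cube_half_nm:
        raise ValueError("nanoparticle larger than the micro cube")
    e_max_kev = spectrum.max_energy_keV
    if e_max_kev * 1e3 <= ELECTRON_CUTOFF_EV:
        raise ValueError("transport cutoff exceeds all source energies")
    if variance_reduction:
        if spectrum.species != "photon":
            raise ValueError("variance reduction supports photons only")
        forced_np = forced_interaction_estimate(spectrum, np_spec,
                                                n_primaries, seed)
        forced_w = forced_interaction_estimate(
            spectrum, NanoparticleSpec(np_spec.diameter_nm, "water"),
            n_primaries, seed)
        pedestal = water_baseline_tally(spectrum, np_spec,
                                        max(n_primaries // 2, 1000), seed)
        return combine_tallies(pedestal, add=[forced_np], sub=[forced_w])

    geom = MicroGeometry(np_spec, cube_half_nm)
    edges = make_shell_grid(np_spec.radius_nm)
    acc = _Accumulator(edges, np_spec.radius_nm)
    if beam_radius_nm is None:
        beam_radius_nm = 5000.0 if spectrum.species == "photon" else 2000.0
    mu_w = _PhotonTables(geom.water, e_max_kev)
    mu_np = (mu_w if np_spec.material == "water"
             else _PhotonTables(geom.np_material, e_max_kev))

    rng0 = np.random.default_rng((seed, 0xE0))
    energies = sample_energies(spectrum, n_primaries, rng0)
    if full_face:
        xs = rng0.uniform(-cube_half_nm, cube_half_nm, n_primaries)
        ys = rng0.uniform(-cube_half_nm, cube_half_nm, n_primaries)
    else:
        radii = beam_radius_nm * np.sqrt(rng0.random(n_primaries))
        phis = 2.0 * math.pi * rng0.random(n_primaries)
        xs = radii * np.cos(phis)
        ys = radii * np.sin(phis)

    for h in range(n_primaries):
        rng = _history_rng(seed, h)
        x0 = float(xs[h])
        y0 = float(ys[h])
        pos = (x0, y0, -geom.cube_half_nm + 1e-3)
        e_kev = float(energies[h])
        if spectrum.species == "photon":
            _transport_photon(pos, (0.0, 0.0, 1.0), e_kev, geom, mu_w, mu_np,
                              rng, acc.score, acc.score_escape,
                              acc.score_np_interaction)
            acc.flush_history(1.0, injected_ev=e_kev * 1e3)
        else:
            _transport_proton_micro(pos, e_kev, geom, rng, acc)
            acc.flush_history(1.0)

    area = ((2.0 * cube_half_nm) ** 2 if full_face
            else math.pi * beam_radius_nm ** 2)
    fluence_norm = n_primaries / area
    return acc.finalize(fluence_norm, np_spec,
                        beam_label=spectrum.depth_label, mode="analog")


def forced_interaction_estimate(spectrum: EnergySpectrum,
                                np_spec: NanoparticleSpec,
                                n_primaries: int, seed: int,
                                cube_half_nm: float = _CUBE_HALF_NM) -> ShellTally:
    """Forced-interaction estimator of the nanoparticle contribution.

    Every history sends a photon through the nanosphere (impact parameter
    uniform over the projected disk) and forces one interaction inside it;
    the history weight is the chord interaction probability, making the
    tally an unbiased estimator of the analog NP-interaction contribution
    per unit fluence.
    """
    if spectrum.species != "photon":
        raise ValueError("forced interaction supports photons only")
    geom = MicroGeometry(np_spec, cube_half_nm)
    edges = make_shell_grid(np_spec.radius_nm)
    acc = _Accumulator(edges, np_spec.radius_nm)
    e_max_kev = spectrum.max_energy_keV
    mu_w = _PhotonTables(geom.water, e_max_kev)
    mu_np = (mu_w if np_spec.material == "water"
             else _PhotonTables(geom.np_material, e_max_kev))
    R = np_spec.radius_nm

    rng0 = np.random.default_rng((seed, 0xF0))
    energies = sample_energies(spectrum, n_primaries, rng0)
    b_radii = R * np.sqrt(rng0.random(n_primaries))

    for h in range(n_primaries):
        rng = _history_rng(seed, h)
        e_kev = float(energies[h])
        b = b_radii[h]
        chord = 2.0 * math.sqrt(max(R * R - b * b, 0.0))
        pe, inc, coh, pair = mu_np.components(e_kev)
        mu = pe + inc + coh + pair
        p_int = -math.expm1(-mu * chord)
        if p_int <= 0.0:
            acc.flush_history(0.0)
            continue
        # interaction point along the chord (truncated exponential)
        t = -math.log(1.0 - rng.random() * p_int) / mu
        phi = 2.0 * math.pi * rng.random()
        x = b * math.cos(phi)
        y = b * math.sin(phi)
        z = -math.sqrt(max(R * R - b * b, 0.0)) + t
        acc.score_np_interaction(1.0)
        xi = rng.random() * mu
        stack = _PhotonStack(acc.score_escape)
        if xi < pe:
            _photo_absorb((x, y, z), e_kev, "np", geom, rng, acc.score, stack)
        elif xi < pe + inc:
            e_sc, ct = sample_compton_scatter(e_kev, rng)
            e_el_ev = (e_kev - e_sc) * 1e3
            new_u = _rotate((0.0, 0.0, 1.0), ct, rng)
            if e_el_ev > ELECTRON_CUTOFF_EV:
                px = -e_sc * new_u[0]
                py = -e_sc * new_u[1]
                pz = e_kev - e_sc * new_u[2]
                pn = math.sqrt(px * px + py * py + pz * pz)
                _transport_electron_kernel(
                    (x, y, z), (px / pn, py / pn, pz / pn), e_el_ev, geom,
                    rng, acc.score, acc.score_escape)
            else:
                acc.score(math.sqrt(x * x + y * y + z * z), e_el_ev)
            stack.push((x, y, z), new_u, e_sc)
        elif xi < pe + inc + coh:
            ct = _thomson_cos(rng)
            stack.push((x, y, z), _rotate((0.0, 0.0, 1.0), ct, rng), e_kev)
        else:
            avail = (e_kev - _PAIR_THRESHOLD_KEV) * 1e3
            frac = rng.random()
            for part_e in (avail * frac, avail * (1.0 - frac)):
                if part_e > ELECTRON_CUTOFF_EV:
                    _transport_electron_kernel((x, y, z), (0.0, 0.0, 1.0),
                                               part_e, geom, rng, acc.score,
                                               acc.score_escape)
                else:
                    acc.score(math.sqrt(x * x + y * y + z * z), part_e)
            ann = _isotropic(rng)
            stack.push((x, y, z), ann, 511.0)
            stack.push((x, y, z), (-ann[0], -ann[1], -ann[2]), 511.0)
        # transport any secondary photons analogically
        while stack.stack:
            ppos, pu, pe_kev = stack.stack.pop()
            _transport_photon(ppos, pu, pe_kev, geom, mu_w, mu_np, rng,
                              acc.score, acc.score_escape, lambda w=1.0: None)
        acc.flush_history(p_int)

    area = math.pi * R * R
    fluence_norm = n_primaries / area
    tally = acc.finalize(fluence_norm, np_spec,
                         beam_label=spectrum.depth_label, mode="forced")
    return tally


def water_baseline_tally(spectrum: EnergySpectrum,
                         np_spec: NanoparticleSpec,
                         n_primaries: int, seed: int) -> ShellTally:
    """Flat pedestal at the analog dose of the standalone water cube.

    This is the non-enhanced baseline D_W of the additional-relative-dose
    metric: a full-face parallel beam on the 1 mm water cube, scored as
    total in-cube energy per unit fluence divided by the cube volume.  At
    kVp energies it is close to collision kerma (charged-particle
    equilibrium develops within tens of micrometers); at 6 MV it is much
    smaller, because megavoltage electrons mostly leave the cube before
    depositing their energy.
    """
    wnp = NanoparticleSpec(np_spec.diameter_nm, "water")
    analog = run_micro(spectrum, wnp, n_primaries, seed, full_face=True)
    v_cube = (2.0 * _CUBE_HALF_NM) ** 3
    in_cube = float(analog.energy_per_shell.sum()) + analog.beyond_grid_ev
    u0 = in_cube / v_cube
    u0_var = (analog.inside_np_var + analog.outside_np_var) / v_cube**2
    edges = make_shell_grid(np_spec.radius_nm)
    vols = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    inside = edges[1:] <= np_spec.radius_nm + 1e-9
    return ShellTally(
        shell_edges=edges,
        energy_per_shell=u0 * vols,
        variance_per_shell=u0_var * vols ** 2,
        n_primaries=n_primaries,
        np_spec=np_spec,
        beam_label=spectrum.depth_label,
        mode="baseline",
        inside_np_ev=float(u0 * vols[inside].sum()),
        inside_np_var=float(u0_var * vols[inside].sum() ** 2),
        outside_np_ev=float(u0 * vols[~inside].sum()),
        outside_np_var=float(u0_var * vols[~inside].sum() ** 2),
    )


def equilibrium_field_tally(spectrum: EnergySpectrum,
                            np_spec: NanoparticleSpec,
                            n_samples: int, seed: int) -> ShellTally:
    """Flat far-field (pedestal) tally for a broad uniform photon beam.

    In a homogeneous water medium under uniform irradiation the energy
    density is uniform by translation symmetry; its value per unit fluence
    is the collision kerma sum(phi(E) * mu(E) * E_transfer(E)), estimated
    here by Monte Carlo sampling of interaction channels.  Secondary
    photons (Compton-scattered, fluorescence, annihilation) escape the
    millimeter cube and are excluded from the transfer.
    """
    if spectrum.species != "photon":
        raise ValueError("equilibrium field tally supports photons only")
    water = get_material("water")
    mu_w = _PhotonTables(water, spectrum.max_energy_keV)
    model_o = get_relaxation_model("O")
    rng = np.random.default_rng((seed, 0xE9))
    energies = sample_energies(spectrum, n_samples, rng)
    transfers = np.zeros(n_samples)
    for i, e_kev in enumerate(energies):
        pe, inc, coh, pair = mu_w.components(e_kev)
        mu = pe + inc + coh + pair
        xi = rng.random() * mu
        e_ev = e_kev * 1e3
        if xi < pe:
            if e_ev <= model_o.binding_eV["K"]:
                t = e_ev
            else:
                shell = model_o.select_shell(e_ev, rng)
                photons = 0.0
                for q in model_o.relax(shell, rng):
                    if q.kind == "photon":
                        photons += q.energy_eV
                t = e_ev - photons
        elif xi < pe + inc:
            e_sc, _ = sample_compton_scatter(e_kev, rng)
            t = (e_kev - e_sc) * 1e3
        elif xi < pe + inc + coh:
            t = 0.0
        else:
            t = e_ev - _PAIR_THRESHOLD_KEV * 1e3
        transfers[i] = mu * t  # eV/nm^3 per unit fluence, per sample
    u0 = float(transfers.mean())
    u0_var = float(transfers.var(ddof=1) / n_samples)
    edges = make_shell_grid(np_spec.radius_nm)
    vols = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    r_np = np_spec.radius_nm
    inside = edges[1:] <= r_np + 1e-9
    return ShellTally(
        shell_edges=edges,
        energy_per_shell=u0 * vols,
        variance_per_shell=u0_var * vols ** 2,
        n_primaries=n_samples,
        np_spec=np_spec,
        beam_label=spectrum.depth_label,
        mode="equilibrium",
        beyond_grid_ev=0.0,
        escaped_ev=0.0,
        inside_np_ev=float(u0 * vols[inside].sum()),
        inside_np_var=float(u0_var * vols[inside].sum() ** 2),
        outside_np_ev=float(u0 * vols[~inside].sum()),
        outside_np_var=float(u0_var * vols[~inside].sum() ** 2),
    )


# ---------------------------------------------------------------------------
# protons in the micro cube

def proton_pedestal_tally(spectrum: EnergySpectrum,
                          np_spec: NanoparticleSpec,
                          n_samples: int, seed: int) -> ShellTally:
    """Flat far-field energy density for a broad uniform proton beam.

    Under charged-particle equilibrium the energy density per unit fluence
    equals the fluence-weighted mean stopping power: U0 = <S(E)> in eV/nm
    (1 MeV/mm = 1 eV/nm), sampled over the spectrum.  Protons below the
    0.5 MeV stopping-power window are evaluated at the window floor.
    """
    if spectrum.species != "proton":
        raise ValueError("proton pedestal requires a proton spectrum")
    water = get_material("water")
    rng = np.random.default_rng((seed, 0xD0))
    energies = sample_energies(spectrum, n_samples, rng) / 1e3  # MeV
    from .physics_data import PROTON_ENERGY_WINDOW_MEV

    lo = PROTON_ENERGY_WINDOW_MEV[0]
    s_vals = np.array([
        proton_stopping_power(water, max(e, lo)) for e in energies])  # eV/nm
    u0 = float(s_vals.mean())
    u0_var = float(s_vals.var(ddof=1) / n_samples)
    edges = make_shell_grid(np_spec.radius_nm)
    vols = 4.0 / 3.0 * np.pi * np.diff(edges ** 3)
    inside = edges[1:] <= np_spec.radius_nm + 1e-9
    return ShellTally(
        shell_edges=edges,
        energy_per_shell=u0 * vols,
        variance_per_shell=u0_var * vols ** 2,
        n_primaries=n_samples,
        np_spec=np_spec,
        beam_label=spectrum.depth_label,
        mode="proton-pedestal",
        inside_np_ev=float(u0 * vols[inside].sum()),
        inside_np_var=float(u0_var * vols[inside].sum() ** 2),
        outside_np_ev=float(u0 * vols[~inside].sum()),
        outside_np_var=float(u0_var * vols[~inside].sum() ** 2),
    )


def proton_np_perturbation_estimate(spectrum: EnergySpectrum,
                                    np_spec: NanoparticleSpec,
                                    n_primaries: int, seed: int) -> ShellTally:
    """Aimed proton runs: impact parameters uniform over the nanoparticle
    disk, normalized per unit fluence over that disk.

    Used in paired gold/water form: with a common seed the random streams
    are identical until the track enters the sphere and re-synchronized
    after it leaves, so the difference of the two tallies isolates the
    nanoparticle's perturbation with most far-field noise cancelling.
    """
    if spectrum.species != "proton":
        raise ValueError("aimed proton estimator requires a proton spectrum")
    geom = MicroGeometry(np_spec)
    edges = make_shell_grid(np_spec.radius_nm)
    acc = _Accumulator(edges, np_spec.radius_nm)
    R = np_spec.radius_nm
    rng0 = np.random.default_rng((seed, 0xD1))
    energies = sample_energies(spectrum, n_primaries, rng0)
    b_radii = R * np.sqrt(rng0.random(n_primaries))
    phis = 2.0 * math.pi * rng0.random(n_primaries)
    for h in range(n_primaries):
        rng = _history_rng(seed, h)
        resync = np.random.default_rng((seed, h, 77))
        x0 = b_radii[h] * math.cos(phis[h])
        y0 = b_radii[h] * math.sin(phis[h])
        _transport_proton_micro((x0, y0, -geom.cube_half_nm + 1e-3),
                                float(energies[h]), geom, rng, acc,
                                resync_rng=resync)
        acc.flush_history(1.0)
    fluence_norm = n_primaries / (math.pi * R * R)
    return acc.finalize(fluence_norm, np_spec,
                        beam_label=spectrum.depth_label, mode="proton-aimed")


def _transport_proton_micro(pos, e_kev, geom: MicroGeometry, rng,
                            acc: _Accumulator, resync_rng=None) -> None:
    """Continuous proton slowing along +z with explicit delta-ray emission."""
    water = geom.water
    np_mat = geom.np_material
    x, y, z = pos
    e_mev = e_kev / 1e3
    r_np = geom.np_spec.radius_nm
    half = geom.cube_half_nm
    b2 = x * x + y * y
    was_in_np = False
    while z < half and e_mev > 0.5:
        r2 = b2 + z * z
        in_np = r2 < r_np * r_np
        if was_in_np and not in_np and resync_rng is not None:
            # re-synchronize the stream after leaving the sphere so paired
            # gold/water runs share identical downstream randomness
            rng = resync_rng
            resync_rng = None
        was_in_np = in_np
        mat = np_mat if in_np else water
        # segment length: fine near the nanoparticle, coarse elsewhere
        dist2_np = math.sqrt(b2 + z * z)
        if in_np:
            seg = min(max(r_np / 10.0, 1.0), geom.dist_to_sphere(
                (x, y, z), (0.0, 0.0, 1.0)) + 1e-3)
        elif dist2_np < 4.0 * GRID_MAX_NM:
            seg = 200.0 if dist2_np < 2000.0 else 2000.0
            d_sph = geom.dist_to_sphere((x, y, z), (0.0, 0.0, 1.0))
            if d_sph < seg:
                seg = d_sph + 1e-3
        else:
            seg = 2e4
        seg = min(seg, half - z)
        s_total = proton_stopping_power(mat, e_mev) * 1e3 / 1e6  # eV/nm
        # Rutherford delta-ray yield above Tmin
        beta2 = 1.0 - 1.0 / (1.0 + e_mev / 938.272) ** 2
        gamma2 = (1.0 + e_mev / 938.272) ** 2
        t_max = 2.0 * _MEC2_EV * beta2 * gamma2  # heavy-projectile limit, eV
        n_e = mat.electrons_per_gram * mat.density_g_cm3 / 1e21  # per nm^3
        k_r = 2.0 * math.pi * (2.818e-6) ** 2 * _MEC2_EV * n_e / beta2  # eV/nm
        t_min = _PROTON_DELTA_TMIN_EV
        if t_max > 2.0 * t_min:
            n_delta_mean = k_r * seg * (1.0 / t_min - 1.0 / t_max)
            e_delta_rate = k_r * math.log(t_max / t_min)  # eV/nm
        else:
            n_delta_mean = 0.0
            e_delta_rate = 0.0
        s_restricted = max(s_total - e_delta_rate, 0.1 * s_total)
        # continuous (restricted) loss along the segment
        de_cont = s_restricted * seg
        _score_segment((x, y, z), (0.0, 0.0, 1.0), seg, de_cont,
                       acc.score, rng)
        n_delta = rng.poisson(n_delta_mean) if n_delta_mean > 0 else 0
        de_delta = 0.0
        for _ in range(n_delta):
            t_ev = t_min / (1.0 - rng.random() * (1.0 - t_min / t_max))
            zd = z + rng.random() * seg
            de_delta += t_ev
            r_d = math.sqrt(b2 + zd * zd)
            etab = geom.electron_tables("np" if r_d < r_np else "water")
            if r_d - etab.csda_range(t_ev) > GRID_MAX_NM:
                acc.score(r_d, t_ev)
                continue
            ct = math.sqrt(min(t_ev / t_max, 1.0))
            ddir = _rotate((0.0, 0.0, 1.0), ct, rng)
            _transport_electron_kernel((x, y, zd), ddir, t_ev, geom, rng,
                                       acc.score, acc.score_escape)
        if in_np or dist2_np < 2.0 * GRID_MAX_NM:
            acc.score_np_interaction(n_delta if in_np else 0.0)
        e_mev -= (de_cont + de_delta) / 1e6
        z += seg
    if e_mev > 0.0 and z < half:
        acc.score(math.sqrt(b2 + z * z), e_mev * 1e6)
    elif e_mev > 0.0:
        acc.score_escape(e_mev * 1e6)
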