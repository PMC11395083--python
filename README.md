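# nanodose

Desk-scale Monte Carlo microdosimetry of gold-nanoparticle-enhanced
radiotherapy.

Gold nanoparticles (GNPs) are studied as radiosensitizers: gold's
photoelectric cross-section grows as Z^4-5, so a nanoparticle bathed in a
kilovoltage X-ray field absorbs far more than the tissue it displaces and
sprays short-range photo- and Auger electrons into its immediate
surroundings.  `nanodose` asks the quantitative questions behind that
picture for three clinical beams - 140 kVp X-rays, 6 MV linac photons,
and 95 MeV protons:

* How is the extra energy distributed around a single nanosphere
  (10-80 nm) as a function of radial distance?
* How far does the enhanced zone extend, and how does it scale with
  particle size?
* What does the enhancement amount to macroscopically at a realistic
  gold concentration (10 mg/L)?

The simulation runs in two stages.  Stage 1 transports the beam through a
20 cm soft-tissue phantom (analog photon transport under the kerma
approximation; CSDA proton stepping with Bohr straggling) and extracts
the energy spectra at the tumor boundaries (5 and 7 cm).  Stage 2
transports those spectra event by event through a 1 mm water cube with a
single gold (or baseline water) nanosphere at its center, scoring energy
in concentric shells (5 nm resolution near the surface).  Rare
photon-nanoparticle interactions are sampled with a forced-interaction
estimator whose history weight is the chord interaction probability.

Core quantities (in the field's notation):

* `DEF_SE(r) = U_GNP(r) / U_WNP(r)` - spatial energy-density enhancement
  versus distance from the particle center, with the density-corrected
  piecewise form inside the particle;
* enhancement-zone radius - where `DEF_SE` settles onto its pedestal;
* `ADR = (D_GNP - D_W) / D_W` and `ADR_LT` (scored outside the particle
  volumes, "living tissue") at a mass concentration;
* mean inter-particle spacing `n^{-1/3}` at a concentration;
* surface potential `phi(r) = Q / (4 pi eps0 r)` of a charged particle.

See `docs/methods.md` for the physics models, estimators and their
limitations.

## Worked example

```python
from nanodose.beam_models import make_kvp_spectrum
from nanodose.macro_transport import run_macro_photons
from nanodose.micro_transport import (
    NanoparticleSpec, forced_interaction_estimate, water_baseline_tally,
    combine_tallies)
from nanodose.dosimetry_metrics import (
    adr_lt_estimate, def_se_profile, enhancement_zone_radius,
    mean_np_spacing, surface_potential)

# stage 1: 140 kVp beam to tumor depth
macro = run_macro_photons(make_kvp_spectrum(140.0), 20000, seed=1)
at_7cm = macro.spectrum_at(70.0)
print(f"mean energy at 7 cm: {at_7cm.mean_energy_keV():.1f} keV")

# stage 2: 20 nm gold nanoparticle vs water baseline
np_spec = NanoparticleSpec(20.0, "gold")
forced_au = forced_interaction_estimate(at_7cm, np_spec, 20000, seed=1)
forced_w = forced_interaction_estimate(
    at_7cm, NanoparticleSpec(20.0, "water"), 20000, seed=1)
baseline = water_baseline_tally(at_7cm, np_spec, 20000, seed=1)

profile = def_se_profile(
    combine_tallies(baseline, add=[forced_au], sub=[forced_w]), baseline)
print(f"first-shell DEF: {profile.first_outer_shell_def():.1f}")
print(f"enhancement zone: {enhancement_zone_radius(profile):.0f} nm")

adr = adr_lt_estimate(np_spec, 10.0, forced_au, forced_w, baseline)
print(f"ADR_LT at 10 mg/L: {adr.adr_lt:.2e}")
print(f"spacing at 10 mg/L: {mean_np_spacing(10.0, 20.0):.1f} um")
print(f"one charge at the surface: {surface_potential(1, 20.0):.0f} mV")
```

Output (seed 1):

```
mean energy at 7 cm: 68.7 keV
first-shell DEF: 9.5
enhancement zone: 75 nm
ADR_LT at 10 mg/L: 3.17e-04
spacing at 10 mg/L: 2.0 um
one charge at the surface: 72 mV
```

Reading: at 7 cm depth the tube spectrum has hardened to a ~68 keV mean,
where gold's photoelectric coefficient exceeds water's several-hundred-fold.
The 5 nm shell hugging the particle surface receives ~10x the baseline
dose, the enhancement fades into the pedestal ~75 nm out, and at 10 mg/L
(particles ~2 um apart) the tissue-wide extra dose is a fraction of a
part per thousand - the local and global pictures differ by orders of
magnitude, which is the study's central point.  A single displaced
electron charges a 20 nm particle to ~72 mV at its surface.

The same workflow runs from the shell:

```bash
nanodose run --config run.yaml --out results/run1
nanodose metrics spacing --conc 10 --diameter 10
nanodose metrics potential --charge 1 --radius-nm 20
```

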