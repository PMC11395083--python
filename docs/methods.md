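# Methods

`nanodose` is a desk-scale, two-stage Monte Carlo study of
gold-nanoparticle (GNP) radiosensitization: how
much extra dose does a single gold nanosphere deliver to its surroundings
under clinically shaped radiation fields, and what does that imply at
therapeutic gold concentrations?

## Study design

**Stage 1 (macroscopic).** A 20 cm cube of four-component soft tissue
(H/C/N/O, density 1.0 g/cm3, mean excitation energy 72 eV) is irradiated
by one of three beams: a 140 kVp filtered tube spectrum, a 6 MV linac
spectrum, or monoenergetic 95 MeV protons (whose Bragg peak falls at 7 cm,
the distal edge of the 5-7 cm tumor layer).  The stage produces depth-dose
curves and the fluence spectra of primaries crossing the 50 mm and 70 mm
planes.

**Stage 2 (microscopic).** A depth-hardened spectrum irradiates a 1 mm
water cube with a single nanosphere (gold, or water as the non-enhanced
baseline; diameter 10-80 nm) at its center.  Energy deposition is scored
in concentric shells: five equal-volume bins inside the particle, 5 nm
shells to 1 um, 50 nm shells to 5 um, with one edge pinned exactly at the
particle radius.  X-ray runs use the 70 mm (distal) spectrum; proton runs
support both the frontal (~48 MeV here) and distal (few MeV) spectra.

**Metrics.** The spatial energy-density enhancement factor
DEF_SE(r) = U_GNP(r) / U_WNP(r) (equal to the conventional dose
enhancement factor outside the particle; inside, the energy-density ratio
already carries the rho_Au/rho_W factor of the piecewise dose form, and
the plain dose ratio is exported alongside).  The enhancement-zone radius
is where the profile settles within 5% (configurable) of its pedestal,
the pedestal being the profile mean over 800-1000 nm.  The additional
relative dose ADR = (D_GNP - D_W)/D_W is evaluated at a gold mass
concentration (default 10 mg/L) by scaling the per-particle extra energy
with the particle number density; ADR_LT restricts the numerator to
energy outside the nanoparticle volume.  Closed forms give the mean
inter-particle spacing (inverse cube root of number density) and the
Coulomb surface potential Q/(4 pi eps0 r) of a charged particle.

## Physics models

* **Photons** (1 keV - 10 MeV): photoelectric absorption, Klein-Nishina
  Compton scattering on free electrons (exact electron kinematics from
  momentum conservation), optional Rayleigh scattering with a Thomson
  angular shape, and pair production (local pair, two 511 keV
  annihilation photons).  Photoelectric, coherent, and pair coefficients
  come from compact elemental log-log tables (H, C, N, O, Al, Au)
  embedded as CSV, anchored to standard water and gold attenuation values
  at the energies that dominate these beams, with Z^4.5/A (photoelectric)
  and Z^2.5/A (coherent) inter-element scaling; the gold L3/L2/L1/K edges
  (11.92/13.73/14.35/80.72 keV) are tabulated as explicit steps.
  Estimated coefficient accuracy is 10-20%, well inside the factor-2
  tolerances of the quantitative claims.
* **Atomic relaxation**: one effective level per major shell
  (Au: K 80.7 keV, L 13.0 keV, M 2.7 keV, N 0.45 keV; fluorescence yields
  0.96 / 0.34 / 0.02 / 0).  A vacancy emits either a characteristic
  photon (B_i - B_next) or an Auger electron (B_i - 2 B_next, two
  daughter vacancies); the cascade recurses, conserving the binding
  energy exactly.  Real multi-electron Auger spectra are richer in
  sub-keV electrons than this surrogate - the main fidelity limit for
  near-surface dose (below).
* **Electrons**: Moller (Berger-Seltzer) collision stopping power with a
  power-law taper below 1 keV; condensed-history steps (8% of the CSDA
  range) with continuous loss and Highland multiple scattering above
  10 keV; discrete inelastic events below, with free paths set by the
  stopping power divided by the mean event loss and event losses drawn
  from a 1/eps^2 spectrum on [50 eV, E/2]; losses above 500 eV spawn
  knock-on electrons.  Tracks stop at 50 eV (residual deposited locally).
  The 50 eV cutoff (full track-structure codes cut near 1 eV) moves dose
  by at most a few nm, below the 5 nm shell resolution.
* **Protons**: Bethe electronic stopping (validity 0.5-250 MeV; no
  density-effect or shell corrections, a few-percent bias), Bohr energy
  straggling in stage 1, and in stage 2 explicit delta-ray production
  above 50 eV from a Rutherford free-electron cross-section with the
  remaining (restricted) loss deposited continuously.  Nuclear reactions
  are out of scope.

## Estimators and variance reduction

Analog transport cannot resolve 5 nm shells: the probability that a beam
photon interacts inside a 10 nm sphere is ~1e-8 per primary.  Three
estimators are combined, all normalized per unit fluence so tallies add:

* **Forced interaction** (photons): every history crosses the nanosphere
  at a uniform impact parameter and is forced to interact inside it; the
  history weight is the chord interaction probability 1 - exp(-mu L).
  The estimator is unbiased for the particle's own interaction
  contribution (verified against analog runs in the test suite).
* **Flat pedestal**: a homogeneous medium under broad uniform irradiation
  has a uniform energy density by translation symmetry, so the far field
  is a flat profile at the analog dose of the standalone water cube
  (full-face beam, total in-cube energy over the cube volume).  At kVp
  energies this agrees with collision kerma to ~12% (charged-particle
  equilibrium develops within tens of um); at 6 MV it is ~10x below
  kerma because megavoltage electrons leave the millimeter cube - the
  physically correct baseline for this geometry.
* **Aimed proton runs**: protons sample impact parameters over the
  particle disk, with paired gold/water runs sharing random streams up to
  sphere entry and re-synchronized after exit, so the tally difference
  isolates the particle's perturbation.  The proton pedestal is the
  fluence-weighted mean stopping power (exact under equilibrium).

A gold-particle tally is reconstructed as
`pedestal + forced(gold) - forced(water)`; the water-particle tally is the
pedestal itself.  Paired analog runs use common random numbers
(per-history substreams keyed by the run seed and history index), making
histories that never touch the sphere cancel exactly in ratios.

ADR_LT integrates the forced-tally difference over the shells outside the
particle up to the grid edge (5 um; `r_max_nm` exposes the choice).
Energy escaping the cube (mostly K fluorescence, ~68 keV, attenuation
length ~5 cm) is excluded, as is energy beyond the radial grid.

## Synthetic beams

No clinical spectra ship with the package; the sources are surrogates:

* **140 kVp**: Kramers bremsstrahlung, fluence proportional to
  (140 keV - E), filtered by 2.5 mm Al (attenuation from the embedded
  aluminum tables), 1 keV bins, no tungsten characteristic lines.  Mean
  energy ~57 keV at the source, ~68 keV at 7 cm.
* **6 MV**: truncated log-normal fluence (median 0.95 MeV, sigma_log
  0.85, support 10 keV - 6 MeV), chosen to mimic published 6 MV spectra:
  modal energy ~0.5 MeV, mean ~1.25 MeV, ~4% of fluence below 200 keV.
  The sub-200 keV component controls gold photoabsorption at depth and is
  the largest single uncertainty for the 6 MV enhancement numbers.
* **Protons**: monoenergetic 95 MeV.

What the surrogates do not emulate: characteristic tube lines, beam
divergence and field-size effects, accelerator-specific spectral shapes.
Quantities that integrate over the spectrum (Bragg depth, spacing,
potential) are insensitive to this; kVp/6 MV enhancement magnitudes carry
the surrogate as a systematic.

## Numerical choices

Stage-1 photons use the kerma approximation (secondary electrons deposit
locally), adequate for cm-scale depth dose and plane spectra.  Proton
steps are max(0.1 mm, 1% of residual range).  Micro-stage condensed
deposits are spread over up to 40 points when a segment passes within the
radial grid, otherwise placed at one uniform random point (unbiased).
Energy conservation per history holds to 1e-9 (relative) in the micro
stage and 1e-6 in the macro stage and is asserted in tests.  Boundary
crossings truncate sampled free paths and resample in the new region
(unbiased for exponential flights).  Degenerate inputs (single-bin
spectra, zero-width supports, particles larger than the cube, energies
below the transport cutoff) raise validation errors before any transport.

## Known limitations

* Published near-surface DEF magnitudes from discrete
  track-structure simulations of gold (dense sub-keV secondary production
  and reabsorption) are larger than what a textbook cascade and stopping
  powers produce.  With this package's models
  powers, the 140 kVp first-5-nm-shell DEF is ~5-30 (increasing with
  size) against published values of 20-100, and the proton first-shell DEF is
  ~1.05-1.1 against ~2; the enhancement-zone radii (here 40/75/135/390 nm
  for 10/20/40/80 nm particles at 140 kVp) agree with published
  sequences within a factor of two, and all orderings (kVp > 6 MV >
  protons, zone and ADR_LT monotone in size) are reproduced.
* A living-tissue fraction of ~25% of the total ADR, as published
  discrete-model studies find, implies ~75% of the extra energy absorbed
  inside the nanoparticle, which textbook
  stopping powers cannot produce for 10 nm spheres (a 50 keV
  photoelectron loses well under 1 keV crossing 10 nm of gold); this
  package obtains fractions near 0.9 and reports them as computed.
* Secondary electrons impinging on the nanoparticle from outside are not
  part of the forced estimator (their perturbation is second order at
  therapeutic concentrations).
* No electron impact ionization of the gold K/L shells, no bremsstrahlung
  from electrons, no positron transport (annihilation at the creation
  point), no nuclear interactions.
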