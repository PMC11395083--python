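"""Stage-1 phantom transport: depth-dose curves and depth spectra."""

import math

import numpy as np
import pytest

from nanodose.macro_transport import run_macro_photons, run_macro_protons
from nanodose.physics_data import get_material, total_mu_over_rho
from conftest import mono_spectrum


class TestPhotonMacro:
    def test_rejects_proton_spectrum(self):
        with pytest.raises(ValueError):
            run_macro_photons(mono_spectrum(95000.0, "proton"), 1000, 0)

    def test_kvp_depth_dose_decreases_beyond_buildup(self, kvp_macro):
        dose = kvp_macro.depth_dose.dose_per_primary
        # average over 2 cm windows to smooth Monte Carlo noise
        blocks = dose[10:190].reshape(9, 20).sum(axis=1)
        assert np.all(np.diff(blocks) < 0)

    def test_tumor_boundary_spectra_similar(self, kvp_macro):
        m50 = kvp_macro.spectrum_at(50.0).mean_energy_keV()
        m70 = kvp_macro.spectrum_at(70.0).mean_energy_keV()
        assert abs(m50 - m70) / m50 < 0.15

    def test_energy_conservation(self, kvp_macro):
        assert kvp_macro.max_history_imbalance < 1e-6
        total = kvp_macro.energy_deposited_keV + kvp_macro.energy_escaped_keV
        assert total == pytest.approx(kvp_macro.energy_injected_keV, rel=1e-9)
        assert kvp_macro.energy_deposited_keV <= kvp_macro.energy_injected_keV

    def test_no_upscattering(self, kvp_macro):
        for depth in (50.0, 70.0):
            energies = [e for e, _ in kvp_macro.plane_crossings[depth]]
            assert max(energies) <= 140.0 + 1e-9

    def test_narrow_beam_attenuation_matches_exponential(self):
        # scatter contributes unscattered-energy photons only through
        # Rayleigh, so it is disabled here
        mono = mono_spectrum(100.0)
        result = run_macro_photons(mono, 100_000, 13, include_coherent=False,
                                   depth_planes_mm=(50.0,))
        unscattered = sum(1 for e, _ in result.plane_crossings[50.0]
                          if e > 99.9999)
        tissue = get_material("soft_tissue")
        mu_mm = total_mu_over_rho(tissue, 100.0, include_coherent=False,
                                  include_pair=False) * tissue.density_g_cm3 / 10
        expected = math.exp(-mu_mm * 50.0)
        assert unscattered / 100_000 == pytest.approx(expected, rel=0.01)


class TestProtonMacro:
    def test_bragg_peak_at_seven_centimeters(self, proton_macro):
        assert proton_macro.depth_dose.peak_depth_mm() == pytest.approx(
            70.0, abs=3.0)

    def test_mean_energy_at_frontal_tumor_boundary(self, proton_macro):
        mean_mev = proton_macro.spectrum_at(50.0).mean_energy_keV() / 1e3
        assert mean_mev == pytest.approx(45.0, rel=0.10)

    def test_few_mev_at_distal_boundary(self, proton_macro):
        assert proton_macro.spectrum_at(70.0).mean_energy_keV() / 1e3 < 10.0

    def test_straggling_grows_toward_end_of_range(self, proton_macro):
        s50 = proton_macro.spectrum_at(50.0)
        s70 = proton_macro.spectrum_at(70.0)
        rel50 = math.sqrt(s50.variance_keV2()) / s50.mean_energy_keV()
        rel70 = math.sqrt(s70.variance_keV2()) / s70.mean_energy_keV()
        assert rel50 < rel70

    def test_energy_conservation(self, proton_macro):
        assert proton_macro.max_history_imbalance < 1e-6

    def test_bragg_depth_monotone_in_energy(self):
        peaks = [run_macro_protons(e, 1000, 3).depth_dose.peak_depth_mm()
                 for e in (60.0, 80.0, 95.0)]
        assert peaks[0] < peaks[1] < peaks[2]


class TestSpectrumExtraction:
    def test_depth_zero_returns_source(self, kvp_macro):
        assert kvp_macro.spectrum_at(0.0) is kvp_macro.source_spectrum

    def test_unregistered_plane_raises(self, kvp_macro):
        with pytest.raises(KeyError):
            kvp_macro.spectrum_at(33.0)


class TestConvergence:
    def test_stderr_scales_as_inverse_root_n(self, kvp_spectrum):
        r1 = run_macro_photons(kvp_spectrum, 2000, 17)
        r2 = run_macro_photons(kvp_spectrum, 8000, 18)
        # compare total standard error over the first 100 bins
        s1 = np.sqrt(r1.depth_dose.variance_per_bin[:100].sum())
        s2 = np.sqrt(r2.depth_dose.variance_per_bin[:100].sum())
        assert s1 / s2 == pytest.approx(2.0, rel=0.2)
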