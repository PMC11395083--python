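"""Constants, materials, cross-sections and stopping powers."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from nanodose.physics_data import (
    CONSTANTS,
    THOMSON_CROSS_SECTION_BARN,
    Material,
    compton_cross_section,
    electron_csda_range,
    electron_stopping_power,
    get_material,
    klein_nishina_differential,
    incoherent_mu_over_rho,
    coherent_mu_over_rho,
    pair_mu_over_rho,
    photoelectric_mu_over_rho,
    proton_csda_range,
    proton_stopping_power,
    total_mu_over_rho,
)

WATER = get_material("water")
GOLD = get_material("gold")
TISSUE = get_material("soft_tissue")


class TestConstants:
    def test_all_positive(self):
        assert all(v > 0 for v in vars(CONSTANTS).values())

    def test_permittivity_close_to_quoted_value(self):
        # the worked potential example uses eps0 = 8.9e-12 F/m
        assert CONSTANTS.vacuum_permittivity_F_per_m == pytest.approx(
            8.9e-12, rel=0.01)


class TestMaterials:
    def test_registry_contents(self):
        assert WATER.density_g_cm3 == 1.0
        assert GOLD.density_g_cm3 == 19.32
        assert GOLD.mean_excitation_energy_eV == 790.0
        assert len(TISSUE.composition) == 4
        assert TISSUE.density_g_cm3 == pytest.approx(1.0, abs=0.1)

    @pytest.mark.parametrize("mat", [WATER, GOLD, TISSUE])
    def test_mass_fractions_sum_to_one(self, mat):
        assert sum(mat.composition.values()) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            Material("bad", 1.0, {"H": 0.3, "O": 0.3})


class TestKleinNishina:
    def test_low_energy_limit_is_thomson(self):
        assert compton_cross_section(0.1) == pytest.approx(
            THOMSON_CROSS_SECTION_BARN, rel=0.005)

    @pytest.mark.parametrize("energy", [1.0, 10.0, 100.0, 511.0, 1000.0, 1e4])
    def test_total_equals_angular_quadrature(self, energy):
        val, _ = quad(
            lambda ct: 2 * math.pi * klein_nishina_differential(energy, ct),
            -1.0, 1.0, limit=200)
        assert compton_cross_section(energy) == pytest.approx(val, rel=1e-4)

    def test_monotone_decreasing(self):
        energies = np.geomspace(2.0, 1e4, 50)
        vals = [compton_cross_section(e) for e in energies]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_energy(self):
        with pytest.raises(ValueError):
            compton_cross_section(-1.0)


class TestPhotoelectric:
    def test_gold_water_ratio_at_80keV(self):
        ratio = (photoelectric_mu_over_rho(GOLD, 80.0)
                 / photoelectric_mu_over_rho(WATER, 80.0))
        assert ratio > 100.0

    def test_gold_k_edge_step(self):
        assert (photoelectric_mu_over_rho(GOLD, 81.0)
                > photoelectric_mu_over_rho(GOLD, 80.0))

    @pytest.mark.parametrize("mat,e_lo,e_hi", [
        (WATER, 5.0, 150.0),
        (GOLD, 20.0, 70.0),
        (GOLD, 90.0, 200.0),
    ])
    def test_local_power_law_slope_between_edges(self, mat, e_lo, e_hi):
        grid = np.geomspace(e_lo, e_hi, 12)
        vals = np.array([photoelectric_mu_over_rho(mat, e) for e in grid])
        slopes = np.diff(np.log(vals)) / np.diff(np.log(grid))
        assert np.all(slopes > -3.5) and np.all(slopes < -2.5)

    def test_range_error_without_extrapolation(self):
        with pytest.raises(ValueError):
            photoelectric_mu_over_rho(WATER, 0.5)

    @pytest.mark.parametrize("w", [0.0, 0.5, 1.0])
    def test_mixture_rule_linear_in_mass_fraction(self, w):
        mix = Material("mix", 1.0, {"H": w, "O": 1.0 - w}) if w in (0.0, 1.0) \
            else Material("mix", 1.0, {"H": w, "O": 1.0 - w})
        e = 30.0
        expect = (w * photoelectric_mu_over_rho(Material("h", 1.0, {"H": 1.0}), e)
                  + (1 - w) * photoelectric_mu_over_rho(
                      Material("o", 1.0, {"O": 1.0}), e))
        assert photoelectric_mu_over_rho(mix, e) == pytest.approx(expect,
                                                                  rel=1e-12)

    def test_total_is_sum_of_components(self):
        for e in (20.0, 80.0, 511.0, 2000.0):
            total = total_mu_over_rho(WATER, e)
            parts = (photoelectric_mu_over_rho(WATER, e)
                     + incoherent_mu_over_rho(WATER, e)
                     + coherent_mu_over_rho(WATER, e)
                     + pair_mu_over_rho(WATER, e))
            assert total == pytest.approx(parts, rel=1e-12)
            assert parts >= 0


class TestProtonStopping:
    def test_bragg_consistent_csda_range_95MeV(self):
        # beam tuned so the depth-dose maximum sits at 7 cm
        assert proton_csda_range(TISSUE, 95.0) == pytest.approx(70.0, rel=0.05)

    def test_residual_range_45MeV(self):
        assert proton_csda_range(TISSUE, 45.0) == pytest.approx(20.0, rel=0.10)

    def test_stopping_increases_as_energy_decreases(self):
        assert (proton_stopping_power(WATER, 10.0)
                > proton_stopping_power(WATER, 95.0))

    def test_range_monotone_in_energy(self):
        energies = [5.0, 20.0, 60.0, 95.0, 150.0, 250.0]
        ranges = [proton_csda_range(WATER, e) for e in energies]
        assert np.all(np.diff(ranges) > 0)

    def test_window_errors(self):
        with pytest.raises(ValueError):
            proton_stopping_power(WATER, 0.1)
        with pytest.raises(ValueError):
            proton_stopping_power(WATER, 300.0)


class TestElectronStopping:
    def test_10keV_range_in_water_is_micrometers(self):
        r = electron_csda_range(WATER, 10.0)
        assert 1e3 < r < 5e3  # nm

    def test_range_monotone(self):
        assert electron_csda_range(WATER, 20.0) > electron_csda_range(WATER, 10.0)

    def test_gold_shorter_than_water(self):
        # at least the order of the density ratio
        assert (electron_csda_range(GOLD, 10.0)
                < electron_csda_range(WATER, 10.0) / 3.0)

    def test_below_cutoff_returns_zero(self):
        assert electron_csda_range(WATER, 0.00001) == 0.0

    def test_stopping_positive_down_to_cutoff(self):
        for e in (0.05e-3 * 1e3, 0.1, 1.0, 10.0, 100.0, 1000.0):
            assert electron_stopping_power(WATER, e) > 0
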