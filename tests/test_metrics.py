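"""Derived dosimetric metrics on analytic fixtures and small runs."""

import numpy as np
import pytest

from nanodose.dosimetry_metrics import (
    adr_from_runs,
    adr_lt_estimate,
    def_se_profile,
    enhancement_zone_radius,
    mean_np_spacing,
    surface_potential,
)
from nanodose.micro_transport import NanoparticleSpec, ShellTally, make_shell_grid
from nanodose.workflow import generate_fixture_tallies


class TestDEFProfile:
    def test_exponential_fixture_recovered(self):
        gnp, wnp = generate_fixture_tallies(shape="exponential",
                                            amplitude=9.0, length_nm=30.0)
        profile = def_se_profile(gnp, wnp)
        mids = profile.shell_mid_radii
        out = mids > 10.0
        expected = 1.0 + 9.0 * np.exp(-(mids[out] - 10.0) / 30.0)
        assert np.allclose(profile.def_se[out], expected, rtol=1e-6)

    def test_identity_for_identical_tallies(self):
        gnp, wnp = generate_fixture_tallies(shape="flat")
        profile = def_se_profile(gnp, wnp)
        out = profile.shell_mid_radii > profile.np_radius_nm
        assert np.allclose(profile.def_se[out], 1.0, atol=1e-12)

    def test_equal_dose_inside_np_gives_density_ratio(self):
        # equal absorbed dose in gold and water means the energy density
        # (hence the tallied shell energy) is higher by rho_Au/rho_w
        gnp, wnp = generate_fixture_tallies(shape="exponential")
        profile = def_se_profile(gnp, wnp)
        inside = profile.shell_mid_radii < profile.np_radius_nm
        assert np.allclose(profile.def_se[inside], 19.32, rtol=1e-9)
        assert np.allclose(profile.dose_ratio[inside], 1.0, rtol=1e-9)

    def test_mismatched_grids_rejected(self):
        gnp, _ = generate_fixture_tallies(np_diameter_nm=20.0)
        _, wnp = generate_fixture_tallies(np_diameter_nm=40.0)
        with pytest.raises(ValueError):
            def_se_profile(gnp, wnp)

    def test_zero_baseline_flagged_nan(self):
        gnp, wnp = generate_fixture_tallies(shape="flat")
        wnp.energy_per_shell[50] = 0.0
        profile = def_se_profile(gnp, wnp)
        assert np.isnan(profile.def_se[50])


class TestEnhancementZone:
    def test_flat_profile_zone_is_np_radius(self):
        gnp, wnp = generate_fixture_tallies(shape="flat", np_diameter_nm=20.0)
        assert enhancement_zone_radius(def_se_profile(gnp, wnp)) == 10.0

    def test_step_profile_zone_is_step_radius(self):
        gnp, wnp = generate_fixture_tallies(shape="step", step_radius_nm=100.0)
        assert enhancement_zone_radius(def_se_profile(gnp, wnp)) == 100.0

    def test_exponential_zone_matches_closed_form(self):
        amplitude, lam = 9.0, 30.0
        gnp, wnp = generate_fixture_tallies(shape="exponential",
                                            amplitude=amplitude, length_nm=lam)
        zone = enhancement_zone_radius(def_se_profile(gnp, wnp),
                                       rel_threshold=0.05)
        # DEF - 1 falls below 0.05 at R + lam*ln(A/0.05)
        analytic = 10.0 + lam * np.log(amplitude / 0.05)
        assert zone == pytest.approx(analytic, abs=10.0)

    def test_never_settling_returns_max_radius(self):
        gnp, wnp = generate_fixture_tallies(shape="exponential",
                                            amplitude=50.0, length_nm=5000.0)
        profile = def_se_profile(gnp, wnp)
        zone = enhancement_zone_radius(profile, rel_threshold=0.001)
        assert zone == profile.shell_edges[-1]


class TestADR:
    def test_null_enhancement(self):
        assert adr_from_runs(1.0, 1.0) == 0.0

    def test_small_enhancement_arithmetic(self):
        assert adr_from_runs(1.0001, 1.0) == pytest.approx(1e-4, rel=1e-9)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            adr_from_runs(1.0, 0.0)

    @pytest.fixture(scope="class")
    def fixture_adr_inputs(self):
        gnp, wnp = generate_fixture_tallies(shape="exponential")
        spec = NanoparticleSpec(20.0, "gold")
        return spec, gnp, wnp

    def test_linearity_in_concentration(self, fixture_adr_inputs):
        spec, gnp, wnp = fixture_adr_inputs
        a1 = adr_lt_estimate(spec, 10.0, gnp, wnp, wnp)
        a2 = adr_lt_estimate(spec, 20.0, gnp, wnp, wnp)
        assert a2.adr_lt / a1.adr_lt == pytest.approx(2.0, rel=1e-9)
        assert a2.adr / a1.adr == pytest.approx(2.0, rel=1e-9)

    def test_lt_never_exceeds_total(self, fixture_adr_inputs):
        spec, gnp, wnp = fixture_adr_inputs
        res = adr_lt_estimate(spec, 10.0, gnp, wnp, wnp)
        assert res.adr_lt <= res.adr
        assert 0.0 <= res.lt_fraction <= 1.0

    def test_invalid_concentration(self, fixture_adr_inputs):
        spec, gnp, wnp = fixture_adr_inputs
        with pytest.raises(ValueError):
            adr_lt_estimate(spec, -1.0, gnp, wnp, wnp)


class TestSpacing:
    def test_paper_sizes_at_10mg_per_L(self):
        # one-significant-figure agreement: 1, 2, 4, 8 micrometers
        for d, expect in ((10.0, 1.0), (20.0, 2.0), (40.0, 4.0), (80.0, 8.0)):
            spacing = mean_np_spacing(10.0, d)
            assert round(spacing, 0) == expect or abs(spacing - expect) / expect < 0.05

    def test_linear_in_diameter(self):
        s1 = mean_np_spacing(10.0, 10.0)
        s4 = mean_np_spacing(10.0, 40.0)
        assert s4 / s1 == pytest.approx(4.0, rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mean_np_spacing(-1.0, 10.0)
        with pytest.raises(ValueError):
            mean_np_spacing(10.0, 0.0)


class TestSurfacePotential:
    def test_single_charge_at_20nm(self):
        # the printed worked example gives ~75 mV with a rounded
        # permittivity; CODATA epsilon_0 yields 72 mV
        assert surface_potential(1.0, 20.0) == pytest.approx(75.0, rel=0.10)

    def test_zero_charge(self):
        assert surface_potential(0.0, 20.0) == 0.0

    def test_inverse_distance_law(self):
        assert surface_potential(1.0, 40.0) == pytest.approx(
            surface_potential(1.0, 20.0) / 2.0, rel=1e-12)

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            surface_potential(1.0, 0.0)
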