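"""Unit tests for the closed-form pump-physics calculators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import jv

from liebauflow import physics
from liebauflow.physics import (
    CompressionProtocol,
    FluidProperties,
    TensileTest,
    TubeGeometry,
    compression_frequency,
    glycerin_water_viscosity,
    kw_correction,
    moens_korteweg_speed,
    natural_frequency,
    pa_s_to_cp,
    peristaltic_flowrate,
    poiseuille_resistance_scaling,
    womersley_number,
    womersley_profile,
    m3_s_to_ul_s,
)

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestYoungModulus:
    def test_unit_stress_unit_strain(self):
        # dL = L and m g = 1 N on a 1 m^2 strip: E = stress/strain = 1 Pa
        t = TensileTest(attached_mass=1 / 9.81, strip_length=0.1,
                        cross_section_area=1.0, elongation=0.1)
        assert physics.young_modulus(t) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        t = TensileTest(attached_mass=0.010, strip_length=0.05,
                        cross_section_area=1e-5, elongation=0.005)
        assert physics.young_modulus(t) == pytest.approx(98100.0)

    def test_linear_in_mass(self):
        t1 = TensileTest(0.010, 0.05, 1e-5, 0.005)
        t2 = TensileTest(0.020, 0.05, 1e-5, 0.005)
        assert physics.young_modulus(t2) == pytest.approx(2 * physics.young_modulus(t1))

    @pytest.mark.parametrize("bad", ["attached_mass", "strip_length",
                                     "cross_section_area", "elongation"])
    def test_nonpositive_field_named_in_error(self, bad):
        kwargs = dict(attached_mass=0.01, strip_length=0.05,
                      cross_section_area=1e-5, elongation=0.005)
        kwargs[bad] = 0.0
        with pytest.raises(ValueError, match=bad):
            TensileTest(**kwargs)

    def test_beyond_linear_regime_rejected(self):
        with pytest.raises(ValueError, match="strain"):
            TensileTest(0.01, 0.05, 1e-5, elongation=0.06)


class TestCompressionFrequency:
    @pytest.mark.parametrize(
        "on,off",
        [(0.2, 1.8), (0.2, 0.2), (0.2, 0.3), (0.2, 0.8), (0.5, 0.5)],
    )
    def test_protocol_grid(self, on, off):
        assert compression_frequency(on, off) == pytest.approx(1.0 / (on + off))
        assert CompressionProtocol(on, off).frequency == pytest.approx(1.0 / (on + off))

    def test_experimental_grid_endpoints(self):
        assert compression_frequency(0.2, 1.8) == pytest.approx(0.5)
        assert compression_frequency(0.2, 0.2) == pytest.approx(2.5)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            compression_frequency(0.0, 0.5)

    def test_from_frequency_roundtrip(self):
        p = CompressionProtocol.from_frequency(1.5, time_on=0.2)
        assert p.time_off == pytest.approx(1 / 1.5 - 0.2)
        assert p.frequency == pytest.approx(1.5)


class TestWomersleyNumber:
    def test_direct_formula(self, water):
        geom = TubeGeometry(0.038, 5e-3, 0.5e-3)
        fluid = FluidProperties(1000.0, 2.26e-3)
        protocol = CompressionProtocol(0.2, 1.8)
        # independent evaluation: r * sqrt(rho * 2 pi F / mu)
        expected = 2.5e-3 * math.sqrt(1000.0 * 2 * math.pi * 0.5 / 2.26e-3)
        wo = womersley_number(geom, fluid, protocol)
        assert wo == pytest.approx(expected)
        assert wo == pytest.approx(2.95, abs=0.01)

    def test_viscosity_sqrt_scaling(self, water, tygon, protocol_25hz):
        thick = FluidProperties(water.density, 4 * water.dynamic_viscosity)
        assert womersley_number(tygon, thick, protocol_25hz) == pytest.approx(
            womersley_number(tygon, water, protocol_25hz) / 2
        )

    def test_experimental_grid_mostly_2_to_8(self):
        values = []
        for r_mm in (1.5, 2.5, 4.0):
            for f_hz in (0.5, 1.0, 1.5, 2.0, 2.5):
                for mu_cp in (0.95, 1.31, 2.26):
                    geom = TubeGeometry(0.038, 2 * r_mm * 1e-3, 0.5e-3)
                    fluid = FluidProperties(1000.0, mu_cp * 1e-3)
                    protocol = CompressionProtocol.from_frequency(f_hz)
                    values.append(womersley_number(geom, fluid, protocol))
        in_range = np.mean([(2.0 <= v <= 8.0) for v in values])
        assert in_range > 0.5


class TestWomersleyProfile:
    @pytest.mark.parametrize("wo", [0.0, 0.5, 3.0, 10.0, 50.0])
    def test_no_slip_and_centerline_normalization(self, wo):
        u = womersley_profile(wo, [0.0, 1.0])
        assert u[0] == pytest.approx(1.0)
        assert u[1] == pytest.approx(0.0, abs=1e-12)

    def test_poiseuille_limit(self):
        xi = np.linspace(0, 1, 101)
        assert np.max(np.abs(womersley_profile(0.1, xi) - (1 - xi**2))) < 1e-2

    def test_intermediate_regime_flatter_than_parabola(self):
        u = womersley_profile(10.0, [0.5])[0]
        assert u > 0.75
        assert abs(1 - u) < abs(1 - 0.75)

    def test_high_wo_flatness_near_wall(self):
        assert womersley_profile(50.0, [0.9])[0] > 0.5

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            womersley_profile(5.0, [1.2])
        with pytest.raises(ValueError):
            womersley_profile(-1.0, [0.5])


class TestKwCorrection:
    def test_poiseuille_limit_is_half(self):
        for wo in (0.0, 0.05, 0.1):
            assert kw_correction(wo) == pytest.approx(0.5, abs=1e-3)

    def test_flat_profile_limit_approaches_one(self):
        assert kw_correction(200.0) > 0.97

    def test_against_fine_grid_quadrature_oracle(self):
        # independent oracle: trapezoid rule at 10x node density on a
        # direct Bessel-function evaluation of the oscillatory profile
        wo = 5.0
        xi = np.linspace(0.0, 1.0, 5121)
        arg = 1j**1.5 * wo
        u = np.abs(1 - jv(0, arg * xi) / jv(0, arg))
        u /= np.abs(1 - 1 / jv(0, arg))
        oracle = np.trapezoid(2 * u * xi, xi)
        assert kw_correction(wo) == pytest.approx(oracle, abs=1e-3)

    def test_monotone_and_bounded_on_grid(self):
        grid = [0.1, 0.5, 1, 2, 5, 10, 20, 50]
        values = [kw_correction(w) for w in grid]
        assert all(0.5 <= v <= 1.0 for v in values)
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_negative_wo_rejected(self):
        with pytest.raises(ValueError):
            kw_correction(-0.1)


class TestWaveAndReference:
    def test_moens_korteweg_worked_example(self):
        geom = TubeGeometry(0.038, 5e-3, 0.4e-3)
        fluid = FluidProperties(1000.0, 1e-3)
        c = moens_korteweg_speed(47e3, geom, fluid)
        assert c == pytest.approx(1.939, abs=0.01)
        assert c == pytest.approx(2.0, rel=0.05)

    def test_moens_korteweg_thicker_wall(self):
        geom = TubeGeometry(0.038, 5e-3, 0.5e-3)
        c = moens_korteweg_speed(47e3, geom, FluidProperties(1000.0, 1e-3))
        assert c == pytest.approx(math.sqrt(47e3 * 0.5e-3 / 5.0), rel=1e-12)
        assert c == pytest.approx(2.17, abs=0.01)

    def test_natural_frequency_worked_example(self):
        geom = TubeGeometry(0.038, 5e-3, 0.4e-3)
        c = moens_korteweg_speed(47e3, geom, FluidProperties(1000.0, 1e-3))
        assert natural_frequency(c, geom) == pytest.approx(25.0, rel=0.1)

    def test_natural_frequency_stiff_tube(self):
        geom = TubeGeometry(0.038, 5e-3, 0.4e-3)
        assert natural_frequency(60.0, geom) == pytest.approx(60 / 0.076, rel=1e-12)
        assert natural_frequency(60.0, geom) == pytest.approx(789.5, abs=1.0)

    def test_peristaltic_reference_values(self):
        geom5 = TubeGeometry(0.038, 5e-3, 0.5e-3)
        protocol = CompressionProtocol(0.2, 0.2, pincher_length=3.5e-3)
        q = m3_s_to_ul_s(peristaltic_flowrate(protocol, geom5))
        assert q == pytest.approx(172.0, abs=0.5)
        geom3 = TubeGeometry(0.038, 3e-3, 0.5e-3)
        q3 = m3_s_to_ul_s(
            peristaltic_flowrate(None, geom3, frequency=1.0, pincher_length=3.5e-3)
        )
        assert q3 == pytest.approx(24.7, abs=0.1)
        assert peristaltic_flowrate(None, geom3, frequency=0.0, pincher_length=3.5e-3) == 0.0


class TestGlycerinWaterViscosity:
    PUBLISHED_TABLE = {0.00: 0.95, 0.05: 1.10, 0.10: 1.31,
                   0.15: 1.56, 0.20: 1.87, 0.25: 2.26}

    @pytest.mark.parametrize("fraction,expected_cp", sorted(PUBLISHED_TABLE.items()))
    def test_matches_tabulated_values_within_2pct(self, fraction, expected_cp):
        mu = pa_s_to_cp(glycerin_water_viscosity(fraction, 22.0))
        assert mu == pytest.approx(expected_cp, rel=0.02)

    def test_monotone_in_concentration(self):
        assert glycerin_water_viscosity(0.10, 22.0) < glycerin_water_viscosity(0.20, 22.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            glycerin_water_viscosity(1.2, 22.0)
        with pytest.raises(ValueError):
            glycerin_water_viscosity(0.2, 150.0)


class TestPoiseuilleScaling:
    def test_ratios(self, tygon):
        thin = FluidProperties(1000.0, 0.95e-3)
        thick = FluidProperties(1000.0, 2.26e-3)
        ratio = poiseuille_resistance_scaling(thick, tygon) / poiseuille_resistance_scaling(
            thin, tygon
        )
        assert ratio == pytest.approx(2.26 / 0.95, rel=1e-12)
        assert ratio == pytest.approx(2.38, abs=0.01)

    def test_radius_fourth_power(self):
        fluid = FluidProperties(1000.0, 1e-3)
        big = TubeGeometry(0.038, 4e-3, 0.5e-3)
        small = TubeGeometry(0.038, 2e-3, 0.5e-3)
        assert poiseuille_resistance_scaling(fluid, small) == pytest.approx(
            16 * poiseuille_resistance_scaling(fluid, big)
        )


class TestPowerLawScaling:
    """Each calculator obeys exact power-law scaling in every argument."""

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=positive)
    def test_womersley_number(self, scale):
        geom = TubeGeometry(0.038, 3e-3, 0.5e-3)
        geom2 = TubeGeometry(0.038, 3e-3 * scale, 0.5e-3)
        fluid = FluidProperties(1000.0, 1e-3)
        fluid2 = FluidProperties(1000.0 * scale, 1e-3 * scale)
        protocol = CompressionProtocol(0.2, 0.3)
        base = womersley_number(geom, fluid, protocol)
        assert womersley_number(geom2, fluid, protocol) == pytest.approx(scale * base)
        # rho and mu scaled together cancel
        assert womersley_number(geom, fluid2, protocol) == pytest.approx(base)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=positive)
    def test_moens_korteweg(self, scale):
        geom = TubeGeometry(0.038, 5e-3, 0.4e-3)
        fluid = FluidProperties(1000.0, 1e-3)
        base = moens_korteweg_speed(47e3, geom, fluid)
        assert moens_korteweg_speed(47e3 * scale, geom, fluid) == pytest.approx(
            math.sqrt(scale) * base
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=positive)
    def test_natural_frequency(self, scale):
        geom = TubeGeometry(0.038, 5e-3, 0.4e-3)
        geom2 = TubeGeometry(0.038 * scale, 5e-3, 0.4e-3)
        assert natural_frequency(2.0, geom2) == pytest.approx(
            natural_frequency(2.0, geom) / scale
        )

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(scale=positive)
    def test_peristaltic_flowrate(self, scale):
        geom = TubeGeometry(0.038, 5e-3, 0.5e-3)
        geom2 = TubeGeometry(0.038, 5e-3 * scale, 0.5e-3)
        protocol = CompressionProtocol(0.2, 0.2)
        assert peristaltic_flowrate(protocol, geom2) == pytest.approx(
            scale**2 * peristaltic_flowrate(protocol, geom)
        )
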