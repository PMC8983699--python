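"""Closed-form RSA mathematics: blocking functions, geometry, kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsacap import (
    ParticleSpec,
    RSAKinetics,
    blocking_function,
    blocking_function_near_jamming,
    d_rsa_from_area,
    effective_area,
    integrate_rsa_kinetics,
    max_packing_count,
    particle_mass,
    surface_coverage,
)
from rsacap.rsa_model import THETA_INF, regime_crossover


class TestBlockingFunction:
    @pytest.mark.parametrize("theta, expected", [
        (0.0, 1.0),
        # direct evaluation of the cubic with 6√3/π and 40/(π√3) − 176/(3π²)
        (0.1, 1 - 0.4 + (6 * math.sqrt(3) / math.pi) * 0.01
         + (40 / (math.pi * math.sqrt(3)) - 176 / (3 * math.pi**2)) * 1e-3),
        (0.547, 1 - 4 * 0.547 + (6 * math.sqrt(3) / math.pi) * 0.547**2
         + (40 / (math.pi * math.sqrt(3)) - 176 / (3 * math.pi**2))
         * 0.547**3),
    ])
    def test_cubic_values(self, theta, expected):
        assert blocking_function(theta) == pytest.approx(expected, rel=1e-12)

    def test_frozen_reference_points(self):
        # independently evaluated cubic: B(0.1) and the nonzero residue at
        # the jamming coverage (why the asymptote replaces the cubic there)
        assert blocking_function(0.1) == pytest.approx(0.63449, abs=1e-5)
        assert blocking_function(0.547) == pytest.approx(0.0320, abs=5e-4)

    def test_rejects_out_of_domain(self):
        with pytest.raises(ValueError):
            blocking_function(-0.01)
        with pytest.raises(ValueError):
            blocking_function(0.6)

    def test_strictly_decreasing_below_validity_limit(self):
        theta = np.linspace(0, 0.3, 301)
        b = blocking_function(theta)
        assert b[0] == 1.0
        assert np.all(np.diff(b) < 0)


class TestNearJamming:
    def test_vanishes_exactly_at_jamming(self):
        assert blocking_function_near_jamming(THETA_INF) == 0.0

    def test_cube_law(self):
        assert blocking_function_near_jamming(0.447) == pytest.approx(
            8.98e-3, rel=1e-9)

    def test_rejects_beyond_jamming(self):
        with pytest.raises(ValueError):
            blocking_function_near_jamming(0.6)

    @given(st.floats(min_value=0.0, max_value=THETA_INF - 1e-9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_positive_below_jamming(self, theta):
        assert blocking_function_near_jamming(theta) > 0


class TestSurfaceCoverage:
    def test_table_row_solid_liquid(self):
        with pytest.warns(UserWarning):
            theta = surface_coverage(419.0, 6.0e4, 5.26e-7)
        assert theta == pytest.approx(0.478, abs=2e-3)

    def test_zero_mass_zero_coverage(self):
        assert surface_coverage(0.0, 1e4, 5.26e-7) == 0.0

    def test_validity_warning_above_030(self):
        with pytest.warns(UserWarning, match="0.3"):
            theta = surface_coverage(1890.0, 1.0e4, 5.26e-7)
        assert theta == pytest.approx(0.359, abs=2e-3)

    def test_linearity(self):
        base = surface_coverage(10.0, 1e4, 5.26e-7)
        assert surface_coverage(30.0, 1e4, 5.26e-7) == pytest.approx(
            3 * base)
        assert surface_coverage(10.0, 3e4, 5.26e-7) == pytest.approx(
            3 * base)
        assert surface_coverage(10.0, 1e4, 3 * 5.26e-7) == pytest.approx(
            base / 3)

    def test_rejects_nonpositive_geometry(self):
        with pytest.raises(ValueError):
            surface_coverage(1.0, 0.0, 1e-7)
        with pytest.raises(ValueError):
            surface_coverage(1.0, 1e4, 0.0)


class TestParticleGeometry:
    @pytest.mark.parametrize("d, rho, expected", [
        (100.0, 1.05, 5.49e-7),    # polystyrene sphere, supplier density
        (1000.0, 1.05, 5.50e-4),
        (100.0, 1.005, 5.26e-7),   # image-analysis mass value
    ])
    def test_sphere_mass(self, d, rho, expected):
        m = particle_mass(ParticleSpec(diameter_abs=d, density=rho))
        assert m == pytest.approx(expected, rel=2e-3)

    def test_mass_scales_with_diameter_cubed(self):
        masses = [particle_mass(ParticleSpec(d, 1.05))
                  for d in (50.0, 100.0, 200.0)]
        assert masses[1] / masses[0] == pytest.approx(8.0)
        assert masses[2] / masses[1] == pytest.approx(8.0)

    def test_effective_area(self):
        spec = ParticleSpec(100.0, 1.05, eff_factor=1.1)
        assert spec.diameter_eff == pytest.approx(110.0)
        assert effective_area(spec) == pytest.approx(math.pi * 55**2)
        tiny = ParticleSpec(2.0, 1.0, eff_factor=1.0)
        assert effective_area(tiny) == pytest.approx(math.pi)

    def test_packing_count_one_mm2(self):
        spec = ParticleSpec(100.0, 1.05, eff_factor=1.1)
        n = max_packing_count(1.0, spec, theta_inf=0.547)
        assert n == pytest.approx(5.76e7, rel=5e-3)

    def test_packing_count_degenerate_and_scaling(self):
        spec = ParticleSpec(100.0, 1.05, eff_factor=1.1)
        area_mm2 = effective_area(spec) * 1e-12
        assert max_packing_count(area_mm2, spec, theta_inf=1.0) == \
            pytest.approx(1.0)
        n1 = max_packing_count(1.0, spec)
        assert max_packing_count(1e-6, spec) == pytest.approx(n1 * 1e-6)
        for alpha in (0.5, 2.0, 7.3):
            assert max_packing_count(alpha, spec) == pytest.approx(
                alpha * n1)

    @pytest.mark.parametrize("a, expected, tol", [
        (6.0e4, 276.4, 0.1),
        (1.0e4, 112.8, 0.1),
        (math.pi * 50**2, 100.0, 1e-9),
    ])
    def test_d_rsa(self, a, expected, tol):
        assert d_rsa_from_area(a) == pytest.approx(expected, abs=tol)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            ParticleSpec(-1.0, 1.0)
        with pytest.raises(ValueError):
            ParticleSpec(100.0, 0.0)
        with pytest.raises(ValueError):
            ParticleSpec(100.0, 1.0, eff_factor=0.9)


class TestKineticsIntegration:
    def test_initial_rate_is_ka_c(self, table1_kinetics):
        t = np.array([0.0, 1e-4, 2e-4])
        g = integrate_rsa_kinetics(table1_kinetics, t)
        rate = (g[1] - g[0]) / 1e-4
        assert rate == pytest.approx(table1_kinetics.ka_c, rel=1e-4)
        assert table1_kinetics.ka_c == pytest.approx(1.0)

    def test_monotone_and_bounded(self, reference_trace, table1_kinetics):
        _, g = reference_trace
        assert np.all(np.diff(g) >= 0)
        assert g[-1] <= table1_kinetics.gamma_jam + 1e-9

    def test_long_time_limit_near_jamming_regime(self):
        params = RSAKinetics(k_a=1e-5, a_nm2=6.0e4, m=5.26e-7, c=1.0e5,
                             regime="near_jamming")
        # the fixed point is approached algebraically (~t^-1/2), so reach
        # far into the tail on a log-spaced grid
        t = np.concatenate([[0.0], np.logspace(0, 9, 40)])
        g = integrate_rsa_kinetics(params, t)
        assert np.all(np.diff(g) >= 0)
        assert g[-1] == pytest.approx(params.gamma_jam, rel=1e-3)

    def test_tolerance_invariance(self, table1_kinetics):
        t = np.arange(0.0, 3601.0, 30.0)
        g1 = integrate_rsa_kinetics(table1_kinetics, t)
        g2 = integrate_rsa_kinetics(table1_kinetics, t,
                                    rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(g2 - g1) / np.maximum(g1, 1e-12)) < 1e-3

    def test_rejects_bad_time_grid(self, table1_kinetics):
        with pytest.raises(ValueError):
            integrate_rsa_kinetics(table1_kinetics, [1.0, 2.0])
        with pytest.raises(ValueError):
            integrate_rsa_kinetics(table1_kinetics, [0.0, 2.0, 1.0])

    def test_regime_crossover_location_and_continuity(self):
        theta_x = regime_crossover()
        assert 0.3 < theta_x < THETA_INF
        left = blocking_function(theta_x)
        right = blocking_function_near_jamming(theta_x)
        assert left == pytest.approx(right, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RSAKinetics(k_a=-1.0, a_nm2=1e4, m=1e-7, c=1e5)
        with pytest.raises(ValueError):
            RSAKinetics(k_a=1e-5, a_nm2=1e4, m=1e-7, c=1e5, theta_inf=1.5)
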