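"""Mosaic-crystal physics: Bragg angle, mosaic distribution, kinematical Q,
two-beam reflectivity, crystallite sampling."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from mosaicfocus.mosaic_crystal import (
    MosaicCrystalSpec,
    bragg_angle,
    bragg_angle_rad,
    get_preset,
    graphite_diffraction_constants,
    kinematical_Q,
    mosaic_pdf,
    peak_reflectivity_theoretical,
    sample_crystallite_normal,
    sample_crystallite_tilts,
    scattering_coefficient,
)


class TestBraggAngle:
    def test_published_angles(self, m012):
        assert bragg_angle(59.0, m012) == pytest.approx(1.79, abs=0.01)
        assert bragg_angle(8.03, m012) == pytest.approx(13.29, abs=0.05)

    def test_monotone_to_zero(self, m012):
        e = np.linspace(10, 500, 100)
        th = bragg_angle(e, m012)
        assert np.all(np.diff(th) < 0)
        assert th[-1] < 0.25

    def test_no_reflection_below_cutoff(self, m012):
        with pytest.raises(ValueError):
            bragg_angle(1.0, m012)  # n*lambda/2d > 1


class TestMosaicPdf:
    def test_peak_value_closed_form(self):
        m = math.radians(0.12)
        assert mosaic_pdf(0.0, m) == pytest.approx(2.0 / (math.pi * m))
        assert mosaic_pdf(0.0, m) == pytest.approx(303.96, rel=1e-3)

    def test_fwhm_property(self):
        m = math.radians(0.3)
        assert mosaic_pdf(m / 2, m) == pytest.approx(mosaic_pdf(0.0, m) / 2)
        assert mosaic_pdf(-m / 2, m) == pytest.approx(mosaic_pdf(0.0, m) / 2)

    def test_normalization(self):
        m = math.radians(0.12)
        val, _ = quad(lambda x: mosaic_pdf(x, m), -np.inf, np.inf)
        assert val == pytest.approx(1.0, rel=1e-8)


class TestKinematicalQ:
    def test_independent_formula_oracle(self, m012):
        """Direct arithmetic evaluation of Q with its own inputs."""
        consts = graphite_diffraction_constants(m012)
        lam = 12.398419 / 59.0
        d = 3.354
        tb = math.asin(lam / (2 * d))
        re_a = 2.8179403e-5
        prefac = (re_a * consts.structure_factor / (consts.cell_volume_nm3 * 1e3)) ** 2
        pol = 0.5 * (1 + math.cos(2 * tb) ** 2)
        expect = prefac * lam**3 / math.sin(2 * tb) * pol * 1e8
        assert kinematical_Q(59.0, m012) == pytest.approx(expect, rel=1e-9)
        # magnitude sanity from a hand evaluation of the same expression
        assert kinematical_Q(59.0, m012) == pytest.approx(2.84e-3, rel=0.02)

    def test_positive_and_finite(self, m012):
        q = kinematical_Q(np.linspace(5, 150, 50), m012)
        assert np.all(q > 0) and np.all(np.isfinite(q))


class TestScatteringCoefficient:
    def test_lorentzian_ratio(self, m012):
        m = m012.mosaic_fwhm_rad
        th0 = math.pi / 2 - bragg_angle_rad(59.0, m012)
        s0 = scattering_coefficient(0.0, 59.0, th0, m012)
        for k in (0.5, 1.0, 3.0):
            ratio = scattering_coefficient(k * m, 59.0, th0, m012) / s0
            assert ratio == pytest.approx(1 / (1 + (2 * k) ** 2), rel=1e-9)

    def test_one_percent_point(self, m012):
        # sigma falls to 1% of peak at |delta| = 9.95 m/2 = 4.97 m
        m = m012.mosaic_fwhm_rad
        th0 = math.pi / 2 - bragg_angle_rad(59.0, m012)
        ratio = scattering_coefficient(4.97 * m, 59.0, th0, m012) \
            / scattering_coefficient(0.0, 59.0, th0, m012)
        assert ratio == pytest.approx(0.01, rel=0.02)

    def test_grazing_geometry_error(self, m012):
        with pytest.raises(ValueError):
            scattering_coefficient(0.0, 59.0, math.pi, m012)


class TestPeakReflectivity:
    def test_published_values(self, m012):
        assert 100 * peak_reflectivity_theoretical(m012, 59.0) == \
            pytest.approx(16.5, rel=0.10)
        assert 100 * peak_reflectivity_theoretical(m012, 8.03) == \
            pytest.approx(46.5, rel=0.10)

    def test_zero_thickness_limit(self):
        thin = MosaicCrystalSpec(mosaic_fwhm_deg=0.12, thickness_um=1e-3)
        assert peak_reflectivity_theoretical(thin, 59.0) < 1e-4

    def test_monotone_in_thickness_and_mosaic(self):
        r_by_T = [
            peak_reflectivity_theoretical(
                MosaicCrystalSpec(0.12, t), 59.0) for t in (20, 80, 200, 1000)
        ]
        assert np.all(np.diff(r_by_T) > 0)
        r_by_m = [
            peak_reflectivity_theoretical(
                MosaicCrystalSpec(m, 80.0), 59.0) for m in (0.12, 0.24, 0.46)
        ]
        assert np.all(np.diff(r_by_m) < 0)
        assert all(0 < r < 1 for r in r_by_T + r_by_m)

    def test_thick_crystal_limit(self, m012):
        """b_p -> inf: r -> a_p/(1 + a_p + sqrt(1+2 a_p))."""
        from mosaicfocus.xray_data import get_material, mass_attenuation
        thick = MosaicCrystalSpec(0.12, 10e4 * 10)  # 10 cm
        r = peak_reflectivity_theoretical(thick, 59.0)
        graphite = get_material("graphite")
        mu = mass_attenuation(graphite, 59.0, "total") * graphite.density
        a_p = mosaic_pdf(0.0, thick.mosaic_fwhm_rad) * kinematical_Q(59.0, thick) / mu
        expect = a_p / (1 + a_p + math.sqrt(1 + 2 * a_p))
        assert r == pytest.approx(expect, rel=1e-9)


class TestCrystalliteSampling:
    def test_unit_norm_and_degenerate_limit(self, rng):
        n = sample_crystallite_normal(1e-20, [0, 0, 1.0], rng, size=100)
        assert np.allclose(n, [0, 0, 1.0])
        n = sample_crystallite_normal(math.radians(0.46), [0, 1.0, 0], rng, size=1000)
        assert np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-12)

    def test_empirical_tilt_fwhm(self, rng):
        m = math.radians(0.12)
        t = sample_crystallite_tilts(m, 1_000_000, rng)
        h, edges = np.histogram(t, bins=400, range=(-5 * m, 5 * m))
        c = 0.5 * (edges[:-1] + edges[1:])
        above = c[h >= h.max() / 2]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(m, rel=0.05)

    def test_truncation_bound(self, rng):
        m = math.radians(0.24)
        t = sample_crystallite_tilts(m, 200_000, rng)
        assert np.all(np.abs(t) <= 5 * m * 1.0000001)
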