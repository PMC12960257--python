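"""Collapsed-projection morphometry: ellipse fits, 3D reconstruction,
distribution statistics and composition estimates."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from skimage import draw

from dipid.morphometry import (Micrograph, MorphometryRecord, collapse_to_3d,
                               distribution_stats, estimate_composition,
                               fit_ellipse, ramanujan_perimeter,
                               segment_containers, tube_diameter,
                               _prolate_surface_area)
from dipid.synth import exact_ellipse_perimeter


class TestRamanujan:
    @pytest.mark.parametrize("aspect", [1.0, 1.5, 2.0, 3.0, 4.0])
    def test_against_elliptic_integral(self, aspect):
        b = 100.0
        a = aspect * b
        assert ramanujan_perimeter(a, b) == \
            pytest.approx(exact_ellipse_perimeter(a, b), rel=1e-3)

    def test_circle_exact(self):
        assert ramanujan_perimeter(50.0, 50.0) == pytest.approx(2 * math.pi * 50)


class TestCollapse:
    def test_collapsed_sphere(self):
        rec = MorphometryRecord(0, math.pi * 50, math.pi * 50, 0.0)
        rec = collapse_to_3d(rec)
        assert rec.d_minor == pytest.approx(200.0)
        assert rec.d_major == pytest.approx(200.0, rel=1e-6)
        assert rec.aspect_ratio == pytest.approx(1.0, rel=1e-6)

    def test_minor_axis_inversion(self):
        rec = collapse_to_3d(MorphometryRecord(0, 78.54, 78.54, 0.0))
        assert rec.d_minor == pytest.approx(100.0, rel=1e-3)

    @pytest.mark.parametrize("d_major,d_minor", [
        (400.0, 200.0), (100.0, 100.0), (1500.0, 900.0), (600.0, 150.0)])
    def test_forward_backward_round_trip(self, d_major, d_minor):
        """Flattening a known spheroid and reconstructing recovers the
        diameters to 0.1% (forward model uses the exact perimeter)."""
        r_minor_2d = math.pi * d_minor / 4.0
        r_major_2d = exact_ellipse_perimeter(d_major / 2, d_minor / 2) / 4.0
        rec = collapse_to_3d(MorphometryRecord(0, r_minor_2d, r_major_2d, 0.0))
        assert rec.d_minor == pytest.approx(d_minor, rel=1e-3)
        assert rec.d_major == pytest.approx(d_major, rel=1e-3)

    def test_inconsistent_axes_flagged(self):
        rec = collapse_to_3d(MorphometryRecord(0, 100.0, 50.0, 0.0))
        assert "inconsistent_axes" in rec.flags
        assert rec.d_major == rec.d_minor


class TestTube:
    def test_half_circumference(self):
        assert tube_diameter(math.pi * 50) == pytest.approx(100.0)

    def test_linear(self):
        assert tube_diameter(200.0) == pytest.approx(2 * tube_diameter(100.0))

    def test_positive_required(self):
        with pytest.raises(ValueError):
            tube_diameter(0.0)


class TestEllipseFit:
    def test_rendered_circle(self):
        img = np.zeros((300, 300), dtype=bool)
        rr, cc = draw.disk((150, 150), 100)
        img[rr, cc] = True
        rec = fit_ellipse(img)
        assert rec.r_minor_2d == pytest.approx(100, abs=1.0)
        assert rec.r_major_2d == pytest.approx(100, abs=1.0)

    def test_rendered_two_to_one_ellipse(self):
        img = np.zeros((300, 500), dtype=bool)
        rr, cc = draw.ellipse(150, 250, 80, 160, rotation=0.4)
        img[rr, cc] = True
        rec = fit_ellipse(img)
        assert rec.r_major_2d / rec.r_minor_2d == pytest.approx(2.0, rel=0.02)

    def test_perimeter_against_quadrature(self):
        img = np.zeros((300, 500), dtype=bool)
        rr, cc = draw.ellipse(150, 250, 90, 150)
        img[rr, cc] = True
        rec = fit_ellipse(img)
        a, b = rec.r_major_2d, rec.r_minor_2d

        def arc(t):
            return math.hypot(a * math.sin(t), b * math.cos(t))

        quad_perim, _ = quad(arc, 0, 2 * math.pi, limit=200)
        assert rec.perimeter_2d == pytest.approx(quad_perim, rel=1e-3)

    def test_small_region_rejected(self):
        img = np.zeros((50, 50), dtype=bool)
        img[10:13, 10:13] = True
        with pytest.raises(ValueError):
            fit_ellipse(img)


class TestDistributionStats:
    def test_constant_sample(self):
        mean, sd, curve = distribution_stats([100.0, 100.0, 100.0 + 1e-9])
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_two_point_closed_form(self):
        mean, sd, _ = distribution_stats([90.0, 110.0])
        assert mean == 100.0
        assert sd == pytest.approx(math.sqrt(2) * 10.0, rel=1e-9)

    def test_kde_normalized(self, rng):
        d = rng.normal(400, 40, 200)
        _, _, curve = distribution_stats(d)
        area = np.trapezoid(curve.density, curve.diameter_nm)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            distribution_stats([100.0])


class TestComposition:
    def test_single_footprint(self):
        s = 37.7
        foot = math.sqrt(3) / 2 * s**2
        d = math.sqrt(foot / math.pi)  # sphere of area == one footprint
        n, mass = estimate_composition(d, d, s_mid=s, monomer_mass_da=1.0)
        assert n == pytest.approx(1.0, rel=1e-9)

    def test_area_scaling(self):
        n1, _ = estimate_composition(400.0, 400.0)
        n2, _ = estimate_composition(800.0, 800.0)
        assert n2 / n1 == pytest.approx(4.0, rel=1e-9)

    @pytest.mark.parametrize("d_major,d_minor", [(400, 400), (800, 400),
                                                 (1500, 600)])
    def test_prolate_area_against_quadrature(self, d_major, d_minor):
        a, b = d_major / 2, d_minor / 2

        def integrand(t):
            # surface of revolution of the ellipse about its major axis
            return (2 * math.pi * b * math.sin(t)
                    * math.sqrt((a * math.sin(t)) ** 2
                                + (b * math.cos(t)) ** 2))

        area_quad, _ = quad(integrand, 0, math.pi, limit=200)
        assert _prolate_surface_area(d_major, d_minor) == \
            pytest.approx(area_quad, rel=5e-3)


class TestSegmentation:
    def test_blank_image(self):
        img = Micrograph(np.full((256, 256), 0.5), 5.0)
        labels, border = segment_containers(img)
        assert labels.max() == 0

    def test_empty_image(self):
        img = Micrograph(np.zeros((0, 0)), 5.0)
        labels, border = segment_containers(img)
        assert labels.size == 0
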