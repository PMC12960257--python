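"""Worm-like-chain strand model and the cone-angle design engine."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dipid.design import (CURVATURE_MENU, DEFAULT_STICKY, DesignRangeError,
                          DomainSpec, GEOMETRY_30NM, VARIANT_TARGETS,
                          angle_error, cone_angle, enumerate_designs,
                          generate_variant, invert_diameter_to_angle,
                          predict_radius_naive, reverse_complement,
                          solve_curvature_length, strand_length,
                          validate_sticky)
from dipid.wlc import WLCParams, wlc_end_to_end


def mc_wlc_rms(Lc, Lp, n_seg=400, n_chains=4000, seed=7):
    """Independent Monte-Carlo oracle: RMS end-to-end distance of a
    discrete worm-like chain with exponentially decaying tangent
    correlations (exact von Mises-Fisher bond-angle sampling)."""
    rng = np.random.default_rng(seed)
    b = Lc / n_seg
    kappa = Lp / b
    t = np.zeros((n_chains, 3))
    t[:, 2] = 1.0
    ends = np.zeros((n_chains, 3))
    for _ in range(n_seg):
        u = rng.random(n_chains)
        cos_t = 1.0 + np.log(u + (1 - u) * np.exp(-2 * kappa)) / kappa
        sin_t = np.sqrt(np.maximum(0.0, 1 - cos_t**2))
        phi = rng.uniform(0, 2 * np.pi, n_chains)
        # local frame around current tangent
        ref = np.where(np.abs(t[:, 2:3]) < 0.9, [[0, 0, 1.0]], [[1.0, 0, 0]])
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1, axis=1)[:, None]
        e2 = np.cross(t, e1)
        t = (cos_t[:, None] * t
             + sin_t[:, None] * (np.cos(phi)[:, None] * e1
                                 + np.sin(phi)[:, None] * e2))
        t /= np.linalg.norm(t, axis=1)[:, None]
        ends += b * t
    r2 = np.sum(ends**2, axis=1)
    return np.sqrt(r2.mean()), r2.std(ddof=1) / np.sqrt(n_chains), r2.mean()


class TestWLC:
    def test_zero_contour(self):
        assert wlc_end_to_end(0.0) == 0.0

    def test_negative_contour_raises(self):
        with pytest.raises(ValueError):
            wlc_end_to_end(-1.0)

    def test_printed_example(self):
        # 16 nt of ssDNA at 0.63 nm/nt, Lp = 1.5 nm
        assert wlc_end_to_end(10.08) == pytest.approx(5.074, abs=1e-3)

    def test_ideal_coil_limit(self):
        p = WLCParams()
        Lc = 1e5
        assert wlc_end_to_end(Lc, p) / math.sqrt(2 * p.Lp * Lc) == \
            pytest.approx(1.0, rel=1e-4)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_bounded_by_contour(self, Lc):
        assert 0 < wlc_end_to_end(Lc) <= Lc

    def test_strictly_increasing(self):
        grid = np.linspace(0.01, 60, 500)
        vals = [wlc_end_to_end(x) for x in grid]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("ratio", [1.0, 3.0, 10.0])
    def test_against_monte_carlo_chain(self, ratio):
        """Closed form vs discrete-chain simulation within 3 SE of <R^2>."""
        Lp = 1.5
        Lc = ratio * Lp
        rms_mc, se_r2, mean_r2 = mc_wlc_rms(Lc, Lp)
        closed = wlc_end_to_end(Lc, WLCParams(Lp=Lp))
        assert abs(closed**2 - mean_r2) < 3 * se_r2


class TestStrandLength:
    def test_printed_example(self):
        d = DomainSpec(flex_len=8, sticky_seq=DEFAULT_STICKY[6])
        assert strand_length(d) == pytest.approx(4.30, abs=5e-3)

    def test_monotone_in_curvature(self):
        lens = [strand_length(DomainSpec(8, DEFAULT_STICKY[6], n))
                for n in range(0, 53)]
        assert np.all(np.diff(lens) > 0)

    def test_half_duplex_term(self):
        # sticky contributes half its duplex length
        d4 = DomainSpec(8, DEFAULT_STICKY[4])
        d8 = DomainSpec(8, DEFAULT_STICKY[8])
        assert strand_length(d8) - strand_length(d4) == \
            pytest.approx(0.5 * 4 * 0.34)


class TestStickyValidation:
    @pytest.mark.parametrize("seq,ok", [
        ("GTAC", True), ("GCGC", True), ("TATATA", True), ("TAATATTA", True),
        ("AAAA", False), ("ATGAT", False), ("ACGTA", False),
    ])
    def test_palindromes(self, seq, ok):
        assert validate_sticky(seq) is ok

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            validate_sticky("ACGX")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=12))
    def test_seq_plus_revcomp_is_palindromic(self, seq):
        assert validate_sticky(seq + reverse_complement(seq))


class TestConeGeometry:
    def test_symmetric_design_is_planar(self):
        # zero curvature extension on every strand -> alpha = 0
        from dipid.design import _design_for
        flat = _design_for(0, 8, DEFAULT_STICKY[6], GEOMETRY_30NM, WLCParams())
        assert cone_angle(flat) == 0.0
        assert math.isinf(predict_radius_naive(flat))

    def test_inverse_consistency(self):
        """invert_diameter_to_angle is the exact inverse of the radius
        prediction for all ten generated variants."""
        for name in VARIANT_TARGETS:
            d = generate_variant(name)
            assert invert_diameter_to_angle(d.diameter_naive, d) == \
                pytest.approx(d.cone_angle_naive, abs=1e-9)
            assert angle_error(d.diameter_naive, d) == pytest.approx(0, abs=1e-9)

    def test_larger_measured_diameter_gives_positive_error(self):
        d = generate_variant("M")
        assert angle_error(1.3 * d.diameter_naive, d) > 0

    def test_halving_alpha_doubles_radius(self):
        d = generate_variant("M")
        s_mid = d.s_mid()
        a = math.radians(d.cone_angle_naive)
        assert (s_mid / a) / (s_mid / (2 * a)) == pytest.approx(2.0)


class TestSolver:
    def test_xs_target_round_trip(self):
        d = solve_curvature_length(119.0)
        assert d.radius_naive == pytest.approx(59.5, abs=0.5)

    def test_fixed_point(self):
        d10 = None
        from dipid.design import _design_for
        d10 = _design_for(10, 8, DEFAULT_STICKY[6], GEOMETRY_30NM, WLCParams())
        again = solve_curvature_length(d10.diameter_naive)
        assert again.face_strand("outer").curvature_len == 10

    def test_out_of_range_raises_with_nearest(self):
        with pytest.raises(DesignRangeError) as exc:
            solve_curvature_length(50.0)
        assert exc.value.nearest[0] > 50.0

    def test_diameter_decreasing_in_curvature_length(self):
        from dipid.design import _design_for
        ds = [_design_for(n, 8, DEFAULT_STICKY[6], GEOMETRY_30NM, WLCParams())
              for n in range(1, 53)]
        diam = [d.diameter_naive for d in ds]
        alpha = [d.cone_angle_naive for d in ds]
        assert np.all(np.diff(diam) < 0)
        assert np.all(np.diff(alpha) > 0)


class TestVariants:
    def test_thirty_strands_each(self):
        for name in VARIANT_TARGETS:
            d = generate_variant(name)
            assert len(d.strands) == 30
            assert all(validate_sticky(s.sticky_seq) for s in d.strands)

    def test_deterministic(self):
        assert generate_variant("S") == generate_variant("S")

    def test_class_ordering(self):
        """Larger target diameter -> smaller cone angle and extension."""
        alphas = [generate_variant(n).cone_angle_naive
                  for n in ("XS", "S", "M", "L", "XL", "XXL")]
        assert np.all(np.diff(alphas) < 0)

    def test_s_vs_xxl_exchange(self):
        s = generate_variant("S")
        xxl = generate_variant("XXL")
        diff = sum(a.full_sequence != b.full_sequence
                   for a, b in zip(s.strands, xxl.strands))
        assert diff == 24

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown variant"):
            generate_variant("XXS")


class TestEnumeration:
    def test_single_menu_grid(self):
        ds, meta = enumerate_designs(flex_menu=(8,), sticky_menu=(6,))
        assert meta["raw_grid"] == 53 and len(ds) == 53

    def test_full_grid_636(self):
        ds, meta = enumerate_designs()
        assert meta["raw_grid"] == 636 == len(ds)

    def test_no_dedup_keeps_grid(self):
        ds, meta = enumerate_designs(dedup_radius_nm=0.0)
        assert meta["count"] == meta["raw_grid"]

    def test_dedup_reduces(self):
        ds, meta = enumerate_designs(dedup_radius_nm=5.0)
        assert meta["count"] < 636
        assert "5.0 nm" in meta["dedup_rule"]

    def test_empty_menu(self):
        ds, meta = enumerate_designs(flex_menu=())
        assert ds == []
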