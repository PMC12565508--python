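"""Geometric feature formulas against closed forms and numerical oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ellipe, ellipeinc, ellipkinc

from fruitvol.features import (
    FEATURE_NAMES,
    build_feature_vector,
    cross_sectional_areas,
    ellipse_perimeter,
    ellipsoid_surface_area,
    ellipsoid_volume_proxies,
    mean_diameter_sphere_volume,
    semi_axes,
    shape_ratios,
    sphericity,
)
from fruitvol.metrology import FruitDimensions

dims_strategy = st.tuples(
    *(st.floats(30.0, 120.0) for _ in range(4))
).map(lambda t: FruitDimensions(*t))


def exact_ellipse_perimeter(A, B):
    """Complete-elliptic-integral oracle: P = 4 a E(e^2), a = max(A, B)."""
    a, b = max(A, B), min(A, B)
    return 4.0 * a * ellipe(1.0 - (b / a) ** 2)


def exact_ellipsoid_surface(a, b, c):
    """Legendre closed form for the ellipsoid surface area (a >= b >= c)."""
    a, b, c = sorted((a, b, c), reverse=True)
    if np.isclose(a, c):
        return 4.0 * np.pi * a * b
    phi = np.arccos(c / a)
    m = (a**2 * (b**2 - c**2)) / (b**2 * (a**2 - c**2))
    F, E = ellipkinc(phi, m), ellipeinc(phi, m)
    s = np.sin(phi)
    return 2.0 * np.pi * c**2 + (2.0 * np.pi * a * b / s) * (E * s**2 + F * np.cos(phi) ** 2)


class TestSemiAxes:
    def test_symmetric(self):
        s = semi_axes(FruitDimensions(60, 60, 60, 60))
        assert (s.a, s.b, s.c_sw, s.c_sh, s.c_avg) == (30, 30, 30, 30, 30)

    def test_halving(self):
        s = semi_axes(FruitDimensions(60, 50, 58, 54))
        assert (s.a, s.b, s.c_sw, s.c_sh, s.c_avg) == (30, 25, 29, 27, 28)

    @given(dims=dims_strategy)
    def test_c_avg_is_mean_of_side_semi_axes(self, dims):
        s = semi_axes(dims)
        assert s.c_avg == pytest.approx((s.c_sw + s.c_sh) / 2, rel=1e-12)


class TestVolumeProxies:
    def test_sphere(self):
        s = semi_axes(FruitDimensions(60, 60, 60, 60))
        for v in ellipsoid_volume_proxies(s):
            assert v == pytest.approx(4 / 3 * np.pi * 27, rel=1e-12)

    def test_ellipsoid_vs_monte_carlo(self):
        # independent Monte-Carlo integration of the ellipsoid indicator
        a, b, c = 30.0, 25.0, 28.0
        rng = np.random.default_rng(123)
        pts = rng.uniform(-1, 1, size=(400_000, 3)) * (a, b, c)
        inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 + (pts[:, 2] / c) ** 2 <= 1
        mc = inside.mean() * 8 * a * b * c / 1000.0
        s = semi_axes(FruitDimensions(2 * a, 2 * b, 56, 56))
        v_avg, _, _ = ellipsoid_volume_proxies(s)
        assert v_avg == pytest.approx(4 / 3 * np.pi * 21, rel=1e-12)
        assert v_avg == pytest.approx(mc, rel=0.01)

    def test_degenerate_side_views_collapse(self):
        s = semi_axes(FruitDimensions(60, 50, 54, 54))
        v = ellipsoid_volume_proxies(s)
        assert v[0] == pytest.approx(v[1], rel=1e-12) and v[1] == pytest.approx(v[2], rel=1e-12)

    @given(dims=dims_strategy, delta=st.floats(0.5, 5.0))
    def test_monotone_in_side_height(self, dims, delta):
        import dataclasses

        bigger = dataclasses.replace(dims, h_side=dims.h_side + delta)
        v0 = ellipsoid_volume_proxies(semi_axes(dims))
        v1 = ellipsoid_volume_proxies(semi_axes(bigger))
        assert v1[0] > v0[0] and v1[2] > v0[2]

    def test_mean_diameter(self):
        d, v = mean_diameter_sphere_volume(FruitDimensions(50, 60, 70, 80))
        assert d == 65.0
        lo = 4 / 3 * np.pi * 25**3 / 1000
        hi = 4 / 3 * np.pi * 40**3 / 1000
        assert lo < v < hi


class TestAreasAndPerimeters:
    def test_circle_area(self):
        a_top, _ = cross_sectional_areas(semi_axes(FruitDimensions(60, 60, 60, 60)))
        assert a_top == pytest.approx(900 * np.pi, rel=1e-12)

    def test_ellipse_area(self):
        a_top, _ = cross_sectional_areas(semi_axes(FruitDimensions(60, 50, 60, 60)))
        assert a_top == pytest.approx(750 * np.pi, rel=1e-12)

    def test_circle_perimeter_exact(self):
        assert ellipse_perimeter(7.0, 7.0) == pytest.approx(2 * np.pi * 7, rel=1e-14)

    def test_two_to_one_ellipse(self):
        # elliptic-integral oracle gives 9.688448 for semi-axes (2, 1)
        assert ellipse_perimeter(2.0, 1.0) == pytest.approx(9.6884, abs=1e-4)
        assert ellipse_perimeter(2.0, 1.0) == pytest.approx(
            exact_ellipse_perimeter(2.0, 1.0), rel=1e-5
        )

    @given(A=st.floats(5.0, 60.0), B=st.floats(5.0, 60.0))
    def test_symmetric_and_accurate(self, A, B):
        assert ellipse_perimeter(A, B) == pytest.approx(ellipse_perimeter(B, A), rel=1e-14)
        if max(A, B) / min(A, B) <= 4:
            assert ellipse_perimeter(A, B) == pytest.approx(
                exact_ellipse_perimeter(A, B), rel=2e-4
            )


class TestSurfaceAndSphericity:
    def test_sphere_surface_exact(self):
        assert ellipsoid_surface_area(30, 30, 30) == pytest.approx(3600 * np.pi, rel=1e-12)

    def test_vs_closed_form_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.uniform(10, 40)
            b, c = a / rng.uniform(1, 3), a / rng.uniform(1, 3)
            approx = ellipsoid_surface_area(a, b, c)
            exact = exact_ellipsoid_surface(a, b, c)
            assert abs(approx / exact - 1) < 0.012

    def test_permutation_invariant(self):
        vals = {ellipsoid_surface_area(*p) for p in [(3, 2, 1), (1, 3, 2), (2, 1, 3)]}
        assert max(vals) - min(vals) < 1e-9

    def test_sphere_sphericity_is_one(self):
        r = 30.0
        v, s = 4 / 3 * np.pi * r**3, 4 * np.pi * r**2
        assert sphericity(v, s) == pytest.approx(1.0, abs=1e-12)

    def test_nonspherical_below_one(self):
        v = 4 / 3 * np.pi * 3 * 2 * 1
        assert sphericity(v, exact_ellipsoid_surface(3, 2, 1)) < 1.0

    def test_scale_invariance(self):
        v, s = 4 / 3 * np.pi * 30 * 25 * 28, exact_ellipsoid_surface(30, 25, 28)
        k = 3.7
        assert sphericity(v, s) == pytest.approx(
            sphericity(v * k**3, s * k**2), rel=1e-12
        )


class TestRatios:
    def test_sphere_ratios(self):
        dims = FruitDimensions(60, 60, 60, 60)
        r = shape_ratios(dims, semi_axes(dims), cross_sectional_areas(semi_axes(dims)))
        assert all(r[k] == pytest.approx(1.0) for k in (
            "aspect_top", "aspect_side", "ratio_w_top_w_side", "ratio_h_top_h_side",
            "ratio_area_top_side",
        ))
        assert r["ecc_top"] == 0.0 and r["ecc_side"] == 0.0

    def test_eccentricity_hand_value(self):
        dims = FruitDimensions(60, 50, 60, 60)
        r = shape_ratios(dims, semi_axes(dims), (1.0, 1.0))
        assert r["ecc_top"] == pytest.approx(np.sqrt(1 - (25 / 30) ** 2), rel=1e-12)

    def test_interaction_term(self):
        dims = FruitDimensions(60, 60, 60, 60)
        s = semi_axes(dims)
        r = shape_ratios(dims, s, cross_sectional_areas(s))
        assert r["inter_area_top_w_side"] == pytest.approx(900 * np.pi * 60, rel=1e-12)


class TestFeatureVector:
    def test_sphere_collapses_proxies(self):
        vec = build_feature_vector(FruitDimensions(60, 60, 60, 60))
        assert list(vec) == FEATURE_NAMES
        sphere_v = 4 / 3 * np.pi * 27
        for k in ("v_ellip_avg", "v_ellip_sw", "v_ellip_sh", "v_sphere"):
            assert vec[k] == pytest.approx(sphere_v, rel=1e-9)
        assert vec["sphericity"] == pytest.approx(1.0, abs=1e-9)

    def test_purity(self):
        dims = FruitDimensions(61.2, 58.9, 60.4, 55.1)
        assert build_feature_vector(dims) == build_feature_vector(dims)

    def test_sensitivity_to_each_dimension(self):
        import dataclasses

        base = FruitDimensions(62, 58, 61, 56)
        v0 = build_feature_vector(base)
        changed = set()
        for fld in ("w_top", "h_top", "w_side", "h_side"):
            v1 = build_feature_vector(
                dataclasses.replace(base, **{fld: getattr(base, fld) + 1.0})
            )
            changed |= {k for k in FEATURE_NAMES if v1[k] != v0[k]}
        assert changed == set(FEATURE_NAMES)

    @given(dims=dims_strategy)
    def test_unit_discipline(self, dims):
        # volumes are carried in mL = mm^3 / 1000 exactly
        s = semi_axes(dims)
        v_ml = ellipsoid_volume_proxies(s)[0]
        v_mm3 = 4 / 3 * np.pi * s.a * s.b * s.c_avg
        assert v_mm3 / v_ml == pytest.approx(1000.0, rel=1e-12)
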