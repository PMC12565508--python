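"""Physics-aware geometric features from four calibrated fruit dimensions.

From the two orthogonal views we have top width/height and side width/height
(mm).  Halving them gives ellipsoid semi-axes; from those we derive volume
proxies, cross-sectional areas, Ramanujan perimeter surrogates, a
Knud-Thomsen surface-area estimate, sphericity, the surface-to-volume ratio,
and a set of aspect/cross-view/eccentricity/interaction descriptors — 25
features in total, the canonical inputs of the volume regressor.

Units: lengths mm, areas mm^2, volumes mL (mm^3 / 1000), ratios and
eccentricities dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrology import FruitDimensions

__all__ = [
    "SemiAxes",
    "KNUD_THOMSEN_P",
    "FEATURE_NAMES",
    "MONOTONE_INCREASING_FEATURES",
    "LOG_SCALE_FEATURES",
    "semi_axes",
    "ellipsoid_volume_proxies",
    "mean_diameter_sphere_volume",
    "cross_sectional_areas",
    "ellipse_perimeter",
    "ellipsoid_surface_area",
    "sphericity",
    "shape_ratios",
    "build_feature_vector",
    "featurize_table",
]

#: Knud-Thomsen exponent for the approximate ellipsoid surface area.
KNUD_THOMSEN_P = 1.6075

#: Canonical ordered 25-feature list.
FEATURE_NAMES = [
    "w_top",
    "h_top",
    "w_side",
    "h_side",
    "mean_diameter",
    "v_ellip_avg",
    "v_ellip_sw",
    "v_ellip_sh",
    "v_sphere",
    "area_top",
    "area_side",
    "perimeter_top",
    "perimeter_side",
    "surface_area",
    "sphericity",
    "sa_to_vol",
    "aspect_top",
    "aspect_side",
    "ratio_w_top_w_side",
    "ratio_h_top_h_side",
    "ratio_area_top_side",
    "ecc_top",
    "ecc_side",
    "inter_area_top_w_side",
    "inter_area_side_h_top",
]

#: Raw dimensions plus the mean diameter: volume must not decrease in these.
MONOTONE_INCREASING_FEATURES = [
    "w_top",
    "h_top",
    "w_side",
    "h_side",
    "mean_diameter",
]

#: Strictly-positive features placed on a log scale during preprocessing;
#: ratios, eccentricities and sphericity stay on their natural scale.
LOG_SCALE_FEATURES = [
    "w_top",
    "h_top",
    "w_side",
    "h_side",
    "mean_diameter",
    "v_ellip_avg",
    "v_ellip_sw",
    "v_ellip_sh",
    "v_sphere",
    "area_top",
    "area_side",
    "perimeter_top",
    "perimeter_side",
    "surface_area",
    "inter_area_top_w_side",
    "inter_area_side_h_top",
]


@dataclass(frozen=True)
class SemiAxes:
    """Ellipsoid semi-axes (mm): a, b from the top view, c variants from the side."""

    a: float
    b: float
    c_sw: float
    c_sh: float
    c_avg: float

    def __post_init__(self):
        if min(self.a, self.b, self.c_sw, self.c_sh, self.c_avg) <= 0:
            raise ValueError("semi-axes must be positive")


def semi_axes(dims: FruitDimensions) -> SemiAxes:
    """a = w_top/2, b = h_top/2, c_sw = w_side/2, c_sh = h_side/2, c_avg = (w_side+h_side)/4."""
    return SemiAxes(
        a=dims.w_top / 2.0,
        b=dims.h_top / 2.0,
        c_sw=dims.w_side / 2.0,
        c_sh=dims.h_side / 2.0,
        c_avg=(dims.w_side + dims.h_side) / 4.0,
    )


def _ellipsoid_volume_ml(a: float, b: float, c: float) -> float:
    return (4.0 / 3.0) * np.pi * a * b * c / 1000.0


def ellipsoid_volume_proxies(s: SemiAxes) -> tuple[float, float, float]:
    """(V_ellip_avg, V_ellip_sw, V_ellip_sh) in mL, V = (4/3) pi a b c."""
    return (
        _ellipsoid_volume_ml(s.a, s.b, s.c_avg),
        _ellipsoid_volume_ml(s.a, s.b, s.c_sw),
        _ellipsoid_volume_ml(s.a, s.b, s.c_sh),
    )


def mean_diameter_sphere_volume(dims: FruitDimensions) -> tuple[float, float]:
    """Mean diameter D (mm) over the four axes and the sphere volume of D (mL)."""
    d_bar = float(np.mean(dims.as_tuple()))
    v_sphere = (4.0 / 3.0) * np.pi * (d_bar / 2.0) ** 3 / 1000.0
    return d_bar, v_sphere


def cross_sectional_areas(s: SemiAxes) -> tuple[float, float]:
    """A_top = pi a b, A_side = pi c_sw c_sh (mm^2)."""
    return float(np.pi * s.a * s.b), float(np.pi * s.c_sw * s.c_sh)


def ellipse_perimeter(A: float, B: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter.

    h = (A-B)^2 / (A+B)^2;  P ~ pi (A+B) (1 + 3h / (10 + sqrt(4 - 3h))).
    Exact for circles; relative error < 1e-5 up to axis ratio 4.
    """
    if A <= 0 or B <= 0:
        raise ValueError("semi-axes must be positive")
    h = (A - B) ** 2 / (A + B) ** 2
    return float(np.pi * (A + B) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def ellipsoid_surface_area(a: float, b: float, c: float, p: float = KNUD_THOMSEN_P) -> float:
    """Knud-Thomsen approximate ellipsoid surface area (mm^2).

    S ~ 4 pi ((a^p b^p + a^p c^p + b^p c^p) / 3)^(1/p), p = 1.6075; worst-case
    relative error about 1.06% over all aspect ratios, exact for spheres.
    """
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    ap, bp, cp = a**p, b**p, c**p
    return float(4.0 * np.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p))


def sphericity(volume_mm3: float, surface_mm2: float) -> float:
    """Psi = pi^(1/3) (6V)^(2/3) / S — surface of the equal-volume sphere over S."""
    if volume_mm3 <= 0 or surface_mm2 <= 0:
        raise ValueError("volume and surface must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume_mm3) ** (2.0 / 3.0) / surface_mm2)


def _eccentricity(u: float, v: float) -> float:
    minor, major = min(u, v), max(u, v)
    return float(np.sqrt(1.0 - (minor / major) ** 2))


def shape_ratios(dims: FruitDimensions, s: SemiAxes, areas: tuple[float, float]) -> dict:
    """Aspect ratios, cross-view ratios, area ratio, eccentricities, interactions."""
    a_top, a_side = areas
    return {
        "aspect_top": dims.w_top / dims.h_top,
        "aspect_side": dims.w_side / dims.h_side,
        "ratio_w_top_w_side": dims.w_top / dims.w_side,
        "ratio_h_top_h_side": dims.h_top / dims.h_side,
        "ratio_area_top_side": a_top / a_side,
        "ecc_top": _eccentricity(s.a, s.b),
        "ecc_side": _eccentricity(s.c_sw, s.c_sh),
        "inter_area_top_w_side": a_top * dims.w_side,
        "inter_area_side_h_top": a_side * dims.h_top,
    }


def build_feature_vector(dims: FruitDimensions) -> dict:
    """Deterministic ordered 25-feature mapping; a pure function of the dimensions."""
    s = semi_axes(dims)
    v_avg, v_sw, v_sh = ellipsoid_volume_proxies(s)
    d_bar, v_sphere = mean_diameter_sphere_volume(dims)
    a_top, a_side = cross_sectional_areas(s)
    surface = ellipsoid_surface_area(s.a, s.b, s.c_avg)
    psi = sphericity(v_avg * 1000.0, surface)
    out = {
        "w_top": dims.w_top,
        "h_top": dims.h_top,
        "w_side": dims.w_side,
        "h_side": dims.h_side,
        "mean_diameter": d_bar,
        "v_ellip_avg": v_avg,
        "v_ellip_sw": v_sw,
        "v_ellip_sh": v_sh,
        "v_sphere": v_sphere,
        "area_top": a_top,
        "area_side": a_side,
        "perimeter_top": ellipse_perimeter(s.a, s.b),
        "perimeter_side": ellipse_perimeter(s.c_sw, s.c_sh),
        "surface_area": surface,
        "sphericity": psi,
        "sa_to_vol": surface / v_avg,
    }
    out.update(shape_ratios(dims, s, (a_top, a_side)))
    vec = {name: float(out[name]) for name in FEATURE_NAMES}
    if not all(np.isfinite(v) for v in vec.values()):
        raise ValueError("non-finite feature value")
    return vec


def featurize_table(dims_table: pd.DataFrame) -> pd.DataFrame:
    """Build the 25-column feature table from a dimension table.

    Expects columns ``fruit_id, w_top_mm, h_top_mm, w_side_mm, h_side_mm``
    (the metrology output schema).
    """
    rows = []
    for rec in dims_table.itertuples(index=False):
        dims = FruitDimensions(
            w_top=rec.w_top_mm,
            h_top=rec.h_top_mm,
            w_side=rec.w_side_mm,
            h_side=rec.h_side_mm,
            fruit_id=str(rec.fruit_id),
        )
        row = {"fruit_id": dims.fruit_id}
        row.update(build_feature_vector(dims))
        rows.append(row)
    return pd.DataFrame(rows, columns=["fruit_id"] + FEATURE_NAMES)
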