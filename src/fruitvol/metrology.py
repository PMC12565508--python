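"""Marker-calibrated conversion of two-view silhouette measurements to millimetres.

A fiducial square of known physical size is placed in each view; its pixel
extent gives the per-frame scale factor alpha = M_mm / M_px, which converts
the fruit's tight bounding-box extents from pixels to millimetres.  Each view
carries its own marker and its own alpha; scale factors are never shared or
averaged across views.

Pixel convention: a bounding-box extent is (max index - min index + 1), i.e.
the number of pixel rows/columns the object occupies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

__all__ = [
    "CalibrationError",
    "ExtractionError",
    "QCRejectionError",
    "QCFlag",
    "MarkerSpec",
    "ViewMeasurement",
    "FruitDimensions",
    "compute_scale_factor",
    "convert_dimension",
    "extract_dimensions_from_mask",
    "quality_check",
    "assemble_fruit_dimensions",
    "dimensions_to_frame",
]

#: Default sanity bounds on calibrated dimensions (mm).
DIM_BOUNDS_MM = (20.0, 150.0)
#: Default per-view max/min aspect-ratio bound.
ASPECT_BOUND = 2.0
#: Marker confidence below this raises the low-confidence flag.
CONFIDENCE_THRESHOLD = 0.5
#: |w - h| / max(w, h) at or below this counts as "square".
SQUARENESS_TOL = 0.1


class CalibrationError(ValueError):
    """Non-positive length fed into the pixel-to-mm conversion."""


class ExtractionError(ValueError):
    """Mask does not contain the expected fruit + marker components."""


class QCRejectionError(ValueError):
    """Strict-mode assembly rejected a measurement; carries the flag set."""

    def __init__(self, flags: frozenset["QCFlag"]):
        self.flags = flags
        super().__init__(f"quality control failed: {sorted(f.value for f in flags)}")


class QCFlag(enum.Enum):
    ASPECT_RATIO_VIOLATION = "aspect_ratio_violation"
    OCCLUSION_SUSPECT = "occlusion_suspect"
    LOW_MARKER_CONFIDENCE = "low_marker_confidence"
    OUT_OF_BOUNDS = "out_of_bounds"


@dataclass(frozen=True)
class MarkerSpec:
    """Fiducial square: physical side length (mm), pixel side length, confidence."""

    physical_size_mm: float
    pixel_size_px: float
    confidence: float = 1.0

    def __post_init__(self):
        if self.physical_size_mm <= 0:
            raise CalibrationError("marker physical size must be positive")
        if self.pixel_size_px <= 0:
            raise CalibrationError("marker pixel size must be positive")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("marker confidence must lie in [0, 1]")


@dataclass(frozen=True)
class ViewMeasurement:
    """Raw pixel measurement of one view plus its calibration marker."""

    view_label: str  # "top" or "side"
    fruit_width_px: float
    fruit_height_px: float
    marker: MarkerSpec
    qc_flags: frozenset[QCFlag] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.view_label not in ("top", "side"):
            raise ValueError("view_label must be 'top' or 'side'")
        if self.fruit_width_px <= 0 or self.fruit_height_px <= 0:
            raise ValueError("fruit pixel extents must be positive")


@dataclass(frozen=True)
class FruitDimensions:
    """The four calibrated orthogonal measurements (mm) that drive everything."""

    w_top: float
    h_top: float
    w_side: float
    h_side: float
    fruit_id: str = ""

    def __post_init__(self):
        if min(self.w_top, self.h_top, self.w_side, self.h_side) <= 0:
            raise ValueError("all dimensions must be positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_top, self.h_top, self.w_side, self.h_side)


def compute_scale_factor(marker: MarkerSpec) -> float:
    """Per-frame scale factor alpha = physical size / pixel size (mm per px)."""
    return marker.physical_size_mm / marker.pixel_size_px


def convert_dimension(d_px: float, alpha: float) -> float:
    """Convert a pixel extent to millimetres: D_mm = alpha * D_px."""
    if d_px <= 0:
        raise CalibrationError("pixel dimension must be positive")
    if alpha <= 0:
        raise CalibrationError("scale factor must be positive")
    return alpha * d_px


def _bbox_extents(region) -> tuple[float, float]:
    """Tight bounding-box (width, height) in px; extent = max - min + 1."""
    minr, minc, maxr, maxc = region.bbox  # half-open in skimage
    return float(maxc - minc), float(maxr - minr)


def _squareness_deviation(w: float, h: float) -> float:
    return abs(w - h) / max(w, h)


def extract_dimensions_from_mask(
    mask: np.ndarray,
    marker_physical_size_mm: float | None = None,
    squareness_tol: float = SQUARENESS_TOL,
) -> dict:
    """Locate marker + fruit in a binary mask and measure their extents.

    The marker is the component best matching a squareness criterion
    (|w - h| / max(w, h) <= ``squareness_tol``); the fruit is the largest
    remaining component.  With several equally plausible square candidates the
    smaller component is taken as the marker and a low-confidence flag is set
    rather than raising.

    Returns a dict with keys ``fruit_width_px``, ``fruit_height_px``,
    ``marker`` (:class:`MarkerSpec` if ``marker_physical_size_mm`` given, else
    marker pixel size), ``qc_flags`` and ``fruit_touches_border``.
    """
    mask = np.asarray(mask)
    lab = label(mask > 0, connectivity=2)
    regions = sorted(regionprops(lab), key=lambda r: r.area, reverse=True)
    if len(regions) < 2:
        raise ExtractionError(
            f"expected at least 2 components (fruit + marker), found {len(regions)}"
        )

    flags: set[QCFlag] = set()
    extents = [_bbox_extents(r) for r in regions]
    devs = [_squareness_deviation(w, h) for w, h in extents]
    # a filled square also fills its bounding box; a near-circular fruit has
    # a square-ish bbox but only ~pi/4 fill, so the fill ratio disambiguates
    fills = [r.area / (w * h) for r, (w, h) in zip(regions, extents)]
    square_idx = [i for i, d in enumerate(devs) if d <= squareness_tol]
    filled_idx = [i for i in square_idx if fills[i] >= 0.92]

    if len(filled_idx) == 1:
        marker_i = filled_idx[0]
        confidence = 1.0 - devs[marker_i] / squareness_tol
    elif square_idx:
        # ambiguous: several plausible squares (or none filled); the smaller
        # component is taken as the marker
        pool = filled_idx or square_idx
        marker_i = min(pool, key=lambda i: regions[i].area)
        confidence = 0.5 * (1.0 - devs[marker_i] / squareness_tol)
        flags.add(QCFlag.LOW_MARKER_CONFIDENCE)
    else:
        # nothing square enough: smallest component stands in, flagged
        marker_i = len(regions) - 1
        confidence = 0.0
        flags.add(QCFlag.LOW_MARKER_CONFIDENCE)

    fruit_candidates = [i for i in range(len(regions)) if i != marker_i]
    fruit_i = fruit_candidates[0]  # regions pre-sorted by area desc
    fw, fh = extents[fruit_i]
    mw, mh = extents[marker_i]
    marker_px = 0.5 * (mw + mh)

    minr, minc, maxr, maxc = regions[fruit_i].bbox
    touches = minr == 0 or minc == 0 or maxr == mask.shape[0] or maxc == mask.shape[1]
    if touches:
        flags.add(QCFlag.OCCLUSION_SUSPECT)

    marker = None
    if marker_physical_size_mm is not None:
        marker = MarkerSpec(marker_physical_size_mm, marker_px, max(0.0, confidence))
    return {
        "fruit_width_px": fw,
        "fruit_height_px": fh,
        "marker_pixel_size": marker_px,
        "marker": marker,
        "marker_confidence": max(0.0, confidence),
        "qc_flags": frozenset(flags),
        "fruit_touches_border": touches,
    }


def quality_check(
    dims: FruitDimensions,
    marker_confidence: float = 1.0,
    aspect_bound: float = ASPECT_BOUND,
    dim_bounds_mm: tuple[float, float] = DIM_BOUNDS_MM,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
    touches_border: bool = False,
) -> frozenset[QCFlag]:
    """Run the sanity checks; always returns a (possibly empty) flag set."""
    flags: set[QCFlag] = set()
    for w, h in ((dims.w_top, dims.h_top), (dims.w_side, dims.h_side)):
        if max(w, h) / min(w, h) > aspect_bound:
            flags.add(QCFlag.ASPECT_RATIO_VIOLATION)
    if marker_confidence < confidence_threshold:
        flags.add(QCFlag.LOW_MARKER_CONFIDENCE)
    if touches_border:
        flags.add(QCFlag.OCCLUSION_SUSPECT)
    lo, hi = dim_bounds_mm
    if any(not lo <= d <= hi for d in dims.as_tuple()):
        flags.add(QCFlag.OUT_OF_BOUNDS)
    return frozenset(flags)


def assemble_fruit_dimensions(
    top: ViewMeasurement,
    side: ViewMeasurement,
    fruit_id: str = "",
    strict: bool = False,
    aspect_bound: float = ASPECT_BOUND,
    dim_bounds_mm: tuple[float, float] = DIM_BOUNDS_MM,
) -> tuple[FruitDimensions, frozenset[QCFlag]]:
    """Calibrate both views with their own per-frame alpha and merge.

    Returns ``(dims, flags)``; in strict mode a non-empty flag set raises
    :class:`QCRejectionError` instead.
    """
    if top.view_label != "top" or side.view_label != "side":
        raise ValueError("expected one 'top' and one 'side' measurement")
    a_top = compute_scale_factor(top.marker)
    a_side = compute_scale_factor(side.marker)
    dims = FruitDimensions(
        w_top=convert_dimension(top.fruit_width_px, a_top),
        h_top=convert_dimension(top.fruit_height_px, a_top),
        w_side=convert_dimension(side.fruit_width_px, a_side),
        h_side=convert_dimension(side.fruit_height_px, a_side),
        fruit_id=fruit_id,
    )
    confidence = min(top.marker.confidence, side.marker.confidence)
    flags = quality_check(
        dims,
        marker_confidence=confidence,
        aspect_bound=aspect_bound,
        dim_bounds_mm=dim_bounds_mm,
    )
    flags = frozenset(flags | top.qc_flags | side.qc_flags)
    if strict and flags:
        raise QCRejectionError(flags)
    return dims, flags


def dimensions_to_frame(records: list[tuple[FruitDimensions, frozenset[QCFlag]]]):
    """Assemble a dimension table (one row per fruit) from (dims, flags) pairs."""
    import pandas as pd

    rows = []
    for dims, flags in records:
        rows.append(
            {
                "fruit_id": dims.fruit_id,
                "w_top_mm": dims.w_top,
                "h_top_mm": dims.h_top,
                "w_side_mm": dims.w_side,
                "h_side_mm": dims.h_side,
                "qc_flags": ";".join(sorted(f.value for f in flags)),
            }
        )
    return pd.DataFrame(rows)
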