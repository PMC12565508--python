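"""Measure a fruit from two rendered silhouette masks with a fiducial marker.

Renders a synthetic fruit's top and side views, each containing a 30 mm
calibration square, then runs the metrology pipeline: locate the marker,
compute the per-frame mm-per-px scale factor, and convert the fruit's
bounding-box extents to millimetres.
"""

from fruitvol.metrology import (
    MarkerSpec,
    ViewMeasurement,
    assemble_fruit_dimensions,
    extract_dimensions_from_mask,
)
from fruitvol.synthetic import FruitShape, render_views, shape_extents

shape = FruitShape(ax=32.0, ay=29.0, az=27.0, epsilon=1.8)
top_mask, side_mask, alpha = render_views(shape, alpha=0.3, canvas_px=(400, 400))
print(f"rendered two 400x400 masks at {alpha:.4f} mm/px")

views = []
for label, mask in (("top", top_mask), ("side", side_mask)):
    res = extract_dimensions_from_mask(mask, marker_physical_size_mm=30.0)
    views.append(
        ViewMeasurement(
            label,
            res["fruit_width_px"],
            res["fruit_height_px"],
            res["marker"],
        )
    )
    print(
        f"{label}: fruit {res['fruit_width_px']:.0f} x {res['fruit_height_px']:.0f} px,"
        f" marker {res['marker_pixel_size']:.0f} px, confidence {res['marker'].confidence:.2f}"
    )

dims, flags = assemble_fruit_dimensions(*views, fruit_id="demo")
print(f"calibrated dimensions (mm): {[round(d, 1) for d in dims.as_tuple()]}")
print(f"true silhouette extents (mm): {[round(e, 1) for e in shape_extents(shape)][:2]} ...")
print(f"QC flags: {sorted(f.value for f in flags) or 'none'}")
# The calibrated dimensions recover the true extents to within one pixel
# (~0.3 mm at this scale); an empty flag set means the measurement passed
# the aspect-ratio, bounds and marker-confidence checks.
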