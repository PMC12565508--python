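"""Build the 25 physics-aware features from four calibrated dimensions.

The feature stage turns (w_top, h_top, w_side, h_side) into ellipsoid
volume proxies, cross-sectional areas, Ramanujan perimeters, a
Knud-Thomsen surface area, sphericity, and ratio/eccentricity/interaction
descriptors — the inputs of the volume regressor.
"""

from fruitvol.features import build_feature_vector
from fruitvol.metrology import FruitDimensions

dims = FruitDimensions(w_top=65.0, h_top=62.0, w_side=64.0, h_side=58.0, fruit_id="demo")
vec = build_feature_vector(dims)

for name, value in vec.items():
    print(f"{name:>24s}: {value:10.3f}")

# v_ellip_* are ellipsoid volumes in mL built from different third-axis
# choices; sphericity near 1 and eccentricities near 0 say this fruit is
# close to spherical; the sa_to_vol ratio is a compactness descriptor.
print(
    f"\nellipsoid volume proxies span "
    f"{vec['v_ellip_sh']:.1f}-{vec['v_ellip_sw']:.1f} mL; "
    f"sphericity {vec['sphericity']:.4f}"
)
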