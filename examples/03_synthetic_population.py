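"""Generate the default synthetic citrus population with oracle volumes.

The generator emulates a 150-fruit, two-variety stream (small oblate
mandarins + larger rounder sweet oranges) with all silhouette diameters in
50-88 mm.  Every fruit carries an exact numerically-integrated volume, the
stand-in for a destructive water-displacement measurement.
"""

import numpy as np

from fruitvol.synthetic import GeneratorConfig, generate_dataset

dataset = generate_dataset(GeneratorConfig(n=150, seed=0))

v = dataset.target.values
dims = dataset.dimensions[["w_top_mm", "h_top_mm", "w_side_mm", "h_side_mm"]].values
print(f"n = {len(v)} fruit")
print(f"dimensions: {dims.min():.1f}-{dims.max():.1f} mm")
print(
    f"true volume: {v.min():.1f}-{v.max():.1f} mL, "
    f"mean {v.mean():.1f}, sd {v.std(ddof=1):.1f}"
)
err = dataset.features["v_ellip_avg"].values / v - 1
print(
    f"ellipsoid-proxy relative error: mean {100 * err.mean():+.1f}%, "
    f"sd {100 * err.std():.1f}%"
)
# The proxy's systematic bias and spread are what the learned models must
# correct: real (and simulated) citrus is not a perfect ellipsoid.
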