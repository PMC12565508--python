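# fruitvol

Non-destructive fruit volume estimation from calibrated two-view
silhouettes. `fruitvol` is aimed at post-harvest quality-control work —
grading lines, factory pilots, lab studies — where each fruit is imaged
from the top and the side next to a fiducial square of known size, four
orthogonal dimensions are extracted, and a regression model maps those
dimensions to true volume (the quantity that, combined with a mass
reading, yields density for defect and maturity grading).

## The model

Each view contains a calibration square of physical side `M_mm` measuring
`M_px` pixels, giving a per-frame scale factor `alpha = M_mm / M_px` that
converts the fruit's silhouette extents to millimetres:
`W_top, H_top, W_side, H_side`.

Halving these gives ellipsoid semi-axes `a, b, c_sw, c_sh` and
`c_avg = (W_side + H_side) / 4`, from which 25 physics-aware features are
built:

- ellipsoid volume proxies `V = (4/3) pi a b c` for `c` in
  `{c_avg, c_sw, c_sh}`, and the mean-diameter sphere volume;
- cross-sectional areas `pi a b`, `pi c_sw c_sh`;
- Ramanujan ellipse perimeters
  `P ≈ pi (A+B) (1 + 3h / (10 + sqrt(4 - 3h)))`, `h = (A-B)^2/(A+B)^2`;
- Knud–Thomsen surface area
  `S ≈ 4 pi ((a^p b^p + a^p c^p + b^p c^p)/3)^(1/p)`, `p = 1.6075`;
- sphericity `Psi = pi^(1/3) (6V)^(2/3) / S`, the surface-to-volume ratio,
  aspect/cross-view/area ratios, eccentricities, and interaction terms.

The regressor is a two-layer stack trained on the log target
`y = log(1 + volume_mL)`: IQR-capped and log-transformed features, embedded
feature selection (XGBoost importances strictly above the median,
re-fitted inside every fold), three grid-tuned boosted base learners
(classic gradient boosting, depth-wise regularised boosting, histogram
leaf-wise boosting) with monotone "volume never decreases with a
dimension" constraints where supported, and a Lasso meta-learner fitted on
strictly out-of-fold base predictions. Metrics (MAE, MSE, RMSE, R²) are
reported on the original mL scale after `exp(y) - 1`.

Because no public dataset of paired dimensions and displacement volumes
exists, the package ships a first-class synthetic generator: a two-variety
citrus population of lobed superellipsoids with an exact (numerically
integrated) volume oracle, calibrated measurement noise, and renderable
mask scenes, so the whole pipeline is testable end to end.

## Worked example

```python
from fruitvol.evaluation import compare_models
from fruitvol.synthetic import GeneratorConfig, generate_dataset

dataset = generate_dataset(GeneratorConfig(n=150, seed=1))
report = compare_models(dataset, seed=1, grids="fast")
print(report.to_frame().to_string(index=False))
```

prints (values in mL / mL²):

```
                     model       mae         mse      rmse       r2
                best_proxy 29.344629 1669.971468 40.865284 0.495815
                    linear  6.598617   80.641901  8.980084 0.975653
              classic_gbrt  4.943298   44.638609  6.681213 0.986523
regularised_depthwise_gbrt  5.305117   48.745892  6.981826 0.985283
   histogram_leafwise_gbrt  5.358650   48.570497  6.969254 0.985336
                     stack  4.886965   43.724139  6.612423 0.986799
```

Reading: the best closed-form ellipsoid proxy is badly biased on a
realistic mixed-variety stream (MSE ≈ 2060 mL²); a linear model on the
engineered features removes most of that bias; the boosted learners
capture the remaining non-linear shape–volume structure; and the stacked
ensemble is the most accurate model (R² ≈ 0.987, typical error ≈ 5 mL on
fruit of 60–250 mL). `examples/` contains one short narrative script per
capability (calibration, features, simulation, training, comparison,
detection metrics), and the `fruitvol` CLI exposes the same steps
(`fruitvol simulate | featurize | train | predict | evaluate | compare`).

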