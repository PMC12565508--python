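# Methods

This note records the models, numerical choices and design decisions
behind `fruitvol`, and what the synthetic experiments do and do not show.

## Metrology

A fiducial square of known side (default 30 mm) in each view gives the
per-frame scale factor `alpha = M_mm / M_px`; fruit bounding-box extents
are converted by `D_mm = alpha * D_px`. Each view carries its own marker
and its own `alpha`; scale factors are never averaged across views, so a
camera or zoom change between views is handled per frame.

Conventions and checks:

- Bounding-box extent is `max index − min index + 1` (the number of pixel
  rows/columns occupied); fixing this convention pins down the ±1 px
  ambiguity in round-trip tests.
- The marker is identified by a squareness criterion on the bounding box
  (`|w − h| / max(w, h) ≤ 0.1`) plus a fill-ratio check (area / bbox area
  ≥ 0.92), because a near-circular fruit also has a square-ish bounding
  box. With several plausible squares the smaller component is taken as
  the marker and a low-confidence flag is raised rather than an error.
- Quality control flags (never exceptions unless strict mode is on):
  per-view aspect ratio above 2.0, any dimension outside 20–150 mm, marker
  confidence below 0.5, fruit touching the image border (occlusion
  suspect). The aspect and size bounds are configurable defaults chosen to
  bracket commercial citrus generously.
- Object detection is deterministic connected-component labelling on
  binary masks. The package measures pre-segmented or synthetic
  silhouettes; training an image detector is out of scope, and the
  detection-evaluation utilities (IoU, precision/recall, mAP@50) are
  provided for scoring any external detector's boxes.

## Feature engineering

The canonical 25-feature vector (module `features`, ordered):

1–4 raw dimensions; 5 mean diameter; 6–8 ellipsoid volume proxies
(`c_avg`, `c_sw`, `c_sh` variants); 9 mean-diameter sphere volume; 10–11
cross-sectional areas; 12–13 Ramanujan perimeters (top and side); 14
Knud–Thomsen surface area on `(a, b, c_avg)` with `p = 1.6075`; 15
sphericity of the (`V_ellip_avg`, `S`) pair; 16 surface-to-volume ratio
`S / V_ellip_avg`; 17–18 per-view aspect ratios; 19–20 cross-view ratios;
21 area ratio; 22–23 per-view eccentricities
`e = sqrt(1 − (minor/major)^2)`; 24–25 interactions `A_top·W_side`,
`A_side·H_top`.

Units: lengths mm, areas mm², volumes mL (mm³/1000 exactly, everywhere).
Where a pairing was open — which `(V, S)` pair feeds sphericity, which
surface area feeds SA/V — the `c_avg`-based variants are canonical, being
the least view-dependent. Accuracy of the closed forms against numerical
oracles: Ramanujan II within 2·10⁻⁴ relative up to axis ratio 4 (tested
against the complete elliptic integral); Knud–Thomsen within 1.2% up to
axis ratio 3 (tested against the Legendre closed form); both exact for
circles/spheres.

## Synthetic population

The generator stands in for a destructive water-displacement ground truth.
Each fruit is a star-shaped solid `r(u) = r_se(u)·(1 + λ·cos(m(φ−φ₀))·sin²θ)`
where `r_se` is the superellipsoid `|x/ax|^ε + |y/ay|^ε + |z/az|^ε = 1`.
The exponent ε controls how fully the fruit fills its bounding box
(ε = 2: exact ellipsoid; ε < 2: tapered, sub-ellipsoidal fill), and the
lobe term (amplitude ≤ 0.03, mode 2–4) adds azimuthal protrusions that
perturb silhouette extents while barely moving volume — exactly the
decoupling that defeats closed-form proxies.

The default population emulates a 150-fruit, two-variety supermarket
citrus stream with all four silhouette diameters in 50–88 mm:

| parameter | mandarin | sweet orange |
|---|---|---|
| mixture weight | 0.45 | 0.55 |
| largest diameter | 50 + 38·Beta(1.2, 3.2) mm | 50 + 38·Beta(4.0, 1.3) mm |
| oblateness (az/ax) | 0.84 | 0.97 |
| exponent ε | 2.00 + 0.15·t + N(0, 0.04) | 1.85 − 0.05·t − 0.30·t² + N(0, 0.04) |

with `t` the diameter scaled to [−1, 1] on the size range. Rationale: the
emulated study's printed extremes (smallest fruit ≈ 50 mm at 58.3 mL;
largest ≈ 88 mm at 287.9 mL) imply volume-to-extent ratios at or below
the ellipsoid factor π/6, and its two varieties motivate a mixture whose
members differ in size, oblateness and fill regime. The opposed,
curved size→ε trends make the dimension→volume map genuinely non-linear:
a linear model on log features cannot represent curvature in log-size or
the variety interaction, while boosted trees can — reproducing the
qualitative model ordering (proxy ≫ linear > single learners ≥ stack) of
the population being emulated. Aggregate statistics land at mean ≈
145–155 mL and SD ≈ 55–60 mL; the simulated maximum (≈ 250 mL) falls
short of the reference 287.9 mL because the tapered fill of the largest
fruit caps their volume — the binding design target was the overlap of
ranges, not the endpoints.

Measurement noise is multiplicative Gaussian with sd 1% per dimension
(no error model was available to copy; 1% matches sub-millimetre pixel
quantisation at the default 0.25–0.40 mm/px scales). Pixel views draw a
per-view scale factor from that range and round to integer pixels.

Numerics:

- **Volume oracle**: `V = (1/3)∮ r³ dΩ` by panelled Gauss–Legendre
  quadrature (two polar panels split at the equator, four azimuthal panels
  split at the axis kinks of `|·|^ε`; 128 × 192 nodes). Against the
  closed form `8·abc·Γ(1+1/ε)³/Γ(1+3/ε)` the error is below 10⁻⁶
  relative across the generator's ε range — comfortably inside the 10⁻⁴
  contract.
- **Silhouette extents**: exact (twice the semi-axes) for lobe-free
  shapes; for lobed shapes, a 121 × 241 direction grid followed by
  Nelder–Mead polish of each of the six coordinate extrema.
- **Rendering**: pixel-centre inside tests; the projection of a
  superellipsoid is the corresponding superellipse (exact 2-D test), and
  lobed shapes use an 81-step scan of the hidden axis. The requested
  mm-per-px is snapped so the marker rasterises to an exact integer pixel
  square, keeping the scene self-consistent with the calibration model.
- Determinism: one `numpy` Generator threaded explicitly through every
  sampling operation; identical seeds give bitwise-identical datasets.

What passing tests on this population do **not** show: robustness to
segmentation failures, lighting, occlusion or camera distortion (masks
are ideal), to shape families outside lobed superellipsoids (no conical
taper asymmetry between stem and blossom ends), or to variety mixes with
different statistics. The generator's realism claims are limited to
matching the emulated population's printed ranges and its qualitative
model-comparison structure.

## Preprocessing

- IQR capping with the conventional k = 1.5 fences on all numeric columns
  (features and, on training folds, the target); quartiles by linear
  interpolation (the numpy default), stated so the worked examples are
  exactly reproducible. Winsorisation and capping are one mechanism here —
  a single clipping to the Tukey fences — to avoid double-clipping
  ambiguity. Predictions are never capped.
- Strictly positive size-like features (lengths, areas, volumes,
  perimeters, surface area, interactions) are log-transformed after
  capping; ratios, eccentricities and sphericity stay on their natural
  scale. Transforms are fitted before selection (transform-then-select).
- Target: `y = log(1 + volume_mL)`, inverted with `exp(ŷ) − 1` before any
  metric; the log scale tames heteroscedastic error growth with fruit
  size.
- Cross-validation: k = 5 folds stratified over 5 empirical target
  quantile bins (round-robin within shuffled bins with a global counter,
  so fold sizes differ by at most one). Five bins keeps ≥ 6 training
  members per bin per fold at n = 150.

## Modelling

- Base learners and canonical grids (exhaustive search, 5-fold CV, MSE on
  the log target): classic gradient boosting over
  {200, 400} trees × lr {0.05, 0.1} × depth {4, 5} × subsample {0.8, 0.9}
  × column subsets {sqrt, log2} (32 candidates); depth-wise regularised
  boosting over {200, 400} × {0.01, 0.05, 0.1} × {4, 5, 6} × {0.8, 0.9} ×
  {0.8, 0.9} (72 candidates); the histogram leaf-wise learner runs with
  library defaults and a fixed seed. Ties in the grid search resolve to
  the simpler model (fewer trees, then shallower, then lower learning
  rate) by visiting candidates in that order and keeping the first
  minimum. A reduced grid preset exists for repeated studies; on datasets
  of this size the optimum sits inside it, and the multi-seed comparison
  study and acceptance script use it.
- Embedded selection: XGBoost importances on the transformed training
  fold; keep features strictly above the median importance. Strict
  inequality with 25 distinct importances keeps at most 12 features (in
  practice 11–12 here). A median rule that reports more than half the
  features surviving (e.g. 14 of 25) is not reproducible under a strict
  reading; this implementation keeps the strict rule and surfaces the
  count in its artifacts.
- Monotone constraints: predicted volume must be non-decreasing in each
  of the four raw dimensions and the mean diameter. The constraints are
  set per selected feature on the two families that support them
  (depth-wise and leaf-wise); the classic family has no such hook and is
  left unconstrained with a logged notice. Because the log transform is
  increasing, constraints on log features are equivalent to constraints
  on the raw scale.
- Stacking: each base learner's out-of-fold predictions on the training
  set form the meta-features; the Lasso meta-learner's penalty is chosen
  by internal CV on the same folds over a log-spaced grid 10⁻⁴–1 (no
  penalty value was available to copy); bases are then refit on the full
  training set. The out-of-fold contract (no meta-feature produced by a
  model that saw that row) is asserted structurally in the tests by
  refitting every fold from scratch and comparing bitwise.
- The whole pipeline — capping, transforms, selection, tuning, stacking —
  is refit inside each outer evaluation fold, the leakage-safe reading of
  per-fold selection; a shuffled-target null run (CV R² ≈ 0 required)
  guards against leakage through any fitted artifact.

## Evaluation

- Metrics on the original mL scale: MAE, MSE, RMSE = √MSE, R². Reports
  carry both MSE and RMSE with MSE as the headline column. R² for a
  constant truth vector is reported as undefined (None), not NaN.
- The comparison study evaluates, on identical folds (hash-checked): the
  best of the four geometric proxies (lowest MSE, no fitting), OLS on the
  same selected log-scale features, each base learner alone, and the
  stack.
- Wilcoxon signed-rank test on paired per-fruit out-of-fold absolute
  errors (n = 150 pairs — five paired fold means would be too few to
  resolve anything); zero differences dropped, exact null by dynamic
  programming over (possibly tied, doubled) ranks for n ≤ 25, normal
  approximation with tie correction above, two-sided doubled tail.
- Average precision uses all-points interpolation (the precision
  envelope integrated over recall), greedy score-ordered matching with
  each ground-truth box used at most once at IoU ≥ 0.5; classes without
  ground truth are excluded from the mean with a warning.

## Problem sizes used in the shipped experiments

Unit and property tests run on n = 80–150 populations; the distribution
check uses n = 1000; the model-comparison study runs 10 seeds at n = 150
with the reduced grids; the acceptance script runs one seed at n = 150.

## Known limitations

- The metrology stage assumes clean binary masks; no detector, no edge
  refinement, no camera model.
- The selection rule's strict median threshold caps the retained feature
  count at 12 of 25 by construction.
- Monotonicity is enforced on two of the three base families; the stack's
  combined prediction inherits it only to the extent the meta-weights on
  the unconstrained family allow.
- Synthetic realism is bounded as described above; absolute error levels
  on real fruit will differ even if the qualitative model ordering holds.
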