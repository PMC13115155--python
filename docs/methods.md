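# Methods

## Problem and model

Frozen pizza loses visual quality during storage mainly through color
change of the tomato-sauce layer (lycopene oxidation proceeds even below
freezing). The package treats the mean HSV saturation of the segmented
sauce region, `HSV_S_mean` (written S below, on the 8-bit 0–255 scale),
as the quality descriptor, and models two relationships on a storage
study of n samples imaged once each at known storage time t (days) and
temperature:

* **Kinetics.** S over time is described by a second-degree polynomial
  fitted by ordinary least squares, f(t) = β₀ + β₁t + β₂t². The
  quadratic is the smallest extension of a linear trend able to express
  the curvature of pigment-degradation kinetics while staying
  interpretable; the contribution of β₂ is assessed by the usual t-test
  (n − 3 degrees of freedom). Reported fit metrics are R² and RMSE with
  divisor n.
* **Acceptability.** Binary consumer acceptability y is modeled as
  P(y = 1 | t, S) = logistic(α₀ + α₁t + α₂S). Temperature is
  deliberately not a predictor: its effect on degradation is already
  integrated in the observed saturation, and it is kept only as grouping
  metadata. The saturation acceptability limit at a fixed time is the
  exact root of the linear predictor, S*(t) = −(α₀ + α₁t)/α₂, which is
  affine in t with slope −α₁/α₂; it is reported even outside [0, 255],
  flagged as out of scale.

Evaluation uses leave-one-out cross-validation (one fold per record,
fitted on the other n − 1; the held-out record never influences its own
prediction), accuracy at the 0.5 threshold and AUC as the Mann–Whitney
concordance probability with ties counted 0.5 (identical to trapezoidal
integration of the empirical ROC). Uncertainty of the probability-vs-S
curve at a fixed time is a percentile bootstrap over records (default
1000 resamples; single-class resamples are redrawn with a retry cap,
then flagged). A composite confidence score C = Σwₖcₖ/Σwₖ summarizes the
pipeline with sub-scores (R², accuracy, AUC) and default weights
(0.68, 0.25, 0.25); the score is computed literally from its definition,
never hard-coded.

## Segmentation pipeline

Four deterministic stages, each mask a subset of the previous one:

1. **Foreground.** A rectangle-initialized, iteratively refined
   two-class color segmentation: pixels outside the initialization
   rectangle are fixed background; in-rectangle pixels are reassigned
   between one full-covariance Gaussian color model per class for a
   capped number of iterations (default 5). The largest connected
   component is kept and interior holes filled. This plays the role of a
   GrabCut-style foreground extractor and is judged by its Dice overlap
   with ground truth, not by algorithm identity.
2. **Erosion** by a disk structuring element (default radius 5 px),
   with out-of-frame pixels counted as background.
3. **Circular crop**: intersection with a disk centered on the eroded
   mask's centroid with radius `crop_radius_fraction` × the mask's
   equal-area radius. Deriving center and radius from the mask (not the
   frame) keeps the crop centered on the product. The default fraction
   is 0.85: with the crust occupying the outer 15% of the product radius,
   0.85 × (eroded equivalent radius) lands just inside the crust
   boundary, excluding crust pixels (whose browning is unrelated to sauce
   state and whose tan hue would otherwise pass the red hue test) while
   discarding as little genuine sauce as possible.
4. **Sauce mask**: keep ROI pixels with hue in [0, 20] ∪ [160, 180]
   (half-degree scale; the high interval is the wrap-around red),
   saturation ≥ 60 and value ≥ 40, then morphological opening and closing
   with disk elements (default radius 3) and re-intersection with the
   ROI. The saturation/brightness floors and element sizes are
   engineering defaults — the imaging protocol does not dictate them —
   and all are configurable.

## Color conversions and features

HSV follows the 8-bit imaging convention H ∈ [0, 180) half-degrees,
S, V ∈ [0, 255], hue of achromatic pixels defined as 0 (hand-written,
since common libraries use unit-interval scales). CIELAB uses the
standard sRGB → linear RGB → XYZ (D65, 2° observer) → Lab path via
scikit-image. Moments are population moments (divisor n): image
statistics conventionally use the population form, and the choice is
fixed for reproducibility. Skewness m₃/m₂^1.5 and excess kurtosis
m₄/m₂² − 3 are defined as 0 when m₂ = 0. Hue is treated linearly — the
sauce mask confines hue to a narrow red band — with the 0/180 seam a
known limitation of the H-channel features only. Feature names are
frozen as `{space}_{channel}_{moment}`.

## Feature screening

Per (temperature × acceptability class) group with n ≥ 3, the Pearson
correlation of each feature with storage time is computed
(zero-variance inputs are reported as r = 0 and flagged undefined);
features are ranked by the mean signed r across groups, ties broken
alphabetically, with |r| averaging available as an option since either
aggregation is defensible. No significance testing or multiplicity
control is applied — screening is descriptive and the modeling stage
uses a single pre-declared feature.

## Synthetic data generator

`imgen` renders what the analysis assumes: a near-black board, a product
disk (radius 0.45 × frame, default 384×384 px), a tan crust annulus
(outer 15% of the radius) whose color would pass the red hue test — so
the crop stage is genuinely load-bearing — a sauce layer painted at a
controlled HSV color over 95% of the inner disk (a smooth random field
thresholded at a quantile), pale low-saturation cheese ellipses
occluding the sauce, and i.i.d. Gaussian sensor noise (default sd 3,
clipped to 8 bits). Ground-truth masks nest sauce ⊆ ROI ⊆ foreground by
construction, and with zero noise the mean saturation over the true
sauce mask reproduces the painted target to within 8-bit rounding (±1).

The default study has 36 samples: 18 per temperature (−12 °C abuse,
−18 °C correct storage) at times equally spaced on [0, 200] days.
Saturation targets follow quadratic trajectories
β(−12) = (140, 0.9, −0.0018) and β(−18) = (140, 0.45, −0.0009) with
per-sample noise sd 5. This split — divergent temperature trajectories,
small per-sample noise — is deliberate: it yields within-group
time–saturation correlations above 0.9 alongside a pooled
time-only quadratic R² near 0.65 (most pooled residual being
between-temperature divergence), which is the correlation structure a
two-temperature storage study of this kind exhibits. Labels are
Bernoulli with α = (−26, −0.01, 0.15): acceptability rises with
saturation (α₂ > 0), and the intercept places the 0.5 boundary so all
four temperature × class groups are populated. Per-sample jitter on
sauce value (sd 25) and hue (sd 3) emulates batch formulation and
lighting variability unrelated to storage; it is what makes the
generating feature `HSV_S_mean` — which is exactly invariant to value
and hue — the uniquely time-linked descriptor, while its Lab/RGB
surrogates decorrelate, as screening on real multi-batch data behaves.

What the generator does **not** emulate: frost or condensation, shading
and specular highlights, textured sauce/cheese surfaces, crust browning
kinetics, camera response nonlinearity, or RAW acquisition. Passing
tests therefore demonstrate correctness of the pipeline's logic and its
statistical machinery under controlled conditions, not segmentation
robustness on real photographs.

## Numerical choices

* Logistic fits use Newton/IRLS on internally standardized predictors,
  convergence when the log-likelihood changes by < 1e−10 (cap 100
  iterations), with a quadratic penalty of 1e−8 on standardized
  coefficients guarding complete separation; fits driven to the guard
  are flagged (|standardized coefficient| > 10), never silently
  accepted. Coefficients, standard errors and covariance are mapped back
  to the original scale. On separated data the penalized likelihood is
  extremely flat, so the iteration cap may be reached; the result is
  flagged both ways.
* OLS is delegated to statsmodels; RMSE (divisor n) and the zero-total-
  variance convention (R² = 0, flagged) are computed on top of it.
* Bootstrap bands are percentile 2.5/97.5 — the minimal reading of
  "bootstrap confidence interval"; BCa was not used.
* All stochastic operations take an explicit seed (default 42); scene
  and study generation are fully reproducible from their specs.
* Degenerate inputs fail loudly and early: empty masks raise a
  missing-region error carrying the sample id, rank-deficient designs
  and single-class labels are rejected with named causes, empty
  intermediate masks warn and propagate as empty rather than crash.

## Problem sizes in the shipped analyses

The default scene is 384 × 384 px (≈ 55k sauce pixels), the default
study 36 images; the test suite's Monte-Carlo checks use 500 replicate
kinetics fits, 200 replicate null logistic fits at n = 5000, and a
100-scene segmentation sweep. The acceptance script summarizes
segmentation over 60 scenes. These sizes give stable statistics
(binomial/Monte-Carlo error well inside the asserted bands) while
keeping a full run in minutes on one CPU.

## Known limitations

* The foreground model is a two-Gaussian approximation of a graph-cut
  segmenter; it relies on the dark, uniform background of the imaging
  protocol and would need spatial regularization for cluttered scenes.
* Hue statistics are linear, not circular (see above).
* The acceptability limit inherits the logistic model's linearity in
  (t, S); no kinetic (Arrhenius-type) temperature model is attempted,
  and survey-design statistics are out of scope.
* With small n and strong separation, LOOCV accuracy/AUC are optimistic
  point estimates; the bootstrap bands quantify curve uncertainty but
  not model-selection uncertainty.
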