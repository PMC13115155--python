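# saucelife

Image-based shelf-life analysis for frozen pizza: segment the
tomato-sauce region from top-down product photographs, quantify its
chromatic state, and model when consumers stop accepting the product.

The visual quality of multi-component frozen foods is driven largely by
the color of the tomato sauce: lycopene, the carotenoid behind tomato
redness, keeps oxidizing even at freezer temperatures, and consumers read
the resulting color shift as loss of freshness. `saucelife` implements
the full analysis pipeline that links that chromatic change to binary
consumer acceptability, for food scientists running storage studies and
for engineers building non-destructive quality monitors:

1. **Segmentation** — a rectangle-initialized, iteratively refined
   two-class color model separates the product from the dark imaging
   board; morphological erosion and an adaptive circular crop remove the
   crust annulus; dual hue-interval HSV thresholding (low-red 0–20 and
   wrap-around high-red 160–180 on the half-degree scale, with
   saturation/brightness floors and opening/closing cleanup) isolates the
   sauce.
2. **Features** — a 36-entry color-moment descriptor: mean, standard
   deviation, skewness and excess kurtosis of R, G, B; H, S, V; CIELAB
   L, a, b over the sauce pixels (9 channels × 4 moments).
3. **Screening** — Pearson correlation of every feature with storage
   time within each (temperature × acceptability) group, ranked by mean
   correlation; the mean HSV saturation `HSV_S_mean` = S is carried
   forward.
4. **Modeling** — quadratic saturation kinetics fitted by OLS,

       f(t) = β₀ + β₁ t + β₂ t²,

   and a logistic acceptability classifier in storage time and saturation,

       P(y = 1 | t, S) = 1 / (1 + exp(−(α₀ + α₁ t + α₂ S))).

5. **Evaluation & limits** — leave-one-out cross-validation pooled over
   all folds (accuracy at the 0.5 threshold, Mann–Whitney AUC),
   percentile-bootstrap bands for the probability curve at fixed times, a
   weighted composite confidence score C = Σwₖcₖ / Σwₖ over
   (R², accuracy, AUC), and closed-form inversion of the 0.5 crossing to
   a saturation acceptability limit S*(t) = −(α₀ + α₁ t)/α₂ — the end of
   primary shelf life expressed on the saturation scale.

Because storage-study photographs of this kind are not publicly
available, the package ships a first-class synthetic scene generator
(`saucelife.imgen`) that renders pizza-like images with pixel-exact
ground-truth masks, quadratic saturation trajectories and labels from a
known logistic model, so every stage of the pipeline is verifiable
against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
default synthetic design (36 samples, −12/−18 °C, 0–200 days):

```sh
python analysis/01_simulate_study.py
python analysis/02_segment_images.py
python analysis/03_extract_features.py
python analysis/04_screen_features.py
python analysis/05_fit_models.py
python analysis/06_evaluate_models.py
python analysis/07_acceptability_limits.py
```

which prints, among other things:

```
sauce Dice vs ground truth: median 0.965, min 0.962
       feature   mean_r  n_groups
    HSV_S_mean 0.940062         4
    LAB_b_mean 0.623109         4
quadratic kinetics: R2 = 0.664, RMSE = 18.18 (curvature p = 0.17)
LOOCV over 36 folds: accuracy 91.7% (33 correct), AUC 0.944
composite confidence score C = 0.777
saturation acceptability limits S* (P = 0.5):
   90 days: S* = 182.6
  150 days: S* = 175.6
  180 days: S* = 172.1
```

Reading these: the segmentation recovers the true sauce region almost
exactly (Dice 0.97); screening identifies the generating feature
`HSV_S_mean` as the strongest time-linked descriptor; time explains about
two-thirds of the pooled saturation variance (the rest is
between-temperature trajectory divergence plus noise); the classifier
separates acceptable from unacceptable samples well out-of-fold; and the
saturation level needed for 50% acceptance is traced per storage time.
All outputs land under `results/`.

The same pipeline is available as a CLI over a YAML config
(`saucelife simulate|segment|features|screen|fit|evaluate|report`), each
command writing a run manifest for traceability.

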