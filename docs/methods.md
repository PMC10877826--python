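# Methods

`milsurv` implements weakly supervised prognosis modelling for
whole-slide images (WSIs): a case is represented as bags of patch
embeddings at one or more magnifications, pooled by gated attention into
case-level embeddings, and mapped by a discrete-time hazard head to a
scalar risk score — the digital pathology signature (DPS). No pixel- or
region-level annotation is used; supervision is overall survival time
and status only.

## Pipeline

**Tissue segmentation.** The slide is downscaled by an integer factor
(default 8) and converted to HSV. Stained tissue has high saturation
against white glass, so the saturation channel is median-filtered
(3×3), thresholded with Otsu's method (with a floor of 0.05 so an
unstained slide yields an empty mask instead of a noise threshold),
morphologically closed (disk radius 2), and cleaned of connected
components and holes below `min_region_area` pixels (default 64 at the
working resolution). The procedure is fully deterministic. A slide with
no detectable stain produces an empty mask with a warning flag, not an
error — downstream tiling then simply returns no patches.

**Tiling.** Patches are 256×256 at the target magnification (5×, 10×,
20×), enumerated row-major over a regular grid with stride
`256·(1−overlap)`; coordinates are stored in level-0 pixel space as
half-open boxes (`w = h = 256·base_mag/target_mag`). A patch is kept
iff its tissue-mask coverage is at least `tissue_frac_min` (default
0.5 — the threshold balances tissue coverage against background
patches; it is not critical for solid tissue blocks). Overlap 0 is used
for training and evaluation; overlap 0.5 increases heatmap resolution
for visualization. Non-integral magnification ratios are handled by
reading the nearest adequate pyramid level and bilinear resampling to
256×256. Slides without magnification metadata are assumed to be 40× at
level 0 (warned, overridable).

**Patch encoding.** Every patch is mapped to a 1024-d embedding through
the `PatchEncoder` contract. The package ships `MockEncoder`, a
deterministic encoder that computes per-32×32-block colour statistics
(mean, variance, gradient energy; 576 numbers) and projects them to
1024 dimensions with a fixed seeded Gaussian matrix. It is intended for
testing and synthetic studies: it keeps distinct textures linearly
separable while requiring no pretrained weights. A pretrained CNN
backbone can be plugged in through the same contract (any encoder
producing finite 1024-d vectors); the package does not train or
fine-tune encoders.

## Model

For a bag of embeddings `f_1..f_B` at one magnification, the gated
attention weight of instance `k` is

    a_k = softmax_k( wᵀ( tanh(V f_k) ⊙ sigmoid(U f_k) ) ),

with independent parameters `V, U ∈ R^{L×D}`, `w ∈ R^L` per
magnification (`D = 1024`, hidden width `L = 256` by default, dropout
0.25 on the attention inputs during training; the softmax normalises
over the whole bag). The case embedding is `h = Σ_k a_k f_k`. Case
embeddings are concatenated in fixed scale order (5×, 10×, 20×), with
`(sex_code, z-scored age)` appended when clinical fusion is enabled
(sex: female = 1; age z-scored with training-fold mean/sd).

Follow-up time is discretised into `n` intervals (default 4) whose cut
points are the empirical quantiles of the *event* times in the training
fold, so every bin contains events. A fully connected layer with one
neuron per interval produces, through a sigmoid, discrete hazards
`p_t ∈ (0,1)`; the survival function is `S_t = Π_{τ≤t}(1−p_τ)` and

    DPS = −Σ_t S_t ∈ [−n, 0],

strictly increasing in every hazard (higher = worse prognosis).

**Loss.** Training minimises the discrete-time survival negative
log-likelihood with right censoring: an event in bin `t` contributes
`−log p_t − Σ_{τ<t} log(1−p_τ)`; a case censored in bin `t` contributes
`−Σ_{τ≤t} log(1−p_τ)`. Hazards are clamped to `[1e-7, 1−1e-7]` before
logs in the public loss function; the training path evaluates the same
likelihood on the head logits (log-sigmoid form) for numerical
stability. An optional `event_weight` up-weights uncensored cases
(default 1).

**Implementation.** The network is small, so it is implemented directly
on numpy arrays with hand-derived analytic gradients (softmax, gated
tanh/sigmoid branches, optional 1024→512 input reduction, hazard head)
and trained with Adam. The backward pass is verified against central
finite differences in the test suite. All randomness (initialisation,
dropout, shuffling) flows from a single seed; inference is
deterministic.

## Training protocol and regularisation

Cross-validation follows a random 1:1:1 three-fold split; the
training / validation / test roles rotate across three repeats so every
case receives exactly one out-of-fold DPS. Optimisation uses Adam
(lr 2e-4), batch size one case (bags vary in size), at most 50 epochs
with early stopping on validation loss (patience 10), restoring the
best parameters.

Two choices matter at cohort sizes of a few hundred cases against
1024-d embeddings:

* **Instance-feature centering.** The per-scale mean embedding of the
  training fold is subtracted inside the model (stored in the
  checkpoint). Without it, any non-centred component of the embedding
  distribution acts as a hidden bias: the early calibration gradient
  (hazards must move from their 0.5 initialisation toward the marginal
  event rates) pushes the head weights along that component, which can
  entangle calibration with discrimination and even invert the learned
  risk ordering before the bias terms catch up.

* **Strong decoupled weight decay (default 64).** With ~100 training
  cases the linear head can memorise each case's 1024-d noise
  fingerprint (training C-index above the generative optimum while
  held-out concordance stays at chance). The decoupled decay
  `lr·wd ≈ 1.3e-2` per step holds the fit near the ridge solution, which
  is close to the best linear read-out of a diffuse signal direction at
  this `n/D` ratio. Interpretation-oriented runs that train on the full
  cohort (no held-out evaluation) lower the decay (e.g. 1e-5): heavy
  decay collapses the attention logits toward uniform, and the residual
  attention orientation becomes arbitrary because the head can absorb
  the sign.

## Evaluation statistics

* **Harrell's C-index** — implemented directly (vectorised permissible
  pair counting: pairs where the earlier time is an event, time ties
  permissible only against a censored case; score ties count 0.5);
  cross-checked against `lifelines` in the tests. Higher DPS must
  predict shorter survival.
* **KM dichotomization** — score split at a percentile cutoff (default
  50), Kaplan-Meier curves, two-sided log-rank test, and univariate
  hazard ratio from a Cox fit (all thin wrappers over `lifelines`). The
  cut-off sweep repeats this over percentiles 5..95 (step 5), flagging
  (not failing) cutoffs that empty a group.
* **iAUC** — cumulative/dynamic time-dependent AUC with IPCW
  (`scikit-survival`), integrated with weights from the estimated event
  distribution over a horizon grid spanning the 10th–90th percentile of
  observed event times; 95% CI by case-level percentile bootstrap
  (default 1000 resamples, seeded). Note the definitional wedge against
  Harrell's C (an average of *incident*/dynamic AUCs): the two agree
  closely only for moderate effect sizes.
* **Continuous NRI** — per-case sign tally:
  `[P(up|event) − P(down|event)] + [P(down|nonevent) − P(up|nonevent)]`,
  zero changes counting neither way; bootstrap CI as above. In
  `run_experiment` the NRI compares a clinical-only Cox model (age, sex)
  against clinical + DPS for mortality by a horizon (default: median
  event time), excluding cases censored before the horizon.

## Interpretation

Heatmaps and top patches use the **raw attention logits**, rank-
normalised per slide to percentile scores in [0, 1] (average ranks for
ties; a single patch maps to 1.0). Softmax weights shrink with bag size
and are incomparable across slides; ranks are not. Top-k patches
(default 100) are sorted by raw score with row-major coordinate
tie-breaks; heatmaps paint each (downscaled) patch box with its
percentile score, averaging where overlapping patches meet, and
alpha-blend over the tissue thumbnail, leaving uncovered background
untouched.

## Synthetic data

`gen_feature_bags` emulates the weak-supervision setting with known
ground truth. Background instances are standard normal in 1024
dimensions. Each case carries a latent signal fraction
`φ_c ~ U(0, 2·signal_fraction)` (mean = `signal_fraction`), realised as
an exact instance count `round(φ_c·B)`; signal instances are
mean-shifted by `signal_shift` along a fixed seeded unit direction (one
independent direction and independent noise per magnification, sharing
the same latent `φ_c`, so multiple scales are genuinely complementary
noisy views). The per-case log hazard ratio is

    r_c = effect_beta · (φ_c − mean φ) / sd(φ),

i.e. `effect_beta` is the log hazard ratio per standard deviation of the
case-level signal burden — the usual simulation convention that keeps
the effect size interpretable regardless of the fraction scale;
`effect_beta = 0` makes survival exactly independent of the bags.
Survival times are proportional-hazards exponential
(`λ_c = λ₀·e^{r_c}`, baseline median 36 months; Weibull shape exposed),
and censoring is uniform on `[0, c_max]` with `c_max` solved by
bisection so the expected censored proportion equals `censor_rate`
given the realised event times. Clinical covariates are drawn
independently (no confounding).

`gen_mock_slide` draws pink-textured elliptical tissue blobs on a white
background, optionally with a rectangular "risk region" filled with a
high-frequency checker texture (both tones well saturated so
segmentation retains them), returning full-resolution ground-truth
tissue and risk masks. `gen_slide_cohort` varies the risk-region area
fraction across slides and drives survival from its z-score, so
attention localization can be validated against known masks after
running the genuine segmentation → tiling → encoding pipeline.

**What the fixtures do and do not show.** The generator plants a
single-direction mean shift in isotropic noise. Recovering that
direction from case-level supervision requires, for ridge-class
learners, roughly `n_train · SNR² ≳ D`, where SNR is the per-case
signal-to-noise of the bag mean (`SNR ≈ signal_shift·sd(φ)·√B`). At a
diffuse operating point (e.g. `signal_fraction 0.1`, `signal_shift 2`,
`B 50`, training folds of ~100 cases) the planted signal is
information-limited: even scoring cases with the *true* direction
caps the C-index near 0.73, and no learner can reach it from the data —
such settings serve as stress references, not performance targets. The
package's desk-scale demonstration point (`signal_fraction 0.4`,
`signal_shift 3`, 300 cases) is comfortably recoverable (pooled
out-of-fold C-index ≈ 0.82 vs generative optimum ≈ 0.84). Real H&E
embeddings are anisotropic and signal-rich in comparison; passing these
synthetic checks validates the machinery (formulas, protocol,
statistics), not clinical performance.

## Problem sizes and numerical choices

Test and demonstration runs are sized for a single CPU: the main
cohorts use 300 cases × 50 instances (single scale), the multi-scale
fusion study 120 cases × 20 instances × 3 scales over 3 seeds
(attention width 128, 20 epochs), and the localization study 24 mock
slides of 1536 px at 20×. Quantile cut points use linear interpolation
(`numpy.quantile`); degenerate grids (fewer distinct event times than
bins) raise with a suggestion to lower `n`. Attention softmax and the
likelihood are evaluated in max-shifted / log-sigmoid form. Bootstrap
replicates that lose an outcome class or all events are skipped, not
imputed.

## Limitations

Attention pooling discards the spatial arrangement of patches; the
model sees bag composition only. The discrete-hazard likelihood is the
standard cross-entropy-over-hazards form without an additional ranking
term. The mock encoder is a statistics projection, not a learned
representation; conclusions about real WSIs require a pretrained
backbone behind the encoder contract and cohorts far larger than the
synthetic demonstrations. TMA spots are treated as ordinary small
slides; stain normalisation and artifact detection are out of scope.
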