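# Methods

## The representation pipeline

A slide is an ordered bag of fixed-size RGB patches with grid coordinates.
The pipeline assumes a *patch scorer*: a CNN that (a) emits a class
probability `P_C` per patch and (b) exposes one internal convolutional
layer — its post-ReLU activation maps `A^m ∈ R^{H×W}`, m = 1..M, and the
gradients `∂P_C/∂A^m_ij` obtained by back-propagation.  Any model honouring
this contract plugs in; the default is a small three-block CNN whose last
conv layer (post-ReLU) is exposed.

Stages, in execution order:

1. **Top-K selection.**  Patches are ranked by `P_C`; ties broken by higher
   mean exposed activation, then by patch index (so the ranking is a total
   order and the pipeline is invariant to patch input order).  `K` is a
   hyper-parameter; 50 is the package default for realistic slide sizes, the
   desk-scale experiments use 16.
2. **Importance weights.**  `α_m = ReLU(Σ_ij ∂P_C/∂A^m_ij)`.  The ReLU is
   applied to the per-map *summed gradient*, eliminating negatively-weighted
   maps before combination.  Original gradient-weighted class-activation
   mapping instead averages gradients per map and rectifies the combined
   map; both variants are available (`average_importance`,
   `rectify_feature_map`), the modified form is the default and `α` uses the
   raw sum (no 1/(H·W) factor).
3. **Class feature map and sorted flattening.**  `T_ij = Σ_m α_m A^m_ij`
   (no second ReLU — with post-ReLU activations and non-negative `α`, `T` is
   already non-negative), flattened and sorted descending into
   `F ∈ R^{H·W}`.  Sorting discards *where* activation occurred inside the
   patch and keeps *how much, at what rank* — what makes maps of different
   patches comparable row-wise.
4. **Aggregation.**  The K vectors are stacked and rows sorted by descending
   row sum (stable sort; ties keep the selection order).  Slides with fewer
   than K patches are zero-padded at the bottom; `pad_count` and per-row
   patch provenance are retained.  No per-map normalization is applied:
   absolute intensity is meaningful across slides (a high-burden slide has a
   globally brighter map), and cohort-level rescaling would be the user's
   deliberate choice.

The gradient target is the post-sigmoid/softmax probability (a config switch
selects the pre-activation logit).  For scorers with a scalar
regression/survival head, ranking uses that scalar directly.

## Slide-level models

The slide CNN consumes `1×K×(H·W)` maps: three conv(64, 3×3) + pool(2×2)
blocks, flatten, dense(1024, ReLU), then a task head — sigmoid (binary
cross-entropy), softmax (cross-entropy), or linear (Cox negative log partial
likelihood, or OLS).  Max pooling is the default; the architecture
description we follow mentions average pooling in one place and max pooling
in another, and we read the structural statement ("convolutional and
max-pooling layers") as authoritative, with `pool_kind="avg"` available.

The Cox loss is `−(1/D) Σ_{i:event} [r_i − log Σ_{t_j ≥ t_i} exp(r_j)]` with
the Breslow convention for tied event times and normalization by the event
count D (batch-size stability).  Cox training is full-batch only, so every
risk set is complete; the config refuses mini-batches for the cox task.
Harrell's concordance counts a pair (i, j) as admissible when `t_i < t_j`
and subject i had the event; risk ties score 0.5.  Pairs with exactly tied
times are not comparable under this definition (some library
implementations count them; lifelines is used as a cross-check only on
tie-free data where the definitions coincide).

Post-hoc pooling baselines (`baseline_mean`, `baseline_max`) reduce the same
patch scores to a slide scalar for comparison.

## The numpy CNN engine

No deep-learning runtime is a dependency; `hipomap.nn` implements the
required layers (3×3 same-convolution via one GEMM per kernel offset,
max/avg pooling with Keras-style cropping of trailing rows, dense, global
average pooling), SGD/momentum and Adam, and a generic training loop.  A
`Sequential` forward pass caches every layer output and a backward pass
records the gradient at every layer output — that hook *is* the Grad-CAM
mechanism.  All parameters derive from a single `numpy` Generator seed;
training is deterministic on a fixed BLAS.  Every layer's backward pass and
all loss gradients are validated against central finite differences in the
test suite (float64 models; the pipelines run float32 for speed).

## Synthetic cohort generator

The generator is the package's study-condition definition, not a test
convenience.  A slide is a bag of 64×64 patches (size configurable,
down from 299×299 real-slide tiles so the full pipeline trains on one CPU):

* **background** — low-frequency Gaussian blobs (4×4 noise cells upsampled,
  amplitude 0.15) + pixel noise (sd 0.10), mimicking loosely structured
  stroma;
* **lesion** — oriented sinusoidal stripes (8 cycles/patch, amplitude 0.15,
  random orientation; class-specific orientations in subtype mode) + the
  same noise.  Base intensity (0.60) is identical for both families, so
  brightness alone carries no signal.

Three slide-level nuisance factors emulate the parts of real cohorts that
break naive score pooling while leaving within-slide ranking informative:

* a global intensity offset per slide (sd 0.05) — staining/exposure
  variation;
* a per-slide severity multiplier (uniform 0.5–1.3) scaling all striped
  tissue of the slide — faint vs. florid disease; within a slide, lesions
  always remain stronger than confounders;
* a per-slide confounder load: a Beta-distributed fraction (mean 0.15,
  concentration 1.2) of background patches carry weak stripes at 0.6× lesion
  amplitude — inflammation/fibrosis-like tissue that draws intermediate
  scores; plus a per-slide noise multiplier (uniform 0.7–1.6) for scan
  quality.

Positive slides receive `round(lesion_fraction × n_patches)` lesion patches
with a floor of one (signal always exists); negatives receive none.
Survival times are exponential with rate
`exp(hazard_coef × burden) / baseline_scale`, burden being the slide's
lesion-patch fraction — proportional hazards by construction, matching the
Cox loss under test.  Censoring is independent exponential with a single
rate calibrated by root finding so the expected censored fraction equals
`censoring_rate`.  Cohorts are byte-reproducible functions of (spec, seed)
via a spawned seed tree.

What the generator does **not** emulate: H&E color statistics and stain
chemistry, pyramidal resolution levels, spatial correlation between
neighbouring patches, artifact classes (folds, pen marks), and realistic
nuclear morphology.  Passing benchmarks on these cohorts therefore
demonstrates the pipeline's mechanics — ranking fidelity, representation
structure, survival-signal recovery — not clinical-grade performance on real
slides.

## Benchmark experiments (`hipomap.experiments`)

* **Classification**: 100 positive + 100 negative slides, 12–24 patches
  each, lesion fraction 0.1 (one or two lesion patches per positive slide),
  stratified 75/25 split.  The patch scorer (10 epochs, Adam 1e-3) trains on
  at most 2,000 patches from training slides (all lesion patches, background
  subsampled).  Maps use K = 16; the slide CNN trains 40 epochs (Adam 1e-3,
  batch 32).  Reported: held-out AUC, mean/max pooling AUCs on the same
  scores, and top-K fidelity — the fraction of top-k selected patches on
  positive slides that are true lesions, with k = the slide's true lesion
  count (precision at the lesion count; with only 1–2 lesions per slide,
  precision at a fixed large K would be bounded by k/K rather than by
  ranking quality).
* **Survival**: 150 tumour-free + 150 high-burden (lesion fraction 1.0)
  slides — the maximal-contrast design for a burden-driven hazard —
  log-hazard 2, baseline scale 60 months, 30% censoring; scorer transferred
  from the classification cohort; Cox head trained full-batch 60 epochs
  (SGD 0.01, momentum 0.9).  Note an intrinsic ceiling: under proportional
  hazards the probability that the shorter-lived of a pair is the
  higher-risk one is HR/(1+HR); with burden ∈ {0,1} and log-hazard 2 the
  between-group concordance is e²/(1+e²) ≈ 0.88 and within-group pairs are
  coin flips, so even the *true* risk scores an expected c-index of ≈ 0.69.
  Measured held-out values near or above 0.7 are at the ceiling, not short
  of it.
* **Survival regression**: the uncensored subset, OLS on z-scored months
  (un-scaled for metrics), 60 epochs.  Exponential survival noise dominates
  here — the between-group means explain only ≈ a quarter of the total
  variance — so out-of-sample R² is small and can be negative on the ~40
  uncensored test slides; the reported RMSE/R² are honest noise-dominated
  values, not a pipeline defect.

## Numerical and design choices

* Tissue detection: Otsu threshold on a Gaussian-blurred grayscale
  (sigma 2 px default); contrast-free images fall back to a fixed 0.8
  threshold so blank tiles yield empty masks.  Patch grid: top-left origin,
  half-open intervals, trailing partial tiles dropped; patches kept at ≥20%
  tissue.  Color normalization is Reinhard-style per-channel mean/sd
  transfer in RGB (LAB optional), applied patch-wise after extraction.
* Row-sum ties in aggregation: stable sort preserving selection order.
* Slides with fewer than K patches: zero-padding, with `pad_count` kept for
  masking rather than silently shrinking the matrix.
* Stratified splits use largest-remainder quotas per class with a seeded
  shuffle; remainders go to the splits with the largest fractional claim.
* All file writes are atomic (temp file + rename); manifests are UTF-8 TSV
  with empty string for missing values.
* Maps persist as float32 `.npy` + JSON sidecar, with TSV and fixed-scale
  8-bit PNG exports (fixed scale so heatmap intensity stays comparable
  across slides).

## Known limitations

* The engine is CPU-bound numpy; it is sized for desk-scale experiments,
  not for training on hundreds of thousands of 299×299 patches.
* The default scorer is a small generic CNN; reproducing published
  texture-specialist backbones is out of scope — any scorer meeting the
  activation/gradient contract can replace it.
* Pyramidal WSI formats are not decoded; `extract` consumes plain RGB
  images (an adapter yielding RGB regions can front-end it).
* Multi-class subtype mode encodes class identity in stripe orientation
  only; it exercises the softmax path, not realistic subtype morphology.
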