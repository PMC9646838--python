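# hipomap

Fixed-size representation maps for whole-slide histopathology images, with
slide-level classification, Cox survival analysis and survival regression on
top of them.

## The problem

A digitized whole-slide image (WSI) is far too large for a CNN to consume
directly, so it is analyzed as a bag of fixed-size patches — but the bag has a
different size and shape for every slide, while most clinical questions
(tumour vs. non-tumour, subtype, prognosis) need exactly one answer per
slide.  Common fixes either pool patch scores post hoc (mean, max, histogram),
which throws away everything except a scalar per patch, or use recurrent /
attention aggregators that must be re-engineered per task.

`hipomap` implements a task-independent alternative: convert every slide into
one matrix of fixed shape, then let a small CNN do any slide-level task on
that matrix.  It is aimed at computational-pathology researchers who have (or
can train) a patch-level scoring CNN and want slide-level models without
pixel-level annotation.

## The representation

Given a patch-scoring CNN that exposes an internal convolutional layer with
activation maps `A^m ∈ R^{H×W}` (m = 1..M) and the class objective `P_C`:

1. **Top-K selection.** Every patch gets a predictive score from the scorer;
   the K highest-scoring patches are kept (score ties broken by higher mean
   exposed activation, then patch index).
2. **Patch representation.** For each selected patch, each activation map
   receives an importance weight

       α_m = ReLU( Σ_i Σ_j ∂P_C / ∂A^m_ij ),

   i.e. negatively-weighted maps are eliminated *before* combination (a
   deliberate departure from original Grad-CAM, which rectifies after).  The
   class feature map `T_ij = Σ_m α_m A^m_ij` is flattened and sorted in
   descending order into a vector `F` of length H·W.
3. **Aggregation.** The K vectors are stacked into `X ∈ R^{K×(H·W)}` and the
   rows sorted by descending row sum, so the most activated patches sit on
   top.  Slides with fewer than K patches are zero-padded.

Every slide, regardless of size, yields the same `K×(H·W)` matrix; a small
CNN (three conv/max-pool blocks of 64 3×3 kernels, a 1024-unit dense layer,
and a sigmoid / softmax / linear head) is then trained on the matrices with
cross-entropy, the Cox negative log partial likelihood (Breslow ties), or
ordinary least squares.

Because no deep-learning runtime is a dependency, the package ships its own
compact numpy CNN engine (`hipomap.nn`) with explicit backpropagation — which
also provides the gradients w.r.t. internal activations that step 2 needs.
Every layer's gradients are verified against finite differences in the test
suite.

## Worked example

A synthetic cohort stands in for real slides: positive slides hide a minority
of striped "lesion" patches among blobby "background" patches.

```python
import numpy as np
from hipomap import (SyntheticCohortSpec, TextureParams, generate_cohort,
                     train_patch_model, score_patches, slide_to_hipomap,
                     rank_top_k, baseline_mean)

textures = TextureParams(confounder_fraction=0.0, severity_range=(1.0, 1.0),
                         noise_multiplier_range=(1.0, 1.0))
spec = SyntheticCohortSpec(n_slides_pos=10, n_slides_neg=10,
                           patches_per_slide_range=(6, 10),
                           lesion_fraction=0.4, patch_size=32,
                           texture_params=textures, seed=7)
slides = generate_cohort(spec)

patches = np.concatenate([s.patch_array() for s in slides])
labels = [int(t) for s in slides for t in s.patch_truth]
scorer = train_patch_model(patches, labels, epochs=25, seed=11)

slide = slides[-1]                      # a positive slide
scores = score_patches(scorer, slide, class_index=1)
top3 = rank_top_k(scores, 3)
print("slide:", slide.slide_id, "| patches:", slide.n_patches,
      "| true lesions:", int(np.sum(slide.patch_truth)))
print("top-3 patches:", top3, "| lesion?", [slide.patch_truth[i] for i in top3])
print("mean patch score:", round(baseline_mean(scores), 3))

hm = slide_to_hipomap(slide, scorer, class_index=1, k=8)
print("map shape:", hm.X.shape, "| pad rows:", hm.pad_count)
print("row sums:", np.round(hm.X.sum(axis=1), 2))
```

prints

```
slide: pos_0009 | patches: 8 | true lesions: 3
top-3 patches: [1, 4, 0] | lesion? [True, True, True]
mean patch score: 0.19
map shape: (8, 16) | pad rows: 0
row sums: [3.33 2.09 1.39 0.71 0.66 0.57 0.55 0.54]
```

The three top-ranked patches are exactly the three lesion patches, and the
representation matrix shows the signature a slide-level CNN learns from: a
few bright, high-sum rows above a low background plateau — information the
0.19 pooled mean score has already discarded.

The same pipeline is available as a CLI (`hipomap simulate / extract /
train-patch / score / build / train / predict / evaluate / k-sweep`); run
`hipomap --help` for details.  `extract` tiles plain RGB slide images into
tissue patches (Gaussian-blur + Otsu tissue mask, ≥20% tissue per patch by
default, optional Reinhard-style reference color normalization).

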