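"""End-to-end experiments on synthetic cohorts.

This module fixes the study conditions for the package's reproducible
benchmark runs and wires the full pipeline together: generate a cohort,
train the patch scorer on the training split, build one representation map
per slide, train the slide CNN, and report held-out metrics next to the
post-hoc pooling baselines.

Conditions
----------
* Classification: 100 positive / 100 negative slides of 12-24 patches
  (64 px), lesion fraction 0.1 — so a positive slide hides only one or two
  lesion patches among background.  Maps use K = 16.
* Survival: 150 tumour-free slides and 150 high-burden slides (lesion
  fraction 1.0), log-hazard 2 per unit burden, 30% censoring.  The patch
  scorer is transferred from the classification cohort; the slide CNN is
  retrained with the Cox partial-likelihood loss (and, on the uncensored
  subset, with the least-squares loss for survival regression).

Background patches include a minority of weak-striped "confounder" patches
(mimicking inflammation or fibrosis regions that draw intermediate scores
from a real scorer), and every slide carries a small global intensity
offset.  Both features leave the within-slide score ranking informative
while adding exactly the kind of slide-level score noise that post-hoc
pooling is sensitive to.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import manifest as mf
from .cohort import Slide, SyntheticCohortSpec, generate_cohort, generate_survival
from .core import slide_to_hipomap
from .scoring import PatchCNN, score_patches, train_patch_model
from .tasks import (SlideModelConfig, baseline_max, baseline_mean, evaluate,
                    train_slide_model)

__all__ = [
    "classification_spec",
    "survival_spec",
    "build_patch_training_set",
    "top_k_lesion_precision",
    "run_classification",
    "run_survival",
    "MAP_K",
]

log = logging.getLogger(__name__)

#: top-patch count used for the desk-scale experiment maps
MAP_K = 16

#: cap on the number of patches used to train the patch scorer
PATCH_TRAINING_BUDGET = 2000


def classification_spec(seed: int) -> SyntheticCohortSpec:
    return SyntheticCohortSpec(
        n_slides_pos=100, n_slides_neg=100,
        patches_per_slide_range=(12, 24), lesion_fraction=0.1,
        patch_size=64, seed=seed)


def survival_spec(seed: int) -> SyntheticCohortSpec:
    # burden is bimodal (0 vs 1): tumour-free versus high-burden slides,
    # the maximal-contrast design for a burden-driven proportional hazard
    return SyntheticCohortSpec(
        n_slides_pos=150, n_slides_neg=150,
        patches_per_slide_range=(12, 24), lesion_fraction=1.0,
        patch_size=64, hazard_coef=2.0, baseline_scale=60.0,
        censoring_rate=0.3, seed=seed)


def _split_ids(slides: list[Slide], seed: int,
               fractions=(0.75, 0.25)) -> tuple[list[str], list[str]]:
    df = pd.DataFrame({
        "slide_id": [s.slide_id for s in slides],
        "path": [s.slide_id for s in slides],
        "label": [s.label for s in slides],
    })
    man = mf.stratified_split(mf.CohortManifest(df), fractions, seed=seed)
    train = man.df.loc[man.df["split"] == "train", "slide_id"].tolist()
    test = man.df.loc[man.df["split"] == "test", "slide_id"].tolist()
    return train, test


def build_patch_training_set(slides: list[Slide], seed: int,
                             budget: int = PATCH_TRAINING_BUDGET):
    """Labeled patch pool: every lesion patch, background subsampled to fill
    the budget."""
    lesions, backgrounds = [], []
    for s in slides:
        arr = s.patch_array()
        for i, truth in enumerate(s.patch_truth):
            (lesions if truth else backgrounds).append(arr[i])
    rng = np.random.default_rng(seed)
    n_bg = min(len(backgrounds), max(budget - len(lesions), len(lesions)))
    keep = rng.choice(len(backgrounds), size=n_bg, replace=False)
    x = np.stack(lesions + [backgrounds[i] for i in keep])
    y = np.array([1] * len(lesions) + [0] * n_bg)
    return x, y


def top_k_lesion_precision(model: PatchCNN, slides: list[Slide],
                           class_index: int = 1) -> float:
    """Fraction of top-k selected patches that are true lesions, pooled over
    positive slides, with k = each slide's true lesion count."""
    from .core import rank_top_k
    hits, total = 0, 0
    for s in slides:
        if s.label in (None, 0):
            continue
        k = int(np.sum(s.patch_truth))
        if k == 0:
            continue
        selected = rank_top_k(score_patches(model, s, class_index), k)
        hits += sum(1 for i in selected if s.patch_truth[i])
        total += k
    if total == 0:
        raise ValueError("no positive slides with lesion patches")
    return hits / total


def run_classification(seed: int) -> tuple[dict[str, float], PatchCNN]:
    """Binary slide classification with map-CNN vs post-hoc pooling.

    Returns the metric dict and the trained patch scorer (reused by the
    survival experiment, mirroring the transfer of a pretrained backbone
    between cohorts).
    """
    spec = classification_spec(seed)
    slides = generate_cohort(spec)
    by_id = {s.slide_id: s for s in slides}
    train_ids, test_ids = _split_ids(slides, seed + 1)

    x, y = build_patch_training_set([by_id[i] for i in train_ids], seed + 2)
    model = train_patch_model(x, y, epochs=10, learning_rate=1e-3,
                              seed=seed + 3)
    train_acc = float(np.mean((model.class_prob(x, 1) > 0.5) == (y == 1)))
    log.info("patch scorer: %d patches, training accuracy %.3f", len(y), train_acc)

    scores = {sid: score_patches(model, by_id[sid], 1) for sid in by_id}
    maps = {sid: slide_to_hipomap(by_id[sid], model, class_index=1, k=MAP_K,
                                  scores=scores[sid])
            for sid in by_id}

    config = SlideModelConfig(task="binary", epochs=40, batch_size=32,
                              learning_rate=1e-3, seed=seed + 4)
    slide_model = train_slide_model(
        [maps[i] for i in train_ids],
        [by_id[i].label for i in train_ids], config)

    truth = [by_id[i].label for i in test_ids]
    preds = slide_model.predict([maps[i] for i in test_ids])
    results = {
        "patch_train_accuracy": train_acc,
        "test_auc": evaluate(preds, truth, "binary")["auc"],
        "baseline_mean_auc": evaluate(
            [baseline_mean(scores[i]) for i in test_ids], truth, "binary")["auc"],
        "baseline_max_auc": evaluate(
            [baseline_max(scores[i]) for i in test_ids], truth, "binary")["auc"],
        "topk_lesion_precision": top_k_lesion_precision(model, slides),
        "n_test_slides": len(test_ids),
    }
    log.info("classification: %s", results)
    return results, model


def run_survival(seed: int, patch_model: PatchCNN | None = None) -> dict[str, float]:
    """Cox survival analysis and survival regression on representation maps."""
    spec = survival_spec(seed + 10)
    slides = generate_cohort(spec)
    generate_survival(slides, spec)
    by_id = {s.slide_id: s for s in slides}
    if patch_model is None:
        x, y = build_patch_training_set(slides, seed + 12)
        patch_model = train_patch_model(x, y, epochs=10, seed=seed + 13)

    maps = {s.slide_id: slide_to_hipomap(s, patch_model, class_index=1, k=MAP_K)
            for s in slides}
    train_ids, test_ids = _split_ids(slides, seed + 11)

    cox_cfg = SlideModelConfig(task="cox", epochs=60, batch_size=None,
                               optimizer="sgd", learning_rate=0.01,
                               seed=seed + 14)
    cox_model = train_slide_model(
        [maps[i] for i in train_ids],
        (np.array([by_id[i].time for i in train_ids]),
         np.array([by_id[i].event for i in train_ids])), cox_cfg)
    risk = cox_model.predict([maps[i] for i in test_ids])
    c_index = evaluate(risk, (np.array([by_id[i].time for i in test_ids]),
                              np.array([by_id[i].event for i in test_ids])),
                       "cox")["c_index"]

    # survival regression on the uncensored subset, months z-scored for
    # optimisation and mapped back before computing the metrics
    reg_train = [i for i in train_ids if by_id[i].event == 1]
    reg_test = [i for i in test_ids if by_id[i].event == 1]
    t_train = np.array([by_id[i].time for i in reg_train])
    mu, sd = t_train.mean(), t_train.std()
    reg_cfg = SlideModelConfig(task="regression", epochs=60, batch_size=32,
                               learning_rate=1e-3, seed=seed + 15)
    reg_model = train_slide_model([maps[i] for i in reg_train],
                                  (t_train - mu) / sd, reg_cfg)
    pred_months = reg_model.predict([maps[i] for i in reg_test]) * sd + mu
    reg_metrics = evaluate(pred_months,
                           np.array([by_id[i].time for i in reg_test]),
                           "regression")
    results = {
        "c_index": c_index,
        "cox_final_train_loss": cox_model.training_history[-1],
        "regression_rmse_months": reg_metrics["rmse"],
        "regression_r2": reg_metrics["r2"],
        "observed_censoring_rate": float(
            1 - np.mean([s.event for s in slides])),
        "n_test_slides": len(test_ids),
        "n_regression_test_slides": len(reg_test),
    }
    log.info("survival: %s", results)
    return results
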