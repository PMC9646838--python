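"""Fixed-size slide representation maps from top-K patches.

The pipeline converts a slide — an arbitrary-size bag of scored patches —
into one K×(H·W) matrix:

1. *top-K selection*: patches are ranked by predictive score, ties broken by
   higher mean exposed activation, then by original patch index;
2. *patch representation*: for each selected patch, every exposed activation
   map m receives an importance weight α_m = ReLU(Σ_ij ∂P_C/∂A^m_ij).  Note
   the ReLU clamps the per-map *summed gradient* — negatively-weighted maps
   are eliminated before combination, rather than rectifying the combined
   map as original gradient-weighted class-activation mapping does.  The
   class feature map T_ij = Σ_m α_m A^m_ij is flattened and sorted in
   descending order into the vector F of length H·W;
3. *aggregation*: the K vectors are stacked and the rows sorted by
   descending row sum, so the most activated patch representations sit at
   the top.  Slides with fewer than K patches are zero-padded at the bottom
   and the pad count recorded.

Because every slide yields the same K×(H·W) shape, the maps can be consumed
directly by a small CNN for slide-level tasks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .cohort import Slide
from .scoring import ActivationBundle, PatchScore, activation_bundles, score_patches

__all__ = [
    "DEFAULT_K",
    "ImportanceVector",
    "ClassFeatureMap",
    "PatchRepresentation",
    "HipoMap",
    "rank_top_k",
    "compute_importance",
    "class_feature_map",
    "patch_representation",
    "build_hipomap",
    "slide_to_hipomap",
    "save_hipomap",
    "load_hipomap",
    "hipomap_to_tsv",
    "hipomap_to_png",
]

#: default number of top patches per slide
DEFAULT_K = 50


@dataclass(frozen=True)
class ImportanceVector:
    """Per-activation-map importance weights α_m ≥ 0."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        if self.alpha.ndim != 1:
            raise ValueError("alpha must be one-dimensional")
        if np.any(self.alpha < 0):
            raise ValueError("importance scores must be non-negative")


@dataclass(frozen=True)
class ClassFeatureMap:
    """T_ij = Σ_m α_m A^m_ij for one patch."""

    T: np.ndarray

    def __post_init__(self) -> None:
        if self.T.ndim != 2:
            raise ValueError("class feature map must be (H, W)")


@dataclass(frozen=True)
class PatchRepresentation:
    """Length-(H·W) non-increasing vector F for one patch."""

    F: np.ndarray

    def __post_init__(self) -> None:
        if self.F.ndim != 1:
            raise ValueError("patch representation must be one-dimensional")
        if np.any(np.diff(self.F) > 0):
            raise ValueError("patch representation must be non-increasing")


@dataclass
class HipoMap:
    """The K×(H·W) slide representation matrix with provenance."""

    X: np.ndarray
    K: int
    slide_id: str = ""
    row_patch_indices: list[int] = field(default_factory=list)  # -1 = pad row
    pad_count: int = 0
    feature_shape: tuple[int, int] | None = None  # (H, W) of the feature maps

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.K:
            raise ValueError(f"map has {self.X.shape[0]} rows, expected K={self.K}")


# ---------------------------------------------------------------------------
# stage 1: top-K selection
# ---------------------------------------------------------------------------


def rank_top_k(scores: Sequence[PatchScore], k: int) -> list[int]:
    """Indices of the top-``k`` patches.

    Ordering: predictive score descending, then mean exposed activation
    descending (the tie rule), then patch index ascending.  Returns
    ``min(k, n)`` indices.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    ranked = sorted(scores, key=lambda s: (-s.prob, -s.mean_activation, s.patch_index))
    return [s.patch_index for s in ranked[:k]]


# ---------------------------------------------------------------------------
# stage 2: patch representation
# ---------------------------------------------------------------------------


def compute_importance(bundle: ActivationBundle,
                       average: bool = False) -> ImportanceVector:
    """α_m = ReLU(Σ_ij ∂P_C/∂A^m_ij) for each exposed map.

    ``average=True`` divides the sum by H·W (the original
    global-average-pooled weighting) before the ReLU clamp.
    """
    sums = bundle.gradients.sum(axis=(1, 2))
    if average:
        h, w = bundle.gradients.shape[1:]
        sums = sums / (h * w)
    return ImportanceVector(np.maximum(sums, 0.0))


def class_feature_map(alpha: ImportanceVector, bundle: ActivationBundle,
                      rectify: bool = False) -> ClassFeatureMap:
    """T = Σ_m α_m A^m.  No rectification of T by default — negative maps
    were already eliminated at the importance stage.  ``rectify=True``
    restores the original behaviour (ReLU on T) for comparison runs."""
    if alpha.alpha.shape[0] != bundle.activations.shape[0]:
        raise ValueError(
            f"alpha has {alpha.alpha.shape[0]} entries for "
            f"{bundle.activations.shape[0]} activation maps")
    T = np.tensordot(alpha.alpha, bundle.activations, axes=(0, 0))
    if rectify:
        T = np.maximum(T, 0.0)
    return ClassFeatureMap(T)


def patch_representation(fmap: ClassFeatureMap) -> PatchRepresentation:
    """Flatten T and sort descending into F."""
    if fmap.T.size == 0:
        raise ValueError("empty class feature map")
    flat = np.sort(fmap.T.reshape(-1))[::-1]
    return PatchRepresentation(np.ascontiguousarray(flat))


# ---------------------------------------------------------------------------
# stage 3: aggregation
# ---------------------------------------------------------------------------


def build_hipomap(reps: Sequence[PatchRepresentation], k: int,
                  patch_indices: Sequence[int] | None = None,
                  slide_id: str = "") -> HipoMap:
    """Stack representations, sort rows by descending row sum, zero-pad to K.

    Row-sum ties keep the pre-sort row order (stable sort).  ``patch_indices``
    carries the originating patch index of each representation for
    provenance; pad rows record -1.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if len(reps) > k:
        raise ValueError(f"got {len(reps)} representations for K={k}")
    if patch_indices is None:
        patch_indices = list(range(len(reps)))
    lengths = {r.F.shape[0] for r in reps}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent representation lengths: {sorted(lengths)}")
    if reps:
        width = lengths.pop()
        stacked = np.stack([r.F for r in reps])
        order = np.argsort(-stacked.sum(axis=1), kind="stable")
        stacked = stacked[order]
        row_idx = [int(patch_indices[i]) for i in order]
    else:
        raise ValueError("at least one patch representation is required")
    pad = k - stacked.shape[0]
    if pad:
        stacked = np.vstack([stacked, np.zeros((pad, width), dtype=stacked.dtype)])
        row_idx += [-1] * pad
    return HipoMap(X=stacked.astype(np.float32), K=k, slide_id=slide_id,
                   row_patch_indices=row_idx, pad_count=pad)


# ---------------------------------------------------------------------------
# end-to-end composition
# ---------------------------------------------------------------------------


def slide_to_hipomap(slide: Slide, model, class_index: int = 1,
                     k: int = DEFAULT_K, average_importance: bool = False,
                     rectify_feature_map: bool = False,
                     scores: Sequence[PatchScore] | None = None) -> HipoMap:
    """Full pipeline: score → select top-K → represent → aggregate.

    Pre-computed ``scores`` may be passed to avoid re-scoring.  For scorers
    with a scalar (regression/survival) head, ``class_index`` addresses the
    lone output.
    """
    if scores is None:
        scores = score_patches(model, slide, class_index)
    if not scores:
        raise ValueError(f"slide {slide.slide_id} has no patches")
    selected = rank_top_k(scores, k)
    batch = slide.patch_array()[selected]
    bundles = activation_bundles(model, batch, class_index)
    reps = []
    fshape = None
    for bundle in bundles:
        alpha = compute_importance(bundle, average=average_importance)
        fmap = class_feature_map(alpha, bundle, rectify=rectify_feature_map)
        fshape = fmap.T.shape
        reps.append(patch_representation(fmap))
    hm = build_hipomap(reps, k, patch_indices=selected, slide_id=slide.slide_id)
    hm.feature_shape = fshape
    return hm


# ---------------------------------------------------------------------------
# persistence and export
# ---------------------------------------------------------------------------


def save_hipomap(hm: HipoMap, path: str | Path) -> None:
    """Single-precision matrix (.npy) plus a sidecar JSON."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), hm.X.astype(np.float32))
    meta = {
        "slide_id": hm.slide_id,
        "K": hm.K,
        "pad_count": hm.pad_count,
        "row_patch_indices": hm.row_patch_indices,
        "feature_shape": list(hm.feature_shape) if hm.feature_shape else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_hipomap(path: str | Path) -> HipoMap:
    path = Path(path)
    X = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return HipoMap(X=X, K=meta["K"], slide_id=meta["slide_id"],
                   row_patch_indices=list(meta["row_patch_indices"]),
                   pad_count=meta["pad_count"],
                   feature_shape=tuple(meta["feature_shape"])
                   if meta.get("feature_shape") else None)


def hipomap_to_tsv(hm: HipoMap, path: str | Path) -> None:
    """K rows × H·W tab-separated values."""
    np.savetxt(path, hm.X, delimiter="\t", fmt="%.6g")


def hipomap_to_png(hm: HipoMap, path: str | Path,
                   vmax: float | None = None) -> None:
    """8-bit grayscale heatmap; ``vmax`` fixes the intensity scale so maps
    are comparable across slides (absolute intensity is meaningful)."""
    vmax = float(hm.X.max()) if vmax is None else float(vmax)
    scale = 255.0 / vmax if vmax > 0 else 0.0
    img = np.clip(hm.X * scale, 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)
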