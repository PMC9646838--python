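"""Patch scorer contract and the default trainable patch CNN.

A *patch model* is any object that (a) scores patches with a class
probability P_C, and (b) exposes a named internal convolutional layer: its
post-ReLU activation maps A^m (m = 1..M, each H×W) and the gradient of the
class objective P_C with respect to every activation value, obtained by
back-propagation.  These two views are everything the slide-representation
stage consumes, so any backbone honouring the contract plugs in.

The default backbone is a small three-block CNN (conv-ReLU-pool ×2 followed
by an exposed conv-ReLU, global average pooling and a dense head).  The
gradient target defaults to the post-sigmoid/softmax probability of the
requested class; a switch selects the pre-activation logit instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .cohort import Slide

__all__ = [
    "PatchScore",
    "ActivationBundle",
    "PatchCNN",
    "train_patch_model",
    "score_patches",
    "activation_bundle",
    "activation_bundles",
]

EXPOSED_LAYER = "gradcam_relu"


@dataclass(frozen=True)
class PatchScore:
    """Per-patch predictive score plus the tie-break statistic.

    ``mean_activation`` is the arithmetic mean over all M·H·W values of the
    exposed activation stack; patches with equal probability rank by it.
    """

    patch_index: int
    prob: float
    mean_activation: float


@dataclass
class ActivationBundle:
    """Exposed activations A (M, H, W) and gradients dP_C/dA, same shape."""

    activations: np.ndarray
    gradients: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        if self.activations.shape != self.gradients.shape:
            raise ValueError("activations and gradients must be shape-identical")
        if self.activations.ndim != 3:
            raise ValueError("expected (M, H, W) activation stack")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.activations.shape


class PatchCNN:
    """Default patch scorer: conv(8)-pool4-conv(16)-pool2-conv(16)[exposed]-GAP-dense.

    ``n_classes == 2`` uses a single-logit sigmoid head (P_1 = sigmoid(z),
    P_0 = 1 - P_1); more classes use a softmax head.  ``patch_size`` must be
    divisible by 8 so the two pooling stages tile exactly.
    """

    def __init__(self, patch_size: int = 64, n_classes: int = 2,
                 channels: tuple[int, int, int] = (8, 16, 16),
                 seed: int = 0, dtype=np.float32,
                 gradient_target: str = "prob"):
        if patch_size % 8 != 0:
            raise ValueError("patch_size must be a multiple of 8")
        if gradient_target not in ("prob", "logit"):
            raise ValueError("gradient_target must be 'prob' or 'logit'")
        self.patch_size = int(patch_size)
        self.n_classes = int(n_classes)
        self.channels = tuple(int(c) for c in channels)
        self.seed = int(seed)
        self.gradient_target = gradient_target
        self.dtype = np.dtype(dtype)
        c1, c2, c3 = self.channels
        n_out = 1 if n_classes == 2 else n_classes
        rng = np.random.default_rng(seed)
        self.network = nn.Sequential([
            nn.Conv2d(3, c1, 3, rng=rng, name="conv1", dtype=dtype),
            nn.ReLU("relu1"),
            nn.MaxPool2d(4, name="pool1"),
            nn.Conv2d(c1, c2, 3, rng=rng, name="conv2", dtype=dtype),
            nn.ReLU("relu2"),
            nn.MaxPool2d(2, name="pool2"),
            nn.Conv2d(c2, c3, 3, rng=rng, name="conv3", dtype=dtype),
            nn.ReLU(EXPOSED_LAYER),
            nn.GlobalAvgPool("gap"),
            nn.Dense(c3, n_out, rng=rng, name="head", dtype=dtype),
        ])
        self.exposed_layer = EXPOSED_LAYER

    # -- scorer contract ----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:3] != (self.patch_size, self.patch_size) or x.shape[3] != 3:
            raise ValueError(
                f"expected patches of size {self.patch_size}x{self.patch_size}x3, "
                f"got {x.shape[1:]}")
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def logits(self, patches: np.ndarray) -> np.ndarray:
        return self.network.forward(self._check_input(patches))

    def probs(self, patches: np.ndarray) -> np.ndarray:
        """(N, n_classes) class probabilities."""
        z = self.logits(patches)
        if self.n_classes == 2:
            p1 = nn.sigmoid(z.reshape(-1))
            return np.stack([1.0 - p1, p1], axis=1)
        return nn.softmax(z, axis=1)

    def class_prob(self, patches: np.ndarray, class_index: int) -> np.ndarray:
        if not 0 <= class_index < self.n_classes:
            raise ValueError(f"class_index {class_index} out of range "
                             f"[0, {self.n_classes})")
        return self.probs(patches)[:, class_index]

    def exposed_activations(self) -> np.ndarray:
        """(N, M, H, W) exposed activations from the latest forward pass."""
        return self.network.outputs[self.exposed_layer]

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.network.state_dict()
        np.savez(path.with_suffix(".npz"), **state)
        meta = {
            "patch_size": self.patch_size,
            "n_classes": self.n_classes,
            "channels": list(self.channels),
            "seed": self.seed,
            "dtype": self.dtype.name,
            "gradient_target": self.gradient_target,
            "exposed_layer": self.exposed_layer,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PatchCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(patch_size=meta["patch_size"], n_classes=meta["n_classes"],
                    channels=tuple(meta["channels"]), seed=meta["seed"],
                    dtype=np.dtype(meta["dtype"]),
                    gradient_target=meta["gradient_target"])
        with np.load(path.with_suffix(".npz")) as data:
            model.network.load_state_dict(dict(data))
        return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_patch_model(patches: np.ndarray, labels: Sequence[int],
                      patch_size: int | None = None,
                      epochs: int = 10, learning_rate: float = 1e-3,
                      batch_size: int = 64, seed: int = 0,
                      channels: tuple[int, int, int] = (8, 16, 16),
                      verbose: bool = False) -> PatchCNN:
    """Train the default patch CNN on labeled (N, H, W, 3) patches.

    Binary labels use sigmoid cross-entropy, multi-class uses softmax
    cross-entropy; Adam optimizer throughout.  Deterministic given the seed.
    """
    patches = np.asarray(patches, dtype=np.float32)
    labels = np.asarray(labels, dtype=int)
    if patches.ndim != 4 or patches.shape[0] != labels.shape[0]:
        raise ValueError("patches must be (N, H, W, 3) aligned with labels")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training patches must contain at least 2 classes")
    n_classes = int(classes.max()) + 1
    patch_size = patch_size or patches.shape[1]
    model = PatchCNN(patch_size=patch_size, n_classes=n_classes,
                     channels=channels, seed=seed)
    loss_fn = nn.bce_with_logits if n_classes == 2 else nn.softmax_cross_entropy
    rng = np.random.default_rng(seed + 1)
    x = np.ascontiguousarray(patches.transpose(0, 3, 1, 2))
    history = nn.fit(model.network, x, labels, loss_fn,
                     nn.Adam(lr=learning_rate), epochs=epochs,
                     batch_size=batch_size, rng=rng)
    model.training_history = history
    if verbose:  # pragma: no cover - logging sugar
        import logging
        logging.getLogger(__name__).info(
            "patch model trained: loss %.4f -> %.4f", history[0], history[-1])
    return model


# ---------------------------------------------------------------------------
# scoring and activation bundles
# ---------------------------------------------------------------------------


def score_patches(model: PatchCNN, slide: Slide, class_index: int = 1) -> list[PatchScore]:
    """Score every patch of a slide; order matches ``slide.patches``."""
    if slide.n_patches == 0:
        return []
    probs = model.class_prob(slide.patch_array(), class_index)
    acts = model.exposed_activations()
    mean_acts = acts.mean(axis=(1, 2, 3))
    return [PatchScore(i, float(p), float(a))
            for i, (p, a) in enumerate(zip(probs, mean_acts))]


def _head_gradient(model: PatchCNN, logits: np.ndarray, class_index: int) -> np.ndarray:
    """dP_C/dlogits for the configured gradient target."""
    if model.gradient_target == "logit":
        grad = np.zeros_like(logits)
        if model.n_classes == 2:
            grad[:, 0] = 1.0 if class_index == 1 else -1.0
        else:
            grad[:, class_index] = 1.0
        return grad
    if model.n_classes == 2:
        p1 = nn.sigmoid(logits.reshape(-1))
        dp = p1 * (1.0 - p1)            # dP_1/dz
        if class_index == 0:
            dp = -dp                    # P_0 = 1 - P_1
        return dp.reshape(logits.shape)
    p = nn.softmax(logits, axis=1)
    pc = p[:, class_index]
    grad = -pc[:, None] * p             # dP_C/dz_j = P_C (δ_Cj - P_j)
    grad[:, class_index] += pc
    return grad


def activation_bundles(model: PatchCNN, patches: np.ndarray,
                       class_index: int = 1) -> list[ActivationBundle]:
    """Batched exposed activations + gradients of P_C for several patches."""
    if not 0 <= class_index < model.n_classes:
        raise ValueError(f"class_index {class_index} out of range "
                         f"[0, {model.n_classes})")
    logits = model.logits(np.asarray(patches))
    acts = model.exposed_activations().copy()
    model.network.backward(_head_gradient(model, logits, class_index))
    grads = model.network.output_grads[model.exposed_layer]
    return [ActivationBundle(a, g, class_index)
            for a, g in zip(acts.astype(float), grads.astype(float))]


def activation_bundle(model: PatchCNN, patch: np.ndarray,
                      class_index: int = 1) -> ActivationBundle:
    """Exposed activations and dP_C/dA for a single patch."""
    return activation_bundles(model, np.asarray(patch)[None], class_index)[0]
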