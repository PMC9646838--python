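"""Slide-level analyses on representation maps.

A small CNN (three conv/pool blocks of 64 3×3 kernels, a 1024-unit dense
layer, and a task head) consumes the K×(H·W) maps:

* ``binary`` — sigmoid head, cross-entropy loss, AUC metric;
* ``multiclass`` — softmax head, cross-entropy, micro-/macro-F1;
* ``cox`` — linear head producing a prognostic index, trained with the
  negative log partial likelihood of the Cox proportional-hazards model
  (Breslow convention for tied event times), evaluated by Harrell's c-index;
* ``regression`` — linear head with ordinary-least-squares loss, evaluated
  by RMSE and R².

Post-hoc pooling baselines (mean / max of patch probabilities as the slide
score) are provided for comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score, r2_score, roc_auc_score

from . import nn
from .core import HipoMap
from .scoring import PatchScore

__all__ = [
    "TASKS",
    "SlideModelConfig",
    "SurvivalBatch",
    "SlideModel",
    "train_slide_model",
    "cox_npll",
    "cox_npll_grad",
    "concordance_index",
    "evaluate",
    "baseline_mean",
    "baseline_max",
    "GI_SURVIVAL_EXAMPLE",
]

TASKS = ("binary", "multiclass", "cox", "regression")

_HEAD_FOR_TASK = {"binary": "sigmoid", "multiclass": "softmax",
                  "cox": "linear", "regression": "linear"}

#: Six (predicted, observed) survival-month pairs from a published
#: demonstration of whole-slide survival prediction on stomach- and
#: colon-adenocarcinoma cohorts; used as the worked example for
#: :func:`evaluate` on the regression task.
GI_SURVIVAL_EXAMPLE = {
    "predictions": (3.2, 28.2, 46.4, 2.8, 17.2, 73.4),
    "truth": (1.0, 23.3, 53.1, 1.0, 12.1, 87.4),
}


@dataclass(frozen=True)
class SlideModelConfig:
    """Architecture and training settings for the slide CNN.

    ``head_activation`` is derived from the task when left empty; supplying
    one that contradicts the task is an error.  ``batch_size=None`` trains
    full-batch — mandatory for ``cox`` so every risk set is complete.
    """

    task: str = "binary"
    conv_channels: tuple[int, ...] = (64, 64, 64)
    conv_kernel: int = 3
    pool: int = 2
    pool_kind: str = "max"       # the paper-default; "avg" available
    fc_width: int = 1024
    head_activation: str = ""
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int | None = 32
    seed: int = 0

    def resolved_head(self) -> str:
        expected = _HEAD_FOR_TASK.get(self.task)
        if expected is None:
            raise ValueError(f"unknown task {self.task!r}; choose from {TASKS}")
        if self.head_activation and self.head_activation != expected:
            raise ValueError(
                f"head_activation {self.head_activation!r} does not match task "
                f"{self.task!r} (expected {expected!r})")
        return expected

    def validate(self) -> None:
        self.resolved_head()
        if self.pool_kind not in ("max", "avg"):
            raise ValueError("pool_kind must be 'max' or 'avg'")
        if self.task == "cox" and self.batch_size is not None:
            raise ValueError("cox training must be full-batch (batch_size=None) "
                             "so risk sets are complete")


@dataclass
class SurvivalBatch:
    """Aligned prognostic indices, follow-up times (months) and event flags."""

    risk: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.risk = np.asarray(self.risk, dtype=float).reshape(-1)
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        self.event = np.asarray(self.event, dtype=int).reshape(-1)
        if not (self.risk.size == self.time.size == self.event.size):
            raise ValueError("risk, time and event must have equal lengths")
        if np.any(self.time < 0):
            raise ValueError("survival times must be >= 0")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event flags must be 0/1")


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties), normalized by event count
# ---------------------------------------------------------------------------


def _cox_prepare(batch: SurvivalBatch):
    if batch.event.sum() < 1:
        raise ValueError("Cox partial likelihood requires at least one event")
    order = np.argsort(batch.time, kind="stable")
    r = batch.risk[order]
    t = batch.time[order]
    e = batch.event[order]
    shift = r.max()
    ex = np.exp(r - shift)
    # S[i] = sum_{j >= i} exp(r_j - shift), so log-denominators are stable
    rev_cumsum = np.cumsum(ex[::-1])[::-1]
    # first index of each tie group: all subjects with t_j >= t_i enter the
    # risk set of i, including those tied with t_i
    group_start = np.zeros(t.size, dtype=int)
    for i in range(1, t.size):
        group_start[i] = group_start[i - 1] if t[i] == t[i - 1] else i
    return order, r, t, e, shift, ex, rev_cumsum, group_start


def cox_npll(batch: SurvivalBatch) -> float:
    """Negative log Cox partial likelihood / number of events.

    −(1/D) Σ_{i: event} [ r_i − log Σ_{j: t_j ≥ t_i} exp(r_j) ] with the
    Breslow convention for tied event times.
    """
    _, r, _, e, shift, _, rev_cumsum, gstart = _cox_prepare(batch)
    ev = e == 1
    log_denoms = shift + np.log(rev_cumsum[gstart[ev]])
    return float(-np.sum(r[ev] - log_denoms) / ev.sum())


def cox_npll_grad(batch: SurvivalBatch) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to each risk value."""
    order, r, _, e, shift, ex, rev_cumsum, gstart = _cox_prepare(batch)
    n, d = r.size, int(e.sum())
    ev = e == 1
    log_denoms = shift + np.log(rev_cumsum[gstart[ev]])
    loss = float(-np.sum(r[ev] - log_denoms) / d)
    # accumulate, over event groups, d_g / S_g up to each subject's group
    inv_s = np.zeros(n)
    np.add.at(inv_s, gstart[ev], 1.0 / rev_cumsum[gstart[ev]])
    csum = np.cumsum(inv_s)
    grad_sorted = -(e - ex * csum) / d
    grad = np.empty(n)
    grad[order] = grad_sorted
    return loss, grad


def concordance_index(batch: SurvivalBatch) -> float:
    """Harrell's C: fraction of admissible pairs whose risk ordering matches
    the survival ordering.

    A pair (i, j) is admissible when t_i < t_j and subject i had the event;
    it scores 1 when risk_i > risk_j and 0.5 on a risk tie.  (Pairs with
    exactly tied times are not comparable under this definition, which is
    where some library implementations differ.)
    """
    t, r, e = batch.time, batch.risk, batch.event
    admissible = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(admissible.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs for the concordance index")
    wins = np.where(r[:, None] > r[None, :], 1.0,
                    np.where(r[:, None] == r[None, :], 0.5, 0.0))
    return float(wins[admissible].sum() / n_pairs)


# ---------------------------------------------------------------------------
# slide CNN
# ---------------------------------------------------------------------------


def _build_network(input_shape: tuple[int, int], n_out: int,
                   config: SlideModelConfig) -> nn.Sequential:
    rng = np.random.default_rng(config.seed)
    pool_cls = nn.MaxPool2d if config.pool_kind == "max" else nn.AvgPool2d
    layers: list[nn.Layer] = []
    c_in = 1
    for i, c_out in enumerate(config.conv_channels, start=1):
        layers.append(nn.Conv2d(c_in, c_out, config.conv_kernel, rng=rng,
                                name=f"conv{i}", dtype=np.float32))
        layers.append(nn.ReLU(f"relu{i}"))
        layers.append(pool_cls(config.pool, name=f"pool{i}"))
        c_in = c_out
    layers.append(nn.Flatten())
    probe = nn.Sequential(layers)
    flat = probe.forward(np.zeros((1, 1, *input_shape), dtype=np.float32)).shape[1]
    layers.append(nn.Dense(flat, config.fc_width, rng=rng, name="fc1",
                           dtype=np.float32))
    layers.append(nn.ReLU("fc1_relu"))
    layers.append(nn.Dense(config.fc_width, n_out, rng=rng, name="head",
                           dtype=np.float32))
    return nn.Sequential(layers)


class SlideModel:
    """A trained slide CNN bound to its task."""

    def __init__(self, network: nn.Sequential, task: str, input_shape: tuple[int, int],
                 n_classes: int = 2, training_history: list[float] | None = None,
                 config: "SlideModelConfig | None" = None):
        self.network = network
        self.task = task
        self.input_shape = tuple(input_shape)
        self.n_classes = n_classes
        self.training_history = training_history or []
        self.config = config

    def save(self, path) -> None:
        """Native-array checkpoint (.npz) plus a sidecar JSON."""
        import json
        from pathlib import Path
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.state_dict())
        cfg = dataclasses.asdict(self.config) if self.config else {}
        meta = {"task": self.task, "input_shape": list(self.input_shape),
                "n_classes": self.n_classes, "config": cfg}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "SlideModel":
        import json
        from pathlib import Path
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = meta.get("config") or {}
        if cfg_dict.get("conv_channels"):
            cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
        config = SlideModelConfig(**cfg_dict) if cfg_dict \
            else SlideModelConfig(task=meta["task"],
                                  batch_size=None if meta["task"] == "cox" else 32)
        n_out = {"binary": 1, "cox": 1, "regression": 1,
                 "multiclass": meta["n_classes"]}[meta["task"]]
        network = _build_network(tuple(meta["input_shape"]), n_out, config)
        with np.load(path.with_suffix(".npz")) as data:
            network.load_state_dict(dict(data))
        return cls(network, meta["task"], tuple(meta["input_shape"]),
                   n_classes=meta["n_classes"], config=config)

    def _stack(self, maps: Sequence[HipoMap]) -> np.ndarray:
        x = np.stack([m.X for m in maps]).astype(np.float32)[:, None]
        if x.shape[2:] != self.input_shape:
            raise ValueError(f"maps of shape {x.shape[2:]} do not match the "
                             f"model input {self.input_shape}")
        return x

    def predict(self, maps: Sequence[HipoMap]) -> np.ndarray:
        """Slide scores: probability (binary), class probabilities
        (multiclass), or scalar index (cox/regression)."""
        z = self.network.forward(self._stack(maps))
        if self.task == "binary":
            return nn.sigmoid(z.reshape(-1))
        if self.task == "multiclass":
            return nn.softmax(z, axis=1)
        return z.reshape(-1)


def _outcome_arrays(outcomes, task: str, n: int):
    if task in ("binary", "multiclass"):
        y = np.asarray(outcomes, dtype=int).reshape(-1)
        if y.size != n:
            raise ValueError(f"{y.size} labels for {n} maps")
        if np.unique(y).size < 2:
            raise ValueError(f"{task} training requires at least 2 classes")
        return y
    if task == "regression":
        y = np.asarray(outcomes, dtype=float).reshape(-1)
        if y.size != n:
            raise ValueError(f"{y.size} targets for {n} maps")
        return y
    if task == "cox":
        try:
            time, event = outcomes
        except (TypeError, ValueError) as exc:
            raise ValueError("cox outcomes must be a (time, event) pair "
                             "of arrays") from exc
        y = np.column_stack([np.asarray(time, dtype=float),
                             np.asarray(event, dtype=float)])
        if y.shape[0] != n:
            raise ValueError(f"{y.shape[0]} outcomes for {n} maps")
        if y[:, 1].sum() < 1:
            raise ValueError("cox training requires at least one event "
                             "(all subjects censored)")
        return y
    raise ValueError(f"unknown task {task!r}")


def _cox_loss(z: np.ndarray, y: np.ndarray):
    batch = SurvivalBatch(risk=z.reshape(-1), time=y[:, 0], event=y[:, 1])
    loss, grad = cox_npll_grad(batch)
    return loss, grad.reshape(z.shape).astype(z.dtype)


def train_slide_model(maps: Sequence[HipoMap], outcomes,
                      config: SlideModelConfig) -> SlideModel:
    """Train the slide CNN on representation maps; deterministic per seed."""
    config.validate()
    if len(maps) < 2:
        raise ValueError("at least 2 slides are required for training")
    x = np.stack([m.X for m in maps]).astype(np.float32)[:, None]
    input_shape = x.shape[2:]
    y = _outcome_arrays(outcomes, config.task, len(maps))
    n_classes = int(y.max()) + 1 if config.task == "multiclass" else 2
    n_out = {"binary": 1, "cox": 1, "regression": 1,
             "multiclass": n_classes}[config.task]
    network = _build_network(input_shape, n_out, config)
    loss_fn = {"binary": nn.bce_with_logits,
               "multiclass": nn.softmax_cross_entropy,
               "regression": nn.mse_loss,
               "cox": _cox_loss}[config.task]
    opt = nn.Adam(lr=config.learning_rate) if config.optimizer == "adam" \
        else nn.SGD(lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = nn.fit(network, x, y, loss_fn, opt, epochs=config.epochs,
                     batch_size=config.batch_size, rng=rng)
    return SlideModel(network, config.task, input_shape, n_classes=n_classes,
                      training_history=history, config=config)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(predictions, truth, task: str) -> dict[str, float]:
    """Task-appropriate metric set.

    binary → ROC-AUC; multiclass → micro-/macro-F1; regression → RMSE and
    R²; cox → Harrell's c-index (truth = (time, event)).
    """
    if task == "binary":
        y = np.asarray(truth, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("AUC is undefined for single-class truth")
        return {"auc": float(roc_auc_score(y, np.asarray(predictions, dtype=float)))}
    if task == "multiclass":
        p = np.asarray(predictions)
        pred_cls = p.argmax(axis=1) if p.ndim == 2 else p.astype(int)
        y = np.asarray(truth, dtype=int)
        return {"micro_f1": float(f1_score(y, pred_cls, average="micro")),
                "macro_f1": float(f1_score(y, pred_cls, average="macro"))}
    if task == "regression":
        p = np.asarray(predictions, dtype=float)
        y = np.asarray(truth, dtype=float)
        if p.shape != y.shape:
            raise ValueError("prediction/truth length mismatch")
        rmse = float(np.sqrt(np.mean((p - y) ** 2)))
        return {"rmse": rmse, "r2": float(r2_score(y, p))}
    if task == "cox":
        time, event = truth
        batch = SurvivalBatch(risk=np.asarray(predictions, dtype=float),
                              time=time, event=event)
        return {"c_index": concordance_index(batch)}
    raise ValueError(f"unknown task {task!r}")


# ---------------------------------------------------------------------------
# post-hoc pooling baselines
# ---------------------------------------------------------------------------


def baseline_mean(scores: Sequence[PatchScore]) -> float:
    """Mean of patch probabilities as the slide score."""
    if not scores:
        raise ValueError("cannot pool an empty score list")
    return float(np.mean([s.prob for s in scores]))


def baseline_max(scores: Sequence[PatchScore]) -> float:
    """Maximum patch probability as the slide score."""
    if not scores:
        raise ValueError("cannot pool an empty score list")
    return float(max(s.prob for s in scores))
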