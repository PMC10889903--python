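"""Training and evaluation of binary tilt classifiers.

The built-in reference architecture ("desknet") is a four-block CNN
sized for CPU training: strided/pooled conv blocks whose final coarse
feature map is flattened into a small dense head.  The head keeps the
horizontal layout of the final map rather than global-average pooling
it: the class signal is the bars' tilt, which at sub-degree magnitudes
is carried by how the bars' vertical position drifts from the left end
of the image to the right, and a translation-invariant pooled code would
discard exactly that cue.  The four post-ReLU block outputs are exposed
as tap points for class-activation maps and feature extraction.

Training follows fine-tuning practice for this task: Adam with decoupled
weight decay, cross-entropy loss, and a step learning-rate schedule that
multiplies the rate by a decay factor every few epochs.  The permutation
significance protocol retrains the classifier on label-shuffled data and
compares the true-label test accuracy with a high percentile of the
resulting null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import nn
from .datasets import manifest_to_arrays
from .utils import derive_rng, derive_seed

__all__ = [
    "HyperParams",
    "MetricsReport",
    "PermutationResult",
    "ARCH_REGISTRY",
    "make_model",
    "learning_rate_at",
    "train",
    "predict",
    "evaluate",
    "metrics_from_confusion",
    "nearest_rank_percentile",
    "permutation_test",
]


@dataclass(frozen=True)
class HyperParams:
    """Optimisation settings; defaults are the desk-scale configuration."""

    initial_lr: float = 0.001
    lr_decay_factor: float = 0.9
    lr_decay_every_epochs: int = 5
    epochs: int = 10
    optimizer: str = "adam"
    weight_decay: float = 1e-4
    dropout_rate: float = 0.2
    batch_size: int = 32
    seed: int = 0
    downscale: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass(frozen=True)
class MetricsReport:
    """Binary classification metrics with C2 as the positive class."""

    accuracy: float
    recall: float
    f1: float
    per_color_accuracy: dict[str, float]
    per_level_accuracy: dict[int, float]
    confusion: np.ndarray  # rows = true (C1, C2), cols = predicted

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "f1": self.f1,
            "per_color_accuracy": self.per_color_accuracy,
            "per_level_accuracy": {str(k): v for k, v in self.per_level_accuracy.items()},
            "confusion": self.confusion.tolist(),
        }


@dataclass(frozen=True)
class PermutationResult:
    """Null accuracies from label-shuffled retraining plus the verdict."""

    null_accuracies: tuple[float, ...]
    percentile95: float
    actual_accuracy: float
    significant: bool


def _build_desknet(
    seed: int, dropout_rate: float, input_hw: tuple[int, int] = (80, 280)
) -> nn.Network:
    """Four conv blocks -> flattened coarse map -> two-way dense head."""
    r = lambda tag: derive_rng(seed, "desknet", tag)
    h, w = input_hw
    h, w = (h + 2 * 2 - 5) // 2 + 1, (w + 2 * 2 - 5) // 2 + 1  # conv1, stride 2
    for _ in range(3):  # pool1..pool3
        h, w = h // 2, w // 2
    if h < 1 or w < 1:
        raise ValueError(f"input {input_hw} too small for desknet")
    layers = [
        ("conv1", nn.Conv2d(3, 16, 5, stride=2, rng=r("conv1"))),
        ("block1", nn.ReLU()),
        ("pool1", nn.MaxPool2d(2)),
        ("conv2", nn.Conv2d(16, 24, 3, rng=r("conv2"))),
        ("block2", nn.ReLU()),
        ("pool2", nn.MaxPool2d(2)),
        ("conv3", nn.Conv2d(24, 32, 3, rng=r("conv3"))),
        ("block3", nn.ReLU()),
        ("pool3", nn.MaxPool2d(2)),
        ("conv4", nn.Conv2d(32, 32, 3, rng=r("conv4"))),
        ("block4", nn.ReLU()),
        ("flatten", nn.Flatten()),
        ("dropout", nn.Dropout(dropout_rate, rng=r("dropout"))),
        ("fc1", nn.Linear(32 * h * w, 64, rng=r("fc1"))),
        ("fc1_relu", nn.ReLU()),
        ("fc2", nn.Linear(64, 2, rng=r("fc2"))),
    ]
    return nn.Network(layers, tap_points=["block1", "block2", "block3", "block4"])


ARCH_REGISTRY: dict[str, Callable[..., nn.Network]] = {
    "desknet": _build_desknet,
}


def make_model(
    arch: str,
    pretrained: bool = False,
    seed: int = 0,
    dropout_rate: float = 0.2,
    input_hw: tuple[int, int] = (80, 280),
) -> nn.Network:
    """Instantiate a registered architecture with seeded initial weights."""
    if arch not in ARCH_REGISTRY:
        raise KeyError(
            f"unknown architecture {arch!r}; registered: {sorted(ARCH_REGISTRY)}"
        )
    if pretrained:
        raise ValueError(
            f"no pretrained weights ship with {arch!r}; train from scratch or "
            "load a checkpoint with Network.load"
        )
    return ARCH_REGISTRY[arch](seed, dropout_rate, input_hw=input_hw)


def learning_rate_at(hp: HyperParams, epoch: int) -> float:
    """Step schedule: initial_lr * factor ** floor(epoch / every)."""
    return hp.initial_lr * hp.lr_decay_factor ** (epoch // hp.lr_decay_every_epochs)


def _normalize(x_uint8: np.ndarray) -> np.ndarray:
    return x_uint8.astype(np.float32) / 255.0 - 0.5


def _forward_in_batches(model: nn.Network, X: np.ndarray, batch: int = 64) -> np.ndarray:
    outs = []
    for i in range(0, len(X), batch):
        logits, _ = model.forward(_normalize(X[i : i + batch]))
        outs.append(logits)
    return np.concatenate(outs)


def train(
    model: nn.Network,
    train_manifest: pd.DataFrame,
    val_manifest: pd.DataFrame | None,
    hp: HyperParams,
    data: tuple | None = None,
) -> pd.DataFrame:
    """Train in place; returns the per-epoch log as a DataFrame.

    ``data`` optionally supplies pre-rendered ((X_train, y_train),
    (X_val, y_val)) arrays so repeated runs (e.g. the permutation test)
    skip re-rendering.
    """
    if train_manifest is not None and train_manifest.empty:
        raise ValueError("training manifest is empty")
    if data is None:
        Xtr, ytr = manifest_to_arrays(train_manifest, downscale=hp.downscale)
        val = (
            manifest_to_arrays(val_manifest, downscale=hp.downscale)
            if val_manifest is not None and not val_manifest.empty
            else None
        )
    else:
        (Xtr, ytr), val = data

    rng = derive_rng(hp.seed, "train_shuffle")
    opt = nn.Adam(weight_decay=hp.weight_decay)
    log = []
    for epoch in range(hp.epochs):
        opt.lr = learning_rate_at(hp, epoch)
        order = rng.permutation(len(Xtr))
        losses, correct = [], 0
        for i in range(0, len(order), hp.batch_size):
            sel = order[i : i + hp.batch_size]
            xb = _normalize(Xtr[sel])
            yb = ytr[sel]
            logits, _ = model.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy_with_grad(logits, yb)
            model.backward(dlogits)
            opt.step(model)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / len(Xtr),
        }
        if val is not None:
            Xv, yv = val
            vlogits = _forward_in_batches(model, Xv)
            vloss, _ = nn.cross_entropy_with_grad(vlogits, yv)
            entry["val_loss"] = vloss
            entry["val_acc"] = float((vlogits.argmax(axis=1) == yv).mean())
        log.append(entry)
    return pd.DataFrame(log)


def predict(
    model: nn.Network, manifest: pd.DataFrame, hp: HyperParams, X: np.ndarray | None = None
) -> np.ndarray:
    """Predicted class labels ("C1"/"C2") for every manifest row."""
    if X is None:
        X, _ = manifest_to_arrays(manifest, downscale=hp.downscale)
    logits = _forward_in_batches(model, X)
    return np.where(logits.argmax(axis=1) == 1, "C2", "C1")


def metrics_from_confusion(confusion: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, recall, F1) with C2 positive, from a 2x2 table."""
    tn, fp = confusion[0]
    fn, tp = confusion[1]
    n = confusion.sum()
    accuracy = (tn + tp) / n if n else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return float(accuracy), float(recall), float(f1)


def evaluate(
    model: nn.Network,
    manifest: pd.DataFrame,
    hp: HyperParams | None = None,
    X: np.ndarray | None = None,
) -> MetricsReport:
    """Accuracy/recall/F1 plus per-colour and per-level breakdowns."""
    if manifest.empty:
        raise ValueError("evaluation manifest is empty")
    hp = hp or HyperParams()
    pred = predict(model, manifest, hp, X=X)
    true = manifest["class_label"].to_numpy()
    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(true, pred):
        confusion[int(t == "C2"), int(p == "C2")] += 1
    accuracy, recall, f1 = metrics_from_confusion(confusion)
    hit = pred == true
    per_color = {
        str(c): float(hit[manifest["color"].to_numpy() == c].mean())
        for c in sorted(manifest["color"].unique())
    }
    per_level = {
        int(k): float(hit[manifest["level"].to_numpy() == k].mean())
        for k in sorted(manifest["level"].unique())
    }
    return MetricsReport(
        accuracy=accuracy,
        recall=recall,
        f1=f1,
        per_color_accuracy=per_color,
        per_level_accuracy=per_level,
        confusion=confusion,
    )


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile on ascending sorted values."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    vals = sorted(values)
    if not vals:
        raise ValueError("no values supplied")
    rank = int(np.ceil(percentile / 100.0 * len(vals)))
    return float(vals[max(rank, 1) - 1])


def permutation_test(
    arch: str,
    train_manifest: pd.DataFrame,
    val_manifest: pd.DataFrame | None,
    test_manifest: pd.DataFrame,
    hp: HyperParams,
    n_perms: int = 1000,
    percentile: float = 95.0,
    budget: int = 100,
    force: bool = False,
) -> PermutationResult:
    """Label-shuffled retraining null for the test accuracy.

    Permutation i shuffles the training (and validation) class labels
    with seed ``hp.seed + i + 1``, retrains a freshly initialised model
    under the same policy, and records its accuracy on the true-label
    test manifest.  Significance requires the true-label accuracy to
    exceed the nearest-rank percentile of the null.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if n_perms > budget and not force:
        raise ValueError(
            f"n_perms = {n_perms} exceeds the configured budget ({budget}); "
            "pass force=True for full-scale runs"
        )
    Xtr, ytr = manifest_to_arrays(train_manifest, downscale=hp.downscale)
    val = (
        manifest_to_arrays(val_manifest, downscale=hp.downscale)
        if val_manifest is not None and not val_manifest.empty
        else None
    )
    Xte, _ = manifest_to_arrays(test_manifest, downscale=hp.downscale)

    input_hw = Xtr.shape[1:3]
    model = make_model(arch, seed=hp.seed, dropout_rate=hp.dropout_rate, input_hw=input_hw)
    train(model, train_manifest, val_manifest, hp, data=((Xtr, ytr), val))
    actual = evaluate(model, test_manifest, hp, X=Xte).accuracy

    null = []
    for i in range(n_perms):
        perm_seed = hp.seed + i + 1
        rng = derive_rng(perm_seed, "label_shuffle")
        ytr_perm = ytr[rng.permutation(len(ytr))]
        val_perm = None
        if val is not None:
            Xv, yv = val
            val_perm = (Xv, yv[rng.permutation(len(yv))])
        m = make_model(arch, seed=perm_seed, dropout_rate=hp.dropout_rate, input_hw=input_hw)
        train(
            m,
            train_manifest,
            val_manifest,
            replace(hp, seed=perm_seed),
            data=((Xtr, ytr_perm), val_perm),
        )
        null.append(evaluate(m, test_manifest, hp, X=Xte).accuracy)

    p95 = nearest_rank_percentile(null, percentile)
    return PermutationResult(
        null_accuracies=tuple(null),
        percentile95=p95,
        actual_accuracy=actual,
        significant=actual > p95,
    )
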