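"""Training loop, evaluation statistics, multi-seed summaries, ablation grid.

Training follows the published recipe: AdamW, learning rate 0.01, batch size
16, cross-entropy loss, up to 130 epochs with early stopping on validation
accuracy (patience 20) and restoration of the best-validation weights.
Evaluation reports the confusion matrix, one-vs-rest precision / recall / F1
per class with macro averages, ROC-AUC and average precision per class, and
across repeated seeded runs the per-metric mean with a Student-t 95%
confidence interval plus paired t-tests on per-class F1 between two models.

Classes are ordered (E, M, D, P) for display and label encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats

from . import nn
from .cytosim import DatasetManifest, STAGES
from .preprocess import AugmentConfig, resize_bicubic
from .slenet_model import ModelConfig, build_model

__all__ = [
    "CLASS_ORDER",
    "TrainConfig",
    "EarlyStopper",
    "ConfusionMatrix",
    "MetricsReport",
    "MultiRunSummary",
    "load_dataset",
    "train_model",
    "predict_proba",
    "evaluate_model",
    "confusion",
    "classification_metrics",
    "roc_pr_ovr",
    "multi_seed_summary",
    "paired_f1_tests",
    "ablation_grid",
    "ABLATION_VARIANTS",
]

CLASS_ORDER = ("E", "M", "D", "P")


@dataclass
class TrainConfig:
    lr: float = 0.01
    batch_size: int = 16
    max_epochs: int = 130
    patience: int = 20
    optimizer: str = "adamw"
    weight_decay: float = 0.01
    warmup_steps: int = 0  # linear learning-rate ramp over the first steps
    lr_schedule: str = "constant"  # constant | cosine (to 10% of lr)
    clip_norm: float | None = None  # global gradient-norm clipping
    seed: int = 0
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.optimizer not in ("adamw", "adam", "sgd"):
            raise ValueError("optimizer must be adamw, adam or sgd")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be constant or cosine")


class EarlyStopper:
    """Stop when the validation metric has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -math.inf
        self.best_epoch = -1
        self._since = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record an epoch value; returns True when training should stop."""
        if value > self.best:
            self.best, self.best_epoch, self._since = value, epoch, 0
        else:
            self._since += 1
        return self._since >= self.patience


def _normalise(x):
    return ((np.asarray(x, dtype=np.float32) / 255.0) - 0.5) / 0.25


def load_dataset(
    manifest: DatasetManifest,
    root=None,
    image_size: int = 224,
    splits=("train", "val", "test"),
):
    """Read manifest images, bicubic-resize to the model input, encode labels.

    Returns ``{split: (X uint8 (N, 3, S, S), y int64 (N,))}``.
    """
    root = Path(root) if root is not None else Path(".")
    label = {s: i for i, s in enumerate(CLASS_ORDER)}
    out = {}
    for split in splits:
        sub = manifest.subset(split)
        xs = np.empty((len(sub), 3, image_size, image_size), dtype=np.uint8)
        ys = np.empty(len(sub), dtype=np.int64)
        for i, row in sub.iterrows():
            img = np.asarray(Image.open(root / row["path"]).convert("RGB"), dtype=np.float64)
            if img.shape[:2] != (image_size, image_size):
                img = resize_bicubic(img, (image_size, image_size))
            xs[i] = np.clip(np.round(img), 0, 255).astype(np.uint8).transpose(2, 0, 1)
            ys[i] = label[row["stage"]]
        out[split] = (xs, ys)
    return out


def _augment_batch(xb, cfg: AugmentConfig, rng):
    """Flips / 90-degree rotations / brightness / contrast on a (B,3,H,W) batch."""
    out = np.empty_like(xb)
    for i in range(xb.shape[0]):
        img = xb[i]
        if cfg.hflip and rng.random() < 0.5:
            img = img[:, :, ::-1]
        if cfg.vflip and rng.random() < 0.5:
            img = img[:, ::-1, :]
        rot = int(rng.choice(cfg.rotation_set))
        if rot % 360:
            img = np.rot90(img, k=(rot // 90) % 4, axes=(1, 2))
        img = img.astype(np.float32)
        b = rng.uniform(1 - cfg.brightness_max_frac, 1 + cfg.brightness_max_frac)
        c = rng.uniform(1 - cfg.contrast_max_frac, 1 + cfg.contrast_max_frac)
        if b != 1.0:
            img = img * b
        if c != 1.0:
            mean = img.mean(axis=(1, 2), keepdims=True)
            img = (img - mean) * c + mean
        out[i] = np.clip(img, 0, 255)
    return out


def predict_proba(network, X, batch_size=32):
    """Class probabilities on uint8 (N, 3, S, S) images (evaluation mode)."""
    network.eval()
    probs = []
    for i in range(0, X.shape[0], batch_size):
        logits = network(_normalise(X[i : i + batch_size]))
        probs.append(nn.softmax(logits, axis=1))
    return np.concatenate(probs, axis=0)


def _accuracy(network, X, y, batch_size=32):
    return float(np.mean(np.argmax(predict_proba(network, X, batch_size), axis=1) == y))


def _make_optimizer(network, cfg: TrainConfig):
    if cfg.optimizer == "adamw":
        return nn.AdamW(network.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    if cfg.optimizer == "adam":
        return nn.AdamW(network.parameters(), lr=cfg.lr, weight_decay=0.0)
    return _SGD(network.parameters(), lr=cfg.lr)


class _SGD:
    def __init__(self, params, lr, momentum=0.9):
        self.params, self.lr, self.momentum = list(params), lr, momentum
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.v):
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def train_model(network, data, cfg: TrainConfig):
    """Optimise on ``data['train']``, early-stop on ``data['val']`` accuracy.

    ``data`` is the mapping produced by :func:`load_dataset`.  Returns the
    network (best-validation weights restored) and a per-epoch history
    ``{"train_loss": [...], "val_accuracy": [...], "best_epoch": int}``.
    """
    x_train, y_train = data["train"]
    x_val, y_val = data["val"]
    if x_train.shape[0] == 0:
        raise ValueError("training split is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = _make_optimizer(network, cfg)
    stopper = EarlyStopper(cfg.patience)
    history = {"train_loss": [], "val_accuracy": []}
    best_state = network.state_dict()
    n = x_train.shape[0]
    steps_per_epoch = (n + cfg.batch_size - 1) // cfg.batch_size
    total_steps = cfg.max_epochs * steps_per_epoch
    step = 0
    for epoch in range(cfg.max_epochs):
        network.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            lr_t = cfg.lr
            if cfg.warmup_steps:
                lr_t *= min(1.0, (step + 1) / cfg.warmup_steps)
            if cfg.lr_schedule == "cosine" and step >= cfg.warmup_steps:
                frac = (step - cfg.warmup_steps) / max(1, total_steps - cfg.warmup_steps)
                lr_t = cfg.lr * (0.1 + 0.45 * (1.0 + math.cos(math.pi * frac)))
            opt.lr = lr_t
            step += 1
            idx = order[i : i + cfg.batch_size]
            xb = x_train[idx].astype(np.float32)
            if cfg.augment is not None:
                xb = _augment_batch(xb, cfg.augment, rng)
            logits = network(_normalise(xb))
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            network.backward(dlogits)
            if cfg.clip_norm is not None:
                params = opt.params
                total = math.sqrt(sum(float(np.sum(p.grad**2)) for p in params))
                if total > cfg.clip_norm:
                    scale = cfg.clip_norm / total
                    for p in params:
                        p.grad *= scale
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(network, x_val, y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        improved = val_acc > stopper.best
        stop = stopper.update(val_acc, epoch)
        if improved:
            best_state = network.state_dict()
        if stop:
            break
    network.load_state_dict(best_state)
    history["best_epoch"] = stopper.best_epoch
    return network, history


# ---------------------------------------------------------------------------
# evaluation statistics


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows true, columns predicted
    class_order: tuple = CLASS_ORDER

    @property
    def total(self):
        return int(self.counts.sum())


def confusion(y_true, y_pred, class_order=CLASS_ORDER) -> ConfusionMatrix:
    """Tally counts[i, j] = #(true class i, predicted class j)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    k = len(class_order)
    index = {c: i for i, c in enumerate(class_order)}

    def encode(y):
        if y.dtype.kind in "iu":
            if y.size and (y.min() < 0 or y.max() >= k):
                raise ValueError("integer label outside class order")
            return y
        try:
            return np.array([index[v] for v in y])
        except KeyError as e:  # label not in class_order
            raise ValueError(f"label {e.args[0]!r} outside class order") from e

    ti, pi = encode(y_true).astype(np.int64), encode(y_pred).astype(np.int64)
    counts = np.zeros((k, k), dtype=np.int64)
    if ti.size:
        np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts, tuple(class_order))


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    undefined: dict[str, list[str]] = field(default_factory=dict)
    auc: dict[str, float] | None = None
    ap: dict[str, float] | None = None


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy and one-vs-rest precision / recall / F1 from a confusion matrix.

    Zero-denominator cases yield 0 and are recorded in ``undefined``.
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    precision, recall, f1 = {}, {}, {}
    undefined = {}
    for i, cls in enumerate(cm.class_order):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        flags = []
        if tp + fp > 0:
            p = tp / (tp + fp)
        else:
            p, flags = 0.0, flags + ["precision"]
        if tp + fn > 0:
            r = tp / (tp + fn)
        else:
            r, flags = 0.0, flags + ["recall"]
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        if (p + r) == 0:
            flags = flags + ["f1"]
        precision[cls], recall[cls], f1[cls] = float(p), float(r), float(f)
        if flags:
            undefined[cls] = flags
    return MetricsReport(
        accuracy=float(np.trace(counts) / total),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        undefined=undefined,
    )


def roc_pr_ovr(y_true, scores, class_order=CLASS_ORDER):
    """One-vs-rest ROC-AUC and average precision per class.

    ``scores`` is (N, K) with rows (approximately) summing to 1.  Classes
    absent from ``y_true`` (or covering all of it) get ``nan`` with a flag.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be N x K aligned with y_true")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-3):
        raise ValueError("score rows must sum to 1")
    auc, ap, flagged = {}, {}, []
    for i, cls in enumerate(class_order):
        pos = (y_true == i).astype(int)
        if pos.min() == pos.max():
            auc[cls] = ap[cls] = float("nan")
            flagged.append(cls)
            continue
        auc[cls] = float(roc_auc_score(pos, scores[:, i]))
        ap[cls] = float(average_precision_score(pos, scores[:, i]))
    return {"auc": auc, "ap": ap, "degenerate": flagged}


def evaluate_model(network, X, y, class_order=CLASS_ORDER) -> MetricsReport:
    """Full test-split report: confusion-derived metrics plus AUC / AP."""
    probs = predict_proba(network, X)
    cm = confusion(y, np.argmax(probs, axis=1), class_order)
    report = classification_metrics(cm)
    curves = roc_pr_ovr(y, probs, class_order)
    report.auc, report.ap = curves["auc"], curves["ap"]
    return report


def _mean_ci(values, level=0.95):
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 2:
        raise ValueError("confidence interval needs at least 2 runs")
    half = stats.t.ppf(0.5 + level / 2, n - 1) * v.std(ddof=1) / math.sqrt(n)
    return float(v.mean()), float(half)


def paired_f1_tests(reports_a, reports_b, class_order=CLASS_ORDER):
    """Paired t-test per class on F1 across seed-paired runs; mean p reported.

    Degenerate classes (all per-seed differences zero) get p = 1 with a flag.
    """
    if len(reports_a) != len(reports_b):
        raise ValueError("runs must be paired by seed")
    p_values, degenerate = {}, []
    for cls in class_order:
        a = np.array([r.f1[cls] for r in reports_a])
        b = np.array([r.f1[cls] for r in reports_b])
        if np.allclose(a - b, 0.0):
            p_values[cls] = 1.0
            degenerate.append(cls)
        else:
            p_values[cls] = float(stats.ttest_rel(a, b).pvalue)
    return {
        "per_class": p_values,
        "average": float(np.mean(list(p_values.values()))),
        "degenerate": degenerate,
    }


@dataclass
class MultiRunSummary:
    n_runs: int
    means: dict[str, float]
    ci_half_widths: dict[str, float]
    p_values: dict | None = None  # paired F1 tests vs. a comparator


def multi_seed_summary(reports, comparator_reports=None, class_order=CLASS_ORDER):
    """Mean and Student-t 95% CI of each metric over repeated seeded runs."""
    if len(reports) < 2:
        raise ValueError("summary needs at least 2 runs")
    metrics = {
        "accuracy": [r.accuracy for r in reports],
        "macro_f1": [r.macro_f1 for r in reports],
        "macro_precision": [r.macro_precision for r in reports],
        "macro_recall": [r.macro_recall for r in reports],
    }
    for cls in class_order:
        metrics[f"f1_{cls}"] = [r.f1[cls] for r in reports]
    means, halves = {}, {}
    for name, vals in metrics.items():
        means[name], halves[name] = _mean_ci(vals)
    p = None
    if comparator_reports is not None:
        p = paired_f1_tests(reports, comparator_reports, class_order)
    return MultiRunSummary(len(reports), means, halves, p)


# ---------------------------------------------------------------------------
# ablation harness

ABLATION_VARIANTS = {
    "baseline": dict(attention="se", use_nonlocal=False),
    "+seca": dict(attention="seca", use_nonlocal=False),
    "+nonlocal": dict(attention="se", use_nonlocal=True),
    "+seca+nonlocal": dict(attention="seca", use_nonlocal=True),
}


def ablation_grid(
    data,
    base_config: ModelConfig,
    train_config: TrainConfig,
    seeds=(0, 1, 2, 3, 4),
    variants=None,
):
    """Train and evaluate the attention ablation variants under shared seeds.

    Every variant sees identical data and the same per-run seed (controlling
    initialisation, shuffling and augmentation).  Returns a DataFrame with a
    row per variant (mean +/- CI of accuracy and macro F1, paired-test p
    against the baseline variant) and the per-variant reports.
    """
    variants = variants or ABLATION_VARIANTS
    all_reports = {}
    for name, toggles in variants.items():
        cfg = replace(base_config, **toggles)
        reports = []
        for seed in seeds:
            net = build_model(cfg, seed=seed)
            run_cfg = replace(train_config, seed=seed)
            net, _ = train_model(net, data, run_cfg)
            x_test, y_test = data["test"]
            reports.append(evaluate_model(net, x_test, y_test))
        all_reports[name] = reports
    rows = []
    baseline = all_reports.get("baseline")
    for name, reports in all_reports.items():
        if len(reports) >= 2:
            summary = multi_seed_summary(
                reports, None if name == "baseline" else baseline
            )
            row = {
                "variant": name,
                "accuracy_mean": summary.means["accuracy"],
                "accuracy_ci": summary.ci_half_widths["accuracy"],
                "macro_f1_mean": summary.means["macro_f1"],
                "macro_f1_ci": summary.ci_half_widths["macro_f1"],
                "p_vs_baseline": summary.p_values["average"] if summary.p_values else None,
            }
        else:  # single-seed smoke runs still produce a full row shape
            row = {
                "variant": name,
                "accuracy_mean": reports[0].accuracy,
                "accuracy_ci": float("nan"),
                "macro_f1_mean": reports[0].macro_f1,
                "macro_f1_ci": float("nan"),
                "p_vs_baseline": None,
            }
        rows.append(row)
    return pd.DataFrame(rows), all_reports
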