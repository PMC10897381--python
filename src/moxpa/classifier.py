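"""Six-layer MLP activity-level classifier, cross-validation, metric formulas
and the synthetic-augmentation experiment protocol.

The classifier maps the five daily features (Sedentary, LPA, MPA, VPA,
Steps) to the five activity-level classes through six dense layers — five
ReLU layers of widths 81, 18, 12, 10 and 5, then a softmax output of width
5 — for exactly 2405 trainable parameters (Σ over layers of
(fan_in + 1)·fan_out).  Training uses categorical cross-entropy on one-hot
labels, Adam (α=0.001, β₁=0.9, β₂=0.999, ε=1e−8, decay 0), stratified
five-fold cross-validation and plateau learning-rate reduction (monitor
validation loss, factor 0.5, patience 10).

``classification_metrics`` implements accuracy, precision,
recall/sensitivity, specificity TN/(TN+FP), F1 and the Matthews correlation
coefficient from per-class confusion counts; zero-denominator ratios are
reported as 0 and flagged.  ``train_on_sources_evaluate_on_real`` runs the
augmentation protocol: train on a union of real and synthetic tables,
always evaluate on held-out real data, averaged over repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._nn import Adam, Network, ReduceLROnPlateau, categorical_cross_entropy

__all__ = [
    "TrainingConfig",
    "ConfusionMatrix",
    "MetricsReport",
    "FEATURES",
    "build_mlp",
    "parameter_count",
    "train_mlp",
    "train_crossval",
    "train_on_sources_evaluate_on_real",
    "classification_metrics",
    "confusion_from_labels",
    "PROTOCOL_ARMS",
]

FEATURES = ["Sedentary", "LPA", "MPA", "VPA", "Steps"]
N_CLASSES = 5

#: Composition of each experiment arm: which tables form the training pool.
PROTOCOL_ARMS = {
    "R": ("R",),
    "FGC": ("FGC",),
    "FC": ("FC",),
    "FGC+R": ("FGC", "R"),
    "FC+R": ("FC", "R"),
    "FGC+FC+R": ("FGC", "FC", "R"),
}


@dataclass(frozen=True)
class TrainingConfig:
    """Architecture and optimization settings of the activity-level MLP."""

    hidden: tuple[int, ...] = (81, 18, 12, 10, 5)
    n_features: int = 5
    n_classes: int = N_CLASSES
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    epochs: int = 150
    batch_size: int = 32
    folds: int = 5
    plateau_factor: float = 0.5
    plateau_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden) < 2:
            raise ValueError("need at least two hidden layers for the stacked MLP")
        if self.folds < 2:
            raise ValueError("folds must be at least 2")


@dataclass
class ConfusionMatrix:
    """K×K (actual × predicted) counts over a fixed class list."""

    matrix: np.ndarray
    classes: list[int]

    def counts(self, cls: int) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, FP, TN, FN) for one class."""
        k = self.classes.index(cls)
        tp = int(self.matrix[k, k])
        fp = int(self.matrix[:, k].sum() - tp)
        fn = int(self.matrix[k, :].sum() - tp)
        tn = int(self.matrix.sum() - tp - fp - fn)
        return tp, fp, tn, fn

    @property
    def n(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricsReport:
    """Classification metrics: macro-averaged headline values plus detail."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    micro: dict[str, float] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)
    loss_history: pd.DataFrame | None = field(default=None, repr=False)

    def as_row(self) -> dict[str, float]:
        """Percent-scale headline metrics (protocol-table layout)."""
        return {
            "Accuracy": 100 * self.accuracy,
            "F1-score": 100 * self.f1,
            "Precision": 100 * self.precision,
            "Recall": 100 * self.recall,
            "MCC": 100 * self.mcc,
        }


def parameter_count(n_features: int, hidden: tuple[int, ...], n_classes: int) -> int:
    """Closed-form trainable-parameter count: Σ (fan_in + 1) · fan_out."""
    widths = [n_features, *hidden, n_classes]
    return sum((widths[i] + 1) * widths[i + 1] for i in range(len(widths) - 1))


def build_mlp(config: TrainingConfig = TrainingConfig()) -> tuple[Network, int]:
    """Build the six-layer MLP; returns (network, trainable parameter count)."""
    widths = [config.n_features, *config.hidden, config.n_classes]
    activations = ["relu"] * len(config.hidden) + ["softmax"]
    net = Network.dense_stack(widths, activations, seed=config.seed)
    count = net.n_params
    assert count == parameter_count(config.n_features, config.hidden, config.n_classes)
    return net, count


def _one_hot(y: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(y), k))
    out[np.arange(len(y)), y.astype(int)] = 1.0
    return out


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: TrainingConfig = TrainingConfig(),
    seed: int | None = None,
) -> tuple[Network, tuple[np.ndarray, np.ndarray], pd.DataFrame]:
    """Train one MLP; returns (network, (mean, scale), loss history).

    Features are standardized on the training split; validation loss (when a
    validation split is given) drives the plateau learning-rate schedule.
    """
    seed = config.seed if seed is None else seed
    cfg = config
    net = Network.dense_stack(
        [cfg.n_features, *cfg.hidden, cfg.n_classes],
        ["relu"] * len(cfg.hidden) + ["softmax"],
        seed=seed,
    )
    mean, scale = _standardize_fit(x_train)
    xs = (x_train - mean) / scale
    t = _one_hot(y_train, cfg.n_classes)
    opt = Adam(lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.epsilon, decay=cfg.decay)
    plateau = ReduceLROnPlateau(opt, factor=cfg.plateau_factor, patience=cfg.plateau_patience)
    rng = np.random.default_rng(seed)
    n = len(xs)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pred = net.forward(xs[idx])
            delta = (pred - t[idx]) / len(idx)  # fused softmax + cross-entropy
            grads, _ = net.backward(delta)
            opt.step(net.parameters(), [g for pair in grads for g in pair])
        train_loss = categorical_cross_entropy(net.forward(xs), t)
        if x_val is not None and len(x_val):
            val_pred = net.forward((x_val - mean) / scale)
            val_loss = categorical_cross_entropy(val_pred, _one_hot(y_val, cfg.n_classes))
        else:
            val_loss = train_loss
        plateau.update(val_loss)
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
    return net, (mean, scale), pd.DataFrame(history)


def _predict(net: Network, scaling: tuple[np.ndarray, np.ndarray], x: np.ndarray) -> np.ndarray:
    mean, scale = scaling
    return net.forward((x - mean) / scale).argmax(axis=1)


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list[int] | None = None
) -> ConfusionMatrix:
    classes = classes or list(range(N_CLASSES))
    k = len(classes)
    m = np.zeros((k, k), dtype=int)
    pos = {c: i for i, c in enumerate(classes)}
    for t_, p_ in zip(y_true, y_pred):
        m[pos[int(t_)], pos[int(p_)]] += 1
    return ConfusionMatrix(matrix=m, classes=classes)


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """All six metric formulas from confusion counts, macro-averaged.

    Per class (one-vs-rest): accuracy (TP+TN)/(TP+FP+FN+TN), precision
    TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP), F1 2PR/(P+R) and
    MCC (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Macro averages
    over classes present in the evaluation; micro metrics pool the counts.
    Zero-denominator ratios are 0 and listed in ``undefined``.
    """
    undefined: list[str] = []
    per_class: dict[int, dict[str, float]] = {}
    agg = np.zeros(4)
    for cls in cm.classes:
        tp, fp, tn, fn = cm.counts(cls)
        agg += (tp, fp, tn, fn)
        per_class[cls] = _binary_metrics(tp, fp, tn, fn, f"class {cls}", undefined)
    macro = {
        key: float(np.mean([per_class[c][key] for c in cm.classes]))
        for key in ("accuracy", "precision", "recall", "specificity", "f1", "mcc")
    }
    micro = _binary_metrics(*(int(v) for v in agg), "micro", undefined)
    # headline accuracy is the plain multi-class fraction correct
    overall_acc = _safe_div(float(np.trace(cm.matrix)), float(cm.n), "overall accuracy", undefined)
    return MetricsReport(
        accuracy=overall_acc,
        precision=macro["precision"],
        recall=macro["recall"],
        specificity=macro["specificity"],
        f1=macro["f1"],
        mcc=macro["mcc"],
        per_class=per_class,
        micro=micro,
        undefined=undefined,
    )


def _binary_metrics(tp: int, fp: int, tn: int, fn: int, tag: str, undefined: list[str]) -> dict[str, float]:
    acc = _safe_div(tp + tn, tp + fp + fn + tn, f"{tag} accuracy", undefined)
    p = _safe_div(tp, tp + fp, f"{tag} precision", undefined)
    r = _safe_div(tp, tp + fn, f"{tag} recall", undefined)
    s = _safe_div(tn, tn + fp, f"{tag} specificity", undefined)
    f1 = _safe_div(2 * p * r, p + r, f"{tag} F1", undefined)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom, f"{tag} MCC", undefined)
    return {"accuracy": acc, "precision": p, "recall": r, "specificity": s, "f1": f1, "mcc": mcc}


def _require_columns(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURES + ["Active"] if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    return table[FEATURES].to_numpy(dtype=float), table["Active"].to_numpy(dtype=int)


def train_crossval(
    table: pd.DataFrame, config: TrainingConfig = TrainingConfig()
) -> tuple[list[MetricsReport], MetricsReport]:
    """Stratified k-fold cross-validation on a labelled daily table.

    Returns per-fold reports (each carrying its train/validation loss
    history) and the mean report.  Every row appears in exactly one
    validation fold.
    """
    x, y = _require_columns(table)
    if len(x) < config.folds * len(np.unique(y)):
        raise ValueError("too few rows for stratified folding")
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    reports: list[MetricsReport] = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        net, scaling, history = train_mlp(
            x[tr], y[tr], x[te], y[te], config=config, seed=config.seed + fold
        )
        pred = _predict(net, scaling, x[te])
        rep = classification_metrics(confusion_from_labels(y[te], pred))
        rep.loss_history = history
        reports.append(rep)
    return reports, _mean_report(reports)


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    def m(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in reports]))

    return MetricsReport(
        accuracy=m("accuracy"),
        precision=m("precision"),
        recall=m("recall"),
        specificity=m("specificity"),
        f1=m("f1"),
        mcc=m("mcc"),
    )


def train_on_sources_evaluate_on_real(
    real: pd.DataFrame,
    synthetic_sets: dict[str, pd.DataFrame],
    arms: list[str] | None = None,
    config: TrainingConfig = TrainingConfig(),
    repeats: int = 4,
    test_size: float = 0.25,
) -> dict[str, dict]:
    """Run the augmentation protocol: train per arm, evaluate on real data.

    Each arm names a union of training tables (e.g. ``"FGC+FC+R"``); the
    ``"R"`` arm degenerates to cross-validation on the real table.  For
    synthetic-containing arms each repetition stratified-splits the real
    table, trains on the arm's union (full synthetic tables plus the real
    training split) and evaluates on the held-out real split; metrics are
    averaged over ``repeats`` repetitions.  ``records`` reports the arm's
    total record count (sum of the constituent full tables).
    """
    arms = arms or list(PROTOCOL_ARMS)
    for tbl in synthetic_sets.values():
        if list(tbl.columns) != list(real.columns):
            raise ValueError("synthetic tables must share the real table's columns")
    results: dict[str, dict] = {}
    for arm in arms:
        sources = PROTOCOL_ARMS[arm]
        records = sum(len(real) if s == "R" else len(synthetic_sets[s]) for s in sources)
        if sources == ("R",):
            _, mean_rep = train_crossval(real, config)
            results[arm] = {"report": mean_rep, "records": records, "repeats": config.folds}
            continue
        reps: list[MetricsReport] = []
        x_real, y_real = _require_columns(real)
        for rep_i in range(repeats):
            tr_idx, te_idx = train_test_split(
                np.arange(len(real)),
                test_size=test_size,
                random_state=config.seed + rep_i,
                stratify=y_real,
            )
            parts = [
                real.iloc[tr_idx] if s == "R" else synthetic_sets[s] for s in sources
            ]
            train_tbl = pd.concat(parts, ignore_index=True)
            x_tr, y_tr = _require_columns(train_tbl)
            net, scaling, _ = train_mlp(
                x_tr, y_tr, x_real[te_idx], y_real[te_idx],
                config=config, seed=config.seed + rep_i,
            )
            pred = _predict(net, scaling, x_real[te_idx])
            reps.append(classification_metrics(confusion_from_labels(y_real[te_idx], pred)))
        results[arm] = {
            "report": _mean_report(reps),
            "records": records,
            "repeats": repeats,
            "per_repeat": reps,
        }
    return results
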