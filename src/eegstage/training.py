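"""Training loop, nine-fold cross-validation, metrics and the gamma sweep.

Training uses Adam (learning rate 0.01, customary defaults otherwise) on the
configured negative-log-likelihood criterion (cross-entropy or focal loss).
If the monitored cost does not decrease for ``patience`` consecutive epochs
(default 20) training stops and the weights from the minimum-cost epoch are
restored.  The monitored cost defaults to the epoch-mean training loss; a
held-out monitor set can be supplied instead.

Evaluation follows the binary movement-stage protocol: data are split into
nine folds (optionally grouped by source trial so crops of one trial never
straddle the train/test boundary), per-class accuracies and their gap are
reported per fold, and Cohen's kappa

    kappa = (P0 - Pe) / (1 - Pe)

summarizes chance-corrected agreement.  When cross-entropy training leaves a
per-class accuracy gap above 0.3, a sweep over the focusing parameter gamma
(0 to 11 in steps of 0.5 in the full protocol) retrains with focal loss and
selects the gamma maximizing balanced accuracy; final figures average
repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold

from .cropping import ClassCounts, CropSet
from .grid_repr import ElectrodeLayout, segments_to_batch
from .losses import LossParams, loss_and_grad
from .model import Model, ModelConfig, build
from . import nn


class TrainingDivergedError(RuntimeError):
    """Raised when the monitored cost becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the movement-stage protocol."""

    learning_rate: float = 0.01
    patience: int = 20
    max_epochs: int = 500
    batch_size: int = 64
    seed: int = 0
    loss: LossParams = field(default_factory=LossParams.ce)
    monitor: str = "train"  # "train" or "valid"

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("train", "valid"):
            raise ValueError("monitor must be 'train' or 'valid'")


@dataclass
class History:
    """Per-epoch monitored costs and the early-stopping outcome."""

    costs: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 1-based epoch with the lowest monitored cost
    stopped_epoch: int = 0
    restored: bool = False


def _as_batch(data, layout: ElectrodeLayout | None):
    """Accept a CropSet (with layout) or an (X, y) array pair."""
    if isinstance(data, CropSet):
        if layout is None:
            raise ValueError("a CropSet needs an electrode layout")
        x = segments_to_batch(data.windows, data.channel_names, layout)
        return x, data.labels
    x, y = data
    return np.asarray(x), np.asarray(y)


def mean_loss(model: Model, x: np.ndarray, y: np.ndarray,
              params: LossParams, batch_size: int = 64) -> float:
    """Mean per-example loss in evaluation mode."""
    total = 0.0
    for i in range(0, x.shape[0], batch_size):
        logits = model.forward(x[i:i + batch_size], training=False)
        losses, _ = loss_and_grad(logits, y[i:i + batch_size], params)
        total += float(losses.sum())
    return total / x.shape[0]


def train(
    model: Model,
    train_data,
    valid_data=None,
    config: TrainConfig = TrainConfig(),
    layout: ElectrodeLayout | None = None,
    monitor_fn: Callable[[Model, int], float] | None = None,
) -> History:
    """Fit ``model`` in place and return the cost history.

    ``train_data``/``valid_data`` are CropSets (with ``layout``) or ``(x, y)``
    pairs of network batches and 0/1 labels.  ``monitor_fn(model, epoch)``
    overrides the monitored cost (used for diagnostics and for exercising
    the early-stopping contract with scripted cost schedules).
    """
    x, y = _as_batch(train_data, layout)
    if x.shape[0] == 0:
        raise ValueError("empty training data")
    counts = ClassCounts(int((y == 1).sum()), int((y == 0).sum()))
    params = config.loss.resolve_alpha(counts)

    if config.monitor == "valid" and monitor_fn is None:
        if valid_data is None:
            raise ValueError("monitor='valid' needs validation data")
        xv, yv = _as_batch(valid_data, layout)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.net.parameters(), lr=config.learning_rate)
    history = History()
    best_cost = np.inf
    best_weights = model.net.get_weights()
    since_improve = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x.shape[0])
        epoch_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model.forward(x[idx], training=True, rng=rng)
            losses, dlogits = loss_and_grad(logits, y[idx], params)
            model.net.backward((dlogits / len(idx)).astype(logits.dtype))
            opt.step(model.net.gradients())
            epoch_loss += float(losses.sum())

        if monitor_fn is not None:
            cost = float(monitor_fn(model, epoch))
        elif config.monitor == "valid":
            cost = mean_loss(model, xv, yv, params, config.batch_size)
        else:
            cost = epoch_loss / x.shape[0]
        if not np.isfinite(cost):
            raise TrainingDivergedError(
                f"non-finite monitored cost at epoch {epoch}")
        history.costs.append(cost)

        if cost < best_cost:
            best_cost = cost
            best_weights = model.net.get_weights()
            history.best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
        history.stopped_epoch = epoch
        if since_improve >= config.patience:
            break

    model.net.set_weights(best_weights)
    history.restored = True
    return history


# -- data splitting ---------------------------------------------------------


def ninefold_split(
    n_items: int,
    seed: int,
    n_folds: int = 9,
    groups: Sequence | None = None,
    labels: Sequence | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random equal-size (+-1) train/test partitions.

    With ``groups`` (e.g. source-trial ids) whole groups are assigned to
    folds so crops of one trial never straddle the split; with ``labels``
    folds are additionally stratified so every fold sees both classes.
    """
    if n_items < n_folds:
        raise ValueError(f"need >= {n_folds} items")
    idx = np.arange(n_items)
    if groups is None and labels is None:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(idx)]
    if groups is None:
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in kf.split(idx, np.asarray(labels))]
    groups = np.asarray(groups)
    if len(groups) != n_items:
        raise ValueError("groups length must match n_items")
    if len(np.unique(groups)) < n_folds:
        raise ValueError(f"need >= {n_folds} distinct groups")
    if labels is None:
        labels = np.zeros(n_items, dtype=int)
    kf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                              random_state=seed)
    return [(tr, te) for tr, te in kf.split(idx, np.asarray(labels), groups)]


# -- metrics ----------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts, rows = true class (y=1, y=0), cols = predicted."""

    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("confusion table must be 2x2 with counts >= 0")
        object.__setattr__(self, "table", t.astype(np.int64))

    @classmethod
    def from_predictions(cls, predictions, labels) -> "ConfusionSummary":
        p = np.asarray(predictions)
        y = np.asarray(labels)
        table = np.array([
            [np.sum((y == 1) & (p == 1)), np.sum((y == 1) & (p == 0))],
            [np.sum((y == 0) & (p == 1)), np.sum((y == 0) & (p == 0))],
        ])
        return cls(table)

    @property
    def n(self) -> int:
        return int(self.table.sum())

    @property
    def P0(self) -> float:
        """Observed agreement: diagonal proportion."""
        return float(np.trace(self.table)) / self.n

    @property
    def Pe(self) -> float:
        """Chance agreement from the marginal products."""
        rows = self.table.sum(axis=1)
        cols = self.table.sum(axis=0)
        return float((rows * cols).sum()) / self.n ** 2


def kappa(confusion: ConfusionSummary) -> float:
    """Cohen's kappa (P0 - Pe) / (1 - Pe)."""
    if confusion.n == 0:
        raise ValueError("empty confusion table")
    pe = confusion.Pe
    if pe >= 1.0:
        raise ValueError("degenerate table: chance agreement is 1")
    return (confusion.P0 - pe) / (1.0 - pe)


def per_class_accuracy(predictions, labels) -> tuple[float, float, float]:
    """(class-1 accuracy, class-2 accuracy, |gap|), classes coded y=1 / y=0."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    for cls in (1, 0):
        if not np.any(y == cls):
            raise ValueError(f"class y={cls} absent from labels")
    acc1 = float(np.mean(p[y == 1] == 1))
    acc2 = float(np.mean(p[y == 0] == 0))
    return acc1, acc2, abs(acc1 - acc2)


@dataclass
class CVReport:
    """Per-fold per-class accuracies, kappa, and run-averaged summaries."""

    acc_c1: np.ndarray  # per fold, class y=1
    acc_c2: np.ndarray  # per fold, class y=0
    overall: np.ndarray  # per fold overall accuracy
    kappas: np.ndarray  # per fold
    gamma: float | None = None  # focusing parameter used (None = CE)
    n_runs: int = 1
    class_names: tuple = ("class1", "class2")

    def __post_init__(self) -> None:
        self.acc_c1 = np.asarray(self.acc_c1, dtype=float)
        self.acc_c2 = np.asarray(self.acc_c2, dtype=float)
        self.overall = np.asarray(self.overall, dtype=float)
        self.kappas = np.asarray(self.kappas, dtype=float)

    @property
    def mean_acc_c1(self) -> float:
        return float(self.acc_c1.mean())

    @property
    def mean_acc_c2(self) -> float:
        return float(self.acc_c2.mean())

    @property
    def gap(self) -> float:
        """Absolute gap between the two classes' mean accuracies."""
        return abs(self.mean_acc_c1 - self.mean_acc_c2)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.mean_acc_c1 + self.mean_acc_c2)

    @property
    def mean_accuracy(self) -> float:
        return float(self.overall.mean())

    @property
    def mean_kappa(self) -> float:
        return float(self.kappas.mean())

    def to_dict(self) -> dict:
        return {
            "acc_c1": self.acc_c1.tolist(),
            "acc_c2": self.acc_c2.tolist(),
            "overall": self.overall.tolist(),
            "kappas": self.kappas.tolist(),
            "gamma": self.gamma,
            "n_runs": self.n_runs,
            "class_names": [str(c) for c in self.class_names],
            "mean_acc_c1": self.mean_acc_c1,
            "mean_acc_c2": self.mean_acc_c2,
            "gap": self.gap,
            "mean_accuracy": self.mean_accuracy,
            "mean_kappa": self.mean_kappa,
        }


def average_runs(reports: Sequence[CVReport]) -> CVReport:
    """Elementwise mean of repeated-run reports of identical structure."""
    if len(reports) == 0:
        raise ValueError("no reports to average")
    first = reports[0]
    for r in reports[1:]:
        if (r.acc_c1.shape != first.acc_c1.shape
                or r.class_names != first.class_names):
            raise ValueError("reports have mismatched structure")
    return CVReport(
        np.mean([r.acc_c1 for r in reports], axis=0),
        np.mean([r.acc_c2 for r in reports], axis=0),
        np.mean([r.overall for r in reports], axis=0),
        np.mean([r.kappas for r in reports], axis=0),
        gamma=first.gamma,
        n_runs=sum(r.n_runs for r in reports),
        class_names=first.class_names,
    )


def run_cv(
    crops: CropSet,
    layout: ElectrodeLayout,
    model_config: ModelConfig,
    train_config: TrainConfig,
    n_folds: int = 9,
    group_by_trial: bool = True,
) -> CVReport:
    """Train and test one model per fold; returns the per-fold report."""
    x = segments_to_batch(crops.windows, crops.channel_names, layout)
    y = crops.labels
    groups = crops.trial_ids if group_by_trial else None
    splits = ninefold_split(len(crops), train_config.seed, n_folds, groups,
                            labels=y)
    acc1s, acc2s, overalls, kappas_ = [], [], [], []
    for fold, (tr, te) in enumerate(splits):
        fold_seed = (train_config.seed * 1009 + fold) % (2 ** 31)
        model = build(model_config, seed=fold_seed)
        cfg = replace(train_config, seed=fold_seed)
        train(model, (x[tr], y[tr]), config=cfg)
        pred = model.predict(x[te])
        a1, a2, _ = per_class_accuracy(pred, y[te])
        acc1s.append(a1)
        acc2s.append(a2)
        overalls.append(float(np.mean(pred == y[te])))
        kappas_.append(kappa(ConfusionSummary.from_predictions(pred, y[te])))
    g = None if train_config.loss == LossParams.ce() else train_config.loss.gamma
    return CVReport(np.array(acc1s), np.array(acc2s), np.array(overalls),
                    np.array(kappas_), gamma=g,
                    class_names=crops.class_names)


def run_holdout(
    train_crops: CropSet,
    test_crops: CropSet,
    layout: ElectrodeLayout,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> CVReport:
    """Train on one crop set, evaluate on another; a single-'fold' report.

    Used by the gamma-sweep experiments, where every candidate gamma is
    scored on the same independently generated test trials.
    """
    xtr = segments_to_batch(train_crops.windows, train_crops.channel_names,
                            layout)
    xte = segments_to_batch(test_crops.windows, test_crops.channel_names,
                            layout)
    model = build(model_config, seed=train_config.seed)
    train(model, (xtr, train_crops.labels), config=train_config)
    pred = model.predict(xte)
    y = test_crops.labels
    a1, a2, _ = per_class_accuracy(pred, y)
    overall = float(np.mean(pred == y))
    k = kappa(ConfusionSummary.from_predictions(pred, y))
    g = None if train_config.loss == LossParams.ce() \
        else train_config.loss.gamma
    return CVReport([a1], [a2], [overall], [k], gamma=g,
                    class_names=train_crops.class_names)


@dataclass
class SweepResult:
    """Outcome of the gamma-sweep protocol."""

    swept: bool
    baseline: CVReport
    curve: dict  # gamma -> CVReport
    best_gamma: float | None
    final: CVReport


def default_gamma_grid() -> np.ndarray:
    """The full protocol's grid: 0 to 11 in steps of 0.5."""
    return np.arange(0.0, 11.5, 0.5)


def gamma_sweep(
    run_fn: Callable[[float, int], CVReport],
    baseline: CVReport,
    grid: Sequence[float] | None = None,
    trigger_gap: float = 0.3,
    runs_per_gamma: int = 1,
    base_seed: int = 0,
    criterion: str = "balanced_accuracy",
) -> SweepResult:
    """Sweep the focusing parameter when the CE baseline is imbalanced.

    ``run_fn(gamma, seed)`` trains with focal loss at that gamma and returns
    a CVReport.  The sweep runs only if ``baseline.gap > trigger_gap``.  The
    best gamma maximizes ``criterion`` ("balanced_accuracy" or
    "min_class_accuracy"); the final report averages ``runs_per_gamma``
    repetitions at that gamma.
    """
    if criterion not in ("balanced_accuracy", "min_class_accuracy"):
        raise ValueError("unknown selection criterion")
    if baseline.gap <= trigger_gap:
        return SweepResult(False, baseline, {}, None, baseline)
    grid = default_gamma_grid() if grid is None else np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty gamma grid")

    def score(r: CVReport) -> float:
        if criterion == "min_class_accuracy":
            return min(r.mean_acc_c1, r.mean_acc_c2)
        return r.balanced_accuracy

    curve: dict[float, CVReport] = {}
    for g in grid:
        curve[float(g)] = run_fn(float(g), (base_seed * 131 + 7) % (2 ** 31))
    best_gamma = max(curve, key=lambda g: score(curve[g]))
    repeats = [curve[best_gamma]]
    for r in range(1, runs_per_gamma):
        repeats.append(run_fn(best_gamma, (base_seed * 131 + 7 + r) % (2 ** 31)))
    return SweepResult(True, baseline, curve, best_gamma,
                       average_runs(repeats))
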