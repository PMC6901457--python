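"""Classifier adapter, fitness, external metrics and the repeated-CV protocol.

The fitness of a feature subset is the balanced rate

    F = (TP/(TP+FN) + TN/(TN+FP)) / 2

i.e. the mean of sensitivity and specificity, which protects against the
majority-class bias of plain accuracy on the unbalanced class counts typical
of tumor/normal cohorts.  External evaluation follows a repeated stratified
k-fold protocol (default 10 repeats of 10-fold): feature selection and every
fold-local statistic are fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from sklearn.svm import SVC

from .data_io import ExpressionDataset, FoldPlan, apply_minmax, minmax_stats, subset_samples

if TYPE_CHECKING:  # pragma: no cover
    from .sfla_engine import SFLAConfig, SelectionResult


@dataclass
class ClassifierConfig:
    """SVM settings used both for the internal fitness CV and external folds."""

    kernel: str = "linear"
    C: float = 1.0
    gamma: str | float = "scale"

    def build(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def add_predictions(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        self.tp += int(((y_true == 1) & (y_pred == 1)).sum())
        self.tn += int(((y_true == -1) & (y_pred == -1)).sum())
        self.fp += int(((y_true == -1) & (y_pred == 1)).sum())
        self.fn += int(((y_true == 1) & (y_pred == -1)).sum())

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        c = cls()
        c.add_predictions(y_true, y_pred)
        return c


@dataclass
class MetricReport:
    accuracy: float
    specificity: float
    sensitivity: float
    balance_rate: float

    def as_percent(self) -> dict[str, float]:
        return {
            "accuracy": 100.0 * self.accuracy,
            "specificity": 100.0 * self.specificity,
            "sensitivity": 100.0 * self.sensitivity,
            "balance_rate": 100.0 * self.balance_rate,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def fitness(counts: ConfusionCounts) -> float:
    """Balanced rate of a confusion table; an absent class contributes 0."""
    sens = _safe_div(counts.tp, counts.tp + counts.fn)
    spec = _safe_div(counts.tn, counts.tn + counts.fp)
    return (sens + spec) / 2.0


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, specificity, sensitivity and balanced rate of a confusion table."""
    if counts.total == 0:
        raise ValueError("metrics are undefined for an empty confusion table")
    sens = _safe_div(counts.tp, counts.tp + counts.fn)
    spec = _safe_div(counts.tn, counts.tn + counts.fp)
    return MetricReport(
        accuracy=(counts.tp + counts.tn) / counts.total,
        specificity=spec,
        sensitivity=sens,
        balance_rate=(spec + sens) / 2.0,
    )


def _fit_predict(
    values: np.ndarray,
    labels: np.ndarray,
    subset: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    clf_config: ClassifierConfig,
) -> np.ndarray:
    """Train on ``train_rows`` (fold-local min-max stats) and predict ``test_rows``."""
    cols = values[:, subset]
    lo, rng = minmax_stats(cols, train_rows)
    scaled = apply_minmax(cols, lo, rng)
    clf = clf_config.build()
    clf.fit(scaled[train_rows], labels[train_rows])
    return clf.predict(scaled[test_rows])


def evaluate_subset(
    subset: list[int] | np.ndarray,
    data: ExpressionDataset,
    folds: FoldPlan,
    clf_config: ClassifierConfig | None = None,
) -> tuple[MetricReport, list[ConfusionCounts]]:
    """External CV of a fixed feature subset.

    Counts are pooled per repeat; the returned report averages the per-repeat
    metrics (the protocol's "average of 10-fold CV repetitions").
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be non-empty")
    if subset.min() < 0 or subset.max() >= data.n_features:
        raise ValueError("subset references unknown features")
    clf_config = clf_config or ClassifierConfig()
    per_repeat: list[ConfusionCounts] = []
    for r in range(folds.repeats):
        counts = ConfusionCounts()
        for f in range(folds.k):
            test_rows = folds.test_rows(r, f)
            train_rows = folds.train_rows(r, f)
            pred = _fit_predict(data.values, data.labels, subset, train_rows, test_rows, clf_config)
            counts.add_predictions(data.labels[test_rows], pred)
        per_repeat.append(counts)
    reports = [metrics(c) for c in per_repeat]
    mean = MetricReport(
        accuracy=float(np.mean([m.accuracy for m in reports])),
        specificity=float(np.mean([m.specificity for m in reports])),
        sensitivity=float(np.mean([m.sensitivity for m in reports])),
        balance_rate=float(np.mean([m.balance_rate for m in reports])),
    )
    return mean, per_repeat


# ---------------------------------------------------------------------------
# outer protocol: selection inside each training split
# ---------------------------------------------------------------------------

@dataclass
class SplitOutcome:
    repeat: int
    fold: int
    subset: tuple[int, ...]
    counts: ConfusionCounts
    selection: "SelectionResult" = field(repr=False, default=None)


@dataclass
class ProtocolResult:
    report: MetricReport
    mean_subset_size: float
    modal_subset: tuple[int, ...]
    per_split: list[SplitOutcome]
    per_repeat_counts: list[ConfusionCounts]


def run_protocol(
    data: ExpressionDataset,
    config: "SFLAConfig",
    k: int = 10,
    repeats: int = 10,
) -> ProtocolResult:
    """Repeated k-fold protocol around the full selection pipeline.

    Per split: run Relief -> SFLA-IWSSr on the training rows, then train the
    classifier on those rows restricted to the selected subset and score the
    held-out fold.  Metrics are pooled per repeat then averaged; the subset
    size is averaged over all splits.
    """
    from .data_io import make_folds
    from .sfla_engine import run  # deferred: sfla_engine imports this module

    folds = make_folds(data, k=k, repeats=repeats, seed=config.seed)
    clf_config = ClassifierConfig(kernel=config.svm_kernel, C=config.svm_c, gamma=config.svm_gamma)
    per_split: list[SplitOutcome] = []
    per_repeat: list[ConfusionCounts] = []
    for r in range(repeats):
        counts = ConfusionCounts()
        for f in range(k):
            train_rows = folds.train_rows(r, f)
            test_rows = folds.test_rows(r, f)
            split_config = config.with_seed(_split_seed(config.seed, r, f))
            selection = run(subset_samples(data, train_rows), split_config)
            subset = np.asarray(selection.best_frog.features, dtype=int)
            pred = _fit_predict(data.values, data.labels, subset, train_rows, test_rows, clf_config)
            counts.add_predictions(data.labels[test_rows], pred)
            per_split.append(
                SplitOutcome(
                    repeat=r,
                    fold=f,
                    subset=tuple(int(j) for j in subset),
                    counts=ConfusionCounts.from_predictions(data.labels[test_rows], pred),
                    selection=selection,
                )
            )
        per_repeat.append(counts)
    reports = [metrics(c) for c in per_repeat]
    mean = MetricReport(
        accuracy=float(np.mean([m.accuracy for m in reports])),
        specificity=float(np.mean([m.specificity for m in reports])),
        sensitivity=float(np.mean([m.sensitivity for m in reports])),
        balance_rate=float(np.mean([m.balance_rate for m in reports])),
    )
    sizes = [len(s.subset) for s in per_split]
    subsets = [frozenset(s.subset) for s in per_split]
    modal = max(set(subsets), key=lambda s: (subsets.count(s), -len(s)))
    return ProtocolResult(
        report=mean,
        mean_subset_size=float(np.mean(sizes)),
        modal_subset=tuple(sorted(modal)),
        per_split=per_split,
        per_repeat_counts=per_repeat,
    )


def _split_seed(seed: int, repeat: int, fold: int) -> int:
    """Stable per-split seed below 2**31."""
    return int(np.random.SeedSequence((seed, repeat, fold)).generate_state(1)[0] % (2**31 - 1))
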