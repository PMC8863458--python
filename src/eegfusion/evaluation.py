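"""Inverted N-fold few-shot cross-validation and its summary statistics.

The protocol deliberately inverts the usual convention: the samples are
partitioned into N class-stratified folds, and each fold in turn is the
*training* set while the remaining N-1 folds form the validation set.  With
100 samples per class this gives training sets of 40 (5-fold), 20 (10-fold)
or 10 (20-fold) samples — the few-shot regime of interest.

Reported statistics are the arithmetic mean of the per-fold accuracies and
their sample standard deviation (divisor N-1), both rounded to four decimals
at reporting time only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import EEGFusionError, InvalidInputError
from .architecture import METHOD_BRANCHES, ArchConfig, HybridNetwork, stack_hybrids
from .segment import EEGSegment, labels_to_indices
from .training import TrainConfig, train_model
from .transforms import HybridInput, TransformConfig, make_hybrid

__all__ = [
    "FoldPlan",
    "FoldReport",
    "make_fold_plan",
    "accuracy",
    "summarize_folds",
    "evaluate_in_batches",
    "run_experiment",
]


@dataclass(frozen=True)
class FoldPlan:
    """Class-stratified fold assignment with inverted train/validate roles."""

    n_folds: int
    assignments: np.ndarray  # per-sample fold index
    task: str = ""
    inverted: bool = True

    @property
    def train_size(self) -> int:
        return int(np.sum(self.assignments == 0))

    def train_indices(self, fold: int) -> np.ndarray:
        mask = self.assignments == fold
        return np.flatnonzero(mask if self.inverted else ~mask)

    def validation_indices(self, fold: int) -> np.ndarray:
        mask = self.assignments == fold
        return np.flatnonzero(~mask if self.inverted else mask)


@dataclass
class FoldReport:
    """Per-fold accuracies with mean and dispersion (sample SD)."""

    per_fold_accuracy: list[float]
    method_label: str = ""
    records: list | None = None  # per-fold TrainRecords when collected

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def dispersion(self) -> float:
        return float(np.std(self.per_fold_accuracy, ddof=1))

    def summary(self) -> pd.DataFrame:
        """One-row table shaped like the published fold tables (K1..KN, Mean, Variance)."""
        cols = {f"K{i + 1}": round(a, 4) for i, a in enumerate(self.per_fold_accuracy)}
        cols["Mean"] = round(self.mean_accuracy, 4)
        cols["Variance"] = round(self.dispersion, 4)
        return pd.DataFrame([cols], index=[self.method_label or "method"])


def make_fold_plan(
    labels: np.ndarray | list[EEGSegment],
    n_folds: int,
    task: str = "",
    seed: int = 0,
    inverted: bool = True,
) -> FoldPlan:
    """Seeded, class-stratified partition into ``n_folds`` equal folds.

    Every class count must divide evenly by ``n_folds`` so folds stay
    balanced.  Under the default inverted semantics fold ``f`` trains on its
    own members and validates on everything else.
    """
    if isinstance(labels, list) and labels and isinstance(labels[0], EEGSegment):
        labels = labels_to_indices(labels)
    y = np.asarray(labels, dtype=np.int64).ravel()
    if n_folds < 2:
        raise InvalidInputError("n_folds must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    assignments = np.full(y.size, -1, dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size % n_folds != 0:
            raise InvalidInputError(
                f"class {cls} count {idx.size} is not divisible by {n_folds} folds"
            )
        idx = rng.permutation(idx)
        per = idx.size // n_folds
        for f in range(n_folds):
            assignments[idx[f * per : (f + 1) * per]] = f
    return FoldPlan(n_folds=n_folds, assignments=assignments, task=task, inverted=inverted)


def accuracy(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of exact matches."""
    p = np.asarray(predictions).ravel()
    y = np.asarray(labels).ravel()
    if p.size != y.size:
        raise InvalidInputError("predictions and labels disagree in length")
    if p.size == 0:
        raise InvalidInputError("empty prediction set")
    return float(np.mean(p == y))


def summarize_folds(per_fold_accuracy, method_label: str = "") -> FoldReport:
    """Mean and sample standard deviation (divisor N-1) of fold accuracies."""
    accs = [float(a) for a in per_fold_accuracy]
    if len(accs) < 2:
        raise InvalidInputError("need at least 2 folds to summarize")
    return FoldReport(per_fold_accuracy=accs, method_label=method_label)


def evaluate_in_batches(
    model: HybridNetwork,
    arrays: dict[str, np.ndarray],
    indices: np.ndarray,
    batch_size: int = 8,
) -> np.ndarray:
    """Predicted class indices for the given sample indices.

    Evaluation runs in small batches purely to bound the im2col workspace;
    batch-norm uses running statistics, so per-sample outputs do not depend
    on batch composition.
    """
    preds = np.empty(indices.size, dtype=np.int64)
    for start in range(0, indices.size, batch_size):
        idx = indices[start : start + batch_size]
        xb = {k: np.ascontiguousarray(a[:, idx]) for k, a in arrays.items()}
        preds[start : start + idx.size] = model.predict(xb)
    return preds


def run_experiment(
    samples: list[EEGSegment] | list[HybridInput],
    method: str = "Hybrid",
    n_folds: int = 5,
    train_config: TrainConfig | None = None,
    seed: int = 0,
    transform_config: TransformConfig | None = None,
    arch: ArchConfig | None = None,
    task: str = "",
    collect_records: bool = False,
) -> FoldReport:
    """Train and validate one method under the inverted N-fold protocol.

    ``method`` is one of EEG / FFT / STFT / DWT (single-branch baselines) or
    Hybrid (all four branches).  Each fold re-initializes the model with a
    fold-indexed seed derived from the master ``seed``; the fold plan uses
    the master seed directly.
    """
    if method not in METHOD_BRANCHES:
        raise InvalidInputError(
            f"method must be one of {sorted(METHOD_BRANCHES)}, got {method!r}"
        )
    train_config = train_config or TrainConfig()
    branches = METHOD_BRANCHES[method]

    if samples and isinstance(samples[0], EEGSegment):
        hybrids = [make_hybrid(s, transform_config) for s in samples]
    else:
        hybrids = list(samples)
    y = labels_to_indices([h.raw for h in hybrids])
    plan = make_fold_plan(y, n_folds, task=task, seed=seed)
    arrays = stack_hybrids(hybrids, branches)

    fold_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(entropy=seed, spawn_key=(2,)).spawn(n_folds)
    ]
    per_fold = []
    records = []
    for fold in range(n_folds):
        tr = plan.train_indices(fold)
        va = plan.validation_indices(fold)
        cfg = dataclasses.replace(train_config, seed=fold_seeds[fold])
        xtr = {k: np.ascontiguousarray(a[:, tr]) for k, a in arrays.items()}
        try:
            record = train_model(xtr, y[tr], cfg, branches=branches, arch=arch)
        except EEGFusionError as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        preds = evaluate_in_batches(record.model, arrays, va)
        per_fold.append(accuracy(preds, y[va]))
        if collect_records:
            records.append(record)
    report = summarize_folds(per_fold, method_label=method)
    if collect_records:
        report.records = records
    return report
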