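"""Cross-validation of the activity pipeline and per-class metrics.

Two schemes are reported side by side:

* **K-fold** (K = 10, class-stratified): the conventional estimate, but
  windows from one subject can appear in both the training and the test
  fold, so it is optimistic about generalization to new people.
* **Leave-one-subject-out (LOSO)**: all windows of one subject form the
  test fold; this measures inter-subject generalization, the quantity that
  matters for deployment on a new patient.

Feature selection and standardization are refit inside every training fold
(no leakage); ``select_once`` on the pipeline config selects once on the full
dataset instead, for comparison with select-once protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nca as nca_mod
from .config import PipelineConfig
from .pipeline import ActivityPipeline
from .types import ALL_CODES, ACTIVITY_NAMES, LabeledDataset, ValidationError

log = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    """A 6x6 confusion matrix with accuracy and per-class recall/precision (%).

    Metrics for a class absent from both truth and predictions are reported
    as ``None`` (absent), not 0.
    """

    matrix: np.ndarray  # rows: truth, cols: predicted, ordered by code 1..6
    n_samples: int

    @property
    def accuracy(self) -> float:
        return 100.0 * np.trace(self.matrix) / self.n_samples

    def recall(self, code: int) -> Optional[float]:
        i = code - 1
        row = self.matrix[i].sum()
        return 100.0 * self.matrix[i, i] / row if row > 0 else None

    def precision(self, code: int) -> Optional[float]:
        i = code - 1
        col = self.matrix[:, i].sum()
        return 100.0 * self.matrix[i, i] / col if col > 0 else None

    def per_class(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "activity": [ACTIVITY_NAMES[c] for c in ALL_CODES],
                "recall_pct": [self.recall(c) for c in ALL_CODES],
                "precision_pct": [self.precision(c) for c in ALL_CODES],
            }
        )

    def min_recall_precision(self) -> float:
        """Minimum over all defined per-class recall and precision values."""
        vals = [v for c in ALL_CODES for v in (self.recall(c), self.precision(c)) if v is not None]
        return min(vals)


def evaluate(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionSummary:
    """Confusion matrix and metrics for paired truth/prediction labels."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.size == 0:
        raise ValidationError("cannot evaluate an empty label set")
    if truth.shape != predicted.shape:
        raise ValidationError("truth and predicted must have equal length")
    for arr, name in ((truth, "truth"), (predicted, "predicted")):
        bad = set(arr.tolist()) - set(ALL_CODES)
        if bad:
            raise ValidationError(f"{name} contains unknown codes {sorted(bad)}")
    m = np.zeros((6, 6), dtype=int)
    np.add.at(m, (truth - 1, predicted - 1), 1)
    return ConfusionSummary(matrix=m, n_samples=int(truth.size))


@dataclass
class CvReport:
    """Per-fold and pooled results of one cross-validation run."""

    scheme: str  # "kfold" or "loso"
    folds: List[ConfusionSummary]
    pooled: ConfusionSummary
    fold_ids: List[str]
    seed: int

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    def accuracy_distribution(self) -> Dict[str, float]:
        acc = self.fold_accuracies
        return {
            "median": float(np.median(acc)),
            "min": float(np.min(acc)),
            "max": float(np.max(acc)),
        }

    def table(self) -> pd.DataFrame:
        """Per-activity recall/precision: pooled and median (min-max) over folds."""
        rows = []
        for c in ALL_CODES:
            rec = [f.recall(c) for f in self.folds]
            prec = [f.precision(c) for f in self.folds]
            rec = [v for v in rec if v is not None]
            prec = [v for v in prec if v is not None]
            rows.append(
                {
                    "activity": ACTIVITY_NAMES[c],
                    "recall_pooled": self.pooled.recall(c),
                    "recall_median": float(np.median(rec)) if rec else None,
                    "recall_min": float(np.min(rec)) if rec else None,
                    "recall_max": float(np.max(rec)) if rec else None,
                    "precision_pooled": self.pooled.precision(c),
                    "precision_median": float(np.median(prec)) if prec else None,
                    "precision_min": float(np.min(prec)) if prec else None,
                    "precision_max": float(np.max(prec)) if prec else None,
                }
            )
        return pd.DataFrame(rows)


def _run_folds(
    dataset: LabeledDataset,
    splits,
    fold_ids: List[str],
    config: PipelineConfig,
    seed: int,
    scheme: str,
) -> CvReport:
    fixed = None
    if config.select_once:
        Xs, mean_, scale_ = nca_mod.standardize(dataset.features)
        std_all = LabeledDataset(Xs, dataset.labels, dataset.subject_ids, list(dataset.feature_names))
        fixed = nca_mod.fit_nca(
            std_all,
            lambda_reg=config.nca.lambda_reg,
            max_iterations=config.nca.max_iterations,
            seed=seed,
            threshold=config.nca.threshold,
            max_samples=config.nca.max_samples,
        )
    folds = []
    pooled_truth, pooled_pred = [], []
    for k, (train_idx, test_idx) in enumerate(splits):
        pipe = ActivityPipeline(config)
        pipe.fit(dataset.subset(train_idx), seed=seed + k, fixed_selection=fixed)
        pred, _ = pipe.predict(dataset.features[test_idx])
        truth = dataset.labels[test_idx]
        folds.append(evaluate(truth, pred))
        pooled_truth.append(truth)
        pooled_pred.append(pred)
    pooled = evaluate(np.concatenate(pooled_truth), np.concatenate(pooled_pred))
    return CvReport(scheme=scheme, folds=folds, pooled=pooled, fold_ids=fold_ids, seed=seed)


def kfold_cv(
    dataset: LabeledDataset,
    k: int = 10,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> CvReport:
    """Class-stratified K-fold cross-validation of the full pipeline."""
    config = config or PipelineConfig()
    if k > dataset.n_samples:
        raise ValidationError(f"k={k} exceeds n={dataset.n_samples}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(dataset.features, dataset.labels))
    return _run_folds(dataset, splits, [f"fold{k}" for k in range(k)], config, seed, "kfold")


def loso_cv(
    dataset: LabeledDataset,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    subjects: Optional[Sequence] = None,
) -> CvReport:
    """Leave-one-subject-out cross-validation: one fold per subject."""
    config = config or PipelineConfig()
    all_subjects = list(dict.fromkeys(dataset.subject_ids.tolist()))  # stable order
    if subjects is not None:
        all_subjects = [s for s in all_subjects if s in set(subjects)]
    if len(all_subjects) < 2:
        raise ValidationError("LOSO needs at least 2 subjects")
    splits = []
    for s in all_subjects:
        test = np.flatnonzero(dataset.subject_ids == s)
        train = np.flatnonzero(dataset.subject_ids != s)
        splits.append((train, test))
    return _run_folds(dataset, splits, [str(s) for s in all_subjects], config, seed, "loso")


def learning_curve(
    dataset: LabeledDataset,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    n_values: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """LOSO performance on nested subject subsets n = 2..N.

    Subjects enter in a fixed seeded order, so each larger subset contains
    the previous one. Returns pooled accuracy and the worst per-class
    recall/precision at each n.
    """
    config = config or PipelineConfig()
    subjects = list(dict.fromkeys(dataset.subject_ids.tolist()))
    if len(subjects) < 3:
        raise ValidationError("learning curve needs >= 3 subjects")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    if n_values is None:
        n_values = range(2, len(subjects) + 1)
    rows = []
    for n in n_values:
        chosen = set(order[:n])
        sub = dataset.subset(np.isin(dataset.subject_ids, list(chosen)))
        report = loso_cv(sub, config, seed=seed)
        rows.append(
            {
                "n_subjects": n,
                "accuracy_pct": report.pooled.accuracy,
                "min_recall_pct": min(
                    (v for c in ALL_CODES if (v := report.pooled.recall(c)) is not None),
                ),
                "min_precision_pct": min(
                    (v for c in ALL_CODES if (v := report.pooled.precision(c)) is not None),
                ),
            }
        )
    return pd.DataFrame(rows)


def sensor_ablation(
    dataset: LabeledDataset,
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    sensor_sets: Sequence[str] = ("arm", "leg", "both"),
    schemes: Sequence[str] = ("kfold", "loso"),
    k: int = 10,
) -> pd.DataFrame:
    """Single-sensor sensitivity analysis: re-run CV on site-masked features.

    Feature names encode the site as an ``arm_``/``leg_`` prefix, so masking
    works on any dataset following the canonical naming.
    """
    config = config or PipelineConfig()
    rows = []
    for sensors in sensor_sets:
        if sensors == "both":
            sub = dataset
        elif sensors in ("arm", "leg"):
            mask = np.array([n.startswith(f"{sensors}_") for n in dataset.feature_names])
            sub = dataset.select_columns(mask)
        else:
            raise ValidationError(f"unknown sensor set {sensors!r}")
        row = {"sensor_set": sensors, "n_features": sub.n_features}
        if "kfold" in schemes:
            row["kfold_accuracy_pct"] = kfold_cv(sub, k=k, config=config, seed=seed).pooled.accuracy
        if "loso" in schemes:
            row["loso_accuracy_pct"] = loso_cv(sub, config=config, seed=seed).pooled.accuracy
        rows.append(row)
    return pd.DataFrame(rows)
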