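"""Diagonal-metric neighbourhood component analysis for feature selection.

NCA learns per-feature weights w by maximizing a smooth surrogate of
leave-one-out 1-NN accuracy. With the diagonal (per-feature) metric

    d(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|,

the stochastic neighbour probabilities are p_ij = exp(-d_ij) / sum_k exp(-d_ik)
(k != i), the probability that sample i is correctly classified is
p_i = sum_{j : y_j = y_i} p_ij, and the regularized objective is

    F(w) = (1/n) sum_i p_i - lambda * sum_r w_r^2.

F is maximized by per-sample stochastic gradient ascent (weights start at 1,
one epoch = one pass over a seeded shuffle, learning rate decaying as
1/(1 + t * decay)). The sign of each w_r is irrelevant (only w_r^2 enters the
model), so weights are reported as magnitudes; features whose weight falls
below the threshold (default 0.1) carry no useful neighbourhood structure
and are discarded.

For large training sets the objective is evaluated against a seeded
class-stratified reference subsample (``max_samples``): each SGD step still
visits every reference point, so cost per epoch is O(m^2 p) with m capped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .types import LabeledDataset, ValidationError

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1
DEFAULT_MAX_ITERATIONS = 30


@dataclass
class NcaResult:
    """Fitted per-feature weights and the derived selection mask."""

    weights: np.ndarray
    selected_mask: np.ndarray
    threshold: float
    lambda_reg: float
    seed: int
    n_iterations_run: int
    objective_per_epoch: List[float] = field(default_factory=list)
    feature_names: List[str] = field(default_factory=list)
    # standardization parameters of the fit, reused at prediction time
    mean_: Optional[np.ndarray] = None
    scale_: Optional[np.ndarray] = None

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.selected_mask))


def standardize(X: np.ndarray, mean=None, scale=None):
    """Zero-mean unit-variance scaling; zero-variance columns get scale 1."""
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def _objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, lambda_reg: float) -> float:
    """Exact regularized objective, O(n^2 p); used for epoch tracking."""
    n = X.shape[0]
    w2 = w * w
    p_i = np.empty(n)
    for i in range(n):
        d = np.abs(X - X[i]) @ w2
        d[i] = np.inf
        e = np.exp(-(d - d.min()))
        e[i] = 0.0
        denom = e.sum()
        p_i[i] = e[y == y[i]].sum() / denom if denom > 0 else 0.0
    return float(p_i.mean() - lambda_reg * np.sum(w2))


def _stratified_subsample(y: np.ndarray, max_samples: int, rng: np.random.Generator) -> np.ndarray:
    n = y.shape[0]
    if n <= max_samples:
        return np.arange(n)
    classes, counts = np.unique(y, return_counts=True)
    # proportional allocation, at least 2 per class
    take = np.maximum(2, np.floor(counts / n * max_samples).astype(int))
    idx = []
    for c, t in zip(classes, take):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=min(t, members.size), replace=False))
    return np.sort(np.concatenate(idx))


def fit_nca(
    dataset: LabeledDataset,
    lambda_reg: Optional[float] = None,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    learning_rate: float = 0.1,
    decay: float = 1e-4,
    max_samples: Optional[int] = 500,
) -> NcaResult:
    """Fit diagonal NCA weights by stochastic gradient ascent.

    Parameters
    ----------
    dataset
        Standardized features (standardization is checked; if the input is
        not standardized a warning is logged and it is standardized
        internally — the parameters used are stored on the result either way).
    lambda_reg
        Ridge penalty on the squared weights; default ``1/n``.
    max_iterations
        Maximum number of SGD epochs (default 30).
    threshold
        Features with fitted weight >= threshold are selected (default 0.1).
    max_samples
        Cap on the reference sample for the fit (seeded stratified
        subsample); ``None`` disables the cap.
    """
    X = np.asarray(dataset.features, dtype=float)
    y = np.asarray(dataset.labels)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("NCA needs at least 2 classes")
    if np.any(counts < 2):
        singletons = classes[counts < 2].tolist()
        raise ValidationError(f"class(es) {singletons} have fewer than 2 samples")

    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0, ddof=0)
    if np.max(np.abs(col_mean)) > 1e-6 or np.max(np.abs(col_sd[col_sd > 0] - 1)) > 1e-6:
        log.warning("NCA input is not standardized; standardizing internally")
        X, mean_, scale_ = standardize(X)
    else:
        mean_ = np.zeros(p)
        scale_ = np.ones(p)

    rng = np.random.default_rng(seed)
    ref = _stratified_subsample(y, max_samples, rng) if max_samples else np.arange(n)
    Xr, yr = X[ref], y[ref]
    m = Xr.shape[0]
    if lambda_reg is None:
        lambda_reg = 1.0 / m

    w = np.ones(p)
    t = 0
    objective_per_epoch = [_objective(Xr, yr, w, lambda_reg)]
    n_run = 0
    for epoch in range(max_iterations):
        order = rng.permutation(m)
        for i in order:
            diffs = np.abs(Xr - Xr[i])  # (m, p)
            d = diffs @ (w * w)
            d[i] = np.inf
            e = np.exp(-(d - np.min(d)))
            e[i] = 0.0
            denom = e.sum()
            if denom <= 0:
                continue
            prob = e / denom
            same = yr == yr[i]
            p_i = prob[same].sum()
            grad = 2.0 * w * (p_i * (prob @ diffs) - (prob * same) @ diffs) - 2.0 * lambda_reg * w
            lr = learning_rate / (1.0 + t * decay)
            w = w + lr * grad
            t += 1
        n_run = epoch + 1
        objective_per_epoch.append(_objective(Xr, yr, w, lambda_reg))
        # converged when the last weight change across an epoch is negligible
        if epoch > 0 and abs(objective_per_epoch[-1] - objective_per_epoch[-2]) < 1e-6:
            break

    weights = np.abs(w)
    mask = weights >= threshold
    result = NcaResult(
        weights=weights,
        selected_mask=mask,
        threshold=threshold,
        lambda_reg=float(lambda_reg),
        seed=seed,
        n_iterations_run=n_run,
        objective_per_epoch=objective_per_epoch,
        feature_names=list(dataset.feature_names),
        mean_=mean_,
        scale_=scale_,
    )
    log.info("NCA selected %d of %d features (threshold %.3g, %d epochs)",
             result.n_selected, p, threshold, n_run)
    return result


def apply_selection(dataset: LabeledDataset, result: NcaResult) -> LabeledDataset:
    """Reduce a dataset to the NCA-selected feature columns."""
    if dataset.n_features != result.weights.shape[0]:
        raise ValidationError(
            f"dataset has {dataset.n_features} features but the NCA result has "
            f"{result.weights.shape[0]} weights"
        )
    if result.feature_names and dataset.feature_names and list(dataset.feature_names) != list(result.feature_names):
        raise ValidationError("feature name order differs between dataset and NCA result")
    if result.n_selected == 0:
        raise ValidationError("NCA selected no features; refusing an empty feature set")
    return dataset.select_columns(result.selected_mask)


def threshold_sweep(result: NcaResult, thresholds=None):
    """n_selected as a function of the selection threshold (sensitivity aid)."""
    import pandas as pd

    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.01, 0.05), 2)
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "n_selected": [int(np.sum(result.weights >= t)) for t in thresholds],
        }
    )
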