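"""Class balancing and the feed-forward activity classifier.

The network mirrors the architecture used for the ward study: one hidden
layer of 18 tanh units and a softmax output over the six activities,
trained with cross-entropy loss and early stopping on a held-out 15% of the
training samples. Static postures are recorded far more often than dynamic
movements on a ward (roughly 3:1), so training sets are rebalanced by
seeded uniform down-sampling to the smallest class before fitting.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from sklearn.neural_network import MLPClassifier

from .types import ALL_CODES, ACTIVITY_NAMES, DYNAMIC_CODES, STATIC_CODES, LabeledDataset, ValidationError

log = logging.getLogger(__name__)

HIDDEN_NODES = 18
MAX_EPOCHS = 500
VALIDATION_FRACTION = 0.15
PATIENCE = 10


def balance_classes(
    dataset: LabeledDataset,
    seed: int = 0,
    static_dynamic_ratio: Optional[float] = None,
) -> LabeledDataset:
    """Down-sample every class to the smallest class count (seeded, shuffled).

    With ``static_dynamic_ratio`` set (e.g. 3.0), static classes are instead
    capped at ratio x the smallest dynamic-class count, leaving dynamic
    classes untouched — a looser rebalancing for imbalance-tolerant
    experiments.
    """
    counts = dataset.class_counts()
    missing = [c for c in ALL_CODES if counts.get(c, 0) == 0]
    if missing:
        names = ", ".join(ACTIVITY_NAMES[c] for c in missing)
        raise ValidationError(f"cannot balance: class(es) absent from dataset: {names}")
    rng = np.random.default_rng(seed)
    keep = []
    if static_dynamic_ratio is None:
        target = {c: min(counts.values()) for c in ALL_CODES}
    else:
        min_dyn = min(counts[c] for c in DYNAMIC_CODES)
        cap = int(round(static_dynamic_ratio * min_dyn))
        target = {c: (min(counts[c], cap) if c in STATIC_CODES else counts[c]) for c in ALL_CODES}
    for c in ALL_CODES:
        members = np.flatnonzero(dataset.labels == c)
        keep.append(rng.choice(members, size=target[c], replace=False))
    index = rng.permutation(np.concatenate(keep))
    return dataset.subset(index)


@dataclass
class AnnModel:
    """A trained feed-forward network plus everything needed to apply it.

    ``estimator`` is the fitted scikit-learn MLP; ``classes_`` are the
    activity codes it predicts. ``mean_``/``scale_`` are the feature
    standardization parameters of the training fold and ``feature_mask`` the
    NCA selection applied before the network (both optional: the bare
    classifier works on already-prepared matrices).
    """

    estimator: MLPClassifier
    input_dim: int
    seed: int
    hidden_nodes: int = HIDDEN_NODES
    mean_: Optional[np.ndarray] = None
    scale_: Optional[np.ndarray] = None
    feature_mask: Optional[np.ndarray] = None
    feature_names: list = field(default_factory=list)

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    @property
    def hidden_weights(self) -> np.ndarray:
        return self.estimator.coefs_[0]

    @property
    def output_weights(self) -> np.ndarray:
        return self.estimator.coefs_[1]

    @property
    def n_epochs_run(self) -> int:
        return self.estimator.n_iter_

    @property
    def final_loss(self) -> float:
        return float(self.estimator.loss_)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "AnnModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, AnnModel):
            raise ValidationError(f"{path} does not contain an AnnModel")
        return model


def train(
    dataset: LabeledDataset,
    hidden_nodes: int = HIDDEN_NODES,
    seed: int = 0,
    max_epochs: int = MAX_EPOCHS,
) -> AnnModel:
    """Train the one-hidden-layer network on a prepared dataset.

    Expects balanced, selected, standardized features. 15% of the samples
    are held out for early stopping (patience 10 epochs, at most 500).
    Deterministic given the seed.
    """
    counts = dataset.class_counts()
    if any(v < 2 for v in counts.values()):
        raise ValidationError(f"need >= 2 samples per class to train, got {counts}")
    # small minibatches + a brisk initial rate: enough optimizer steps per
    # epoch that 10-epoch patience is meaningful even on small folds
    est = MLPClassifier(
        hidden_layer_sizes=(hidden_nodes,),
        activation="tanh",
        solver="adam",
        learning_rate_init=0.01,
        batch_size=min(32, dataset.n_samples),
        max_iter=max_epochs,
        early_stopping=True,
        validation_fraction=VALIDATION_FRACTION,
        n_iter_no_change=PATIENCE,
        random_state=seed,
    )
    est.fit(dataset.features, dataset.labels)
    log.info("ANN trained: %d epochs, final loss %.4f", est.n_iter_, est.loss_)
    return AnnModel(
        estimator=est,
        input_dim=dataset.n_features,
        seed=seed,
        hidden_nodes=hidden_nodes,
        feature_names=list(dataset.feature_names),
    )


def predict(model: AnnModel, features: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Predicted activity codes and class probabilities for a feature matrix.

    The label is the argmax of the softmax output; exact ties break toward
    the lowest activity code. Probability rows sum to 1.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != model.input_dim:
        raise ValidationError(
            f"feature dimension {features.shape[1]} != model input dimension {model.input_dim}"
        )
    proba = model.estimator.predict_proba(features)
    # argmax returns the first (lowest-code) class on ties
    labels = model.classes_[np.argmax(proba, axis=1)]
    return labels.astype(int), proba
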