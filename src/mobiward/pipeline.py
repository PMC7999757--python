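"""End-to-end orchestration: raw dual-site traces -> features -> labels.

``ActivityPipeline`` ties the stages together for one training fold:
balance -> standardize -> NCA selection -> ANN, and applies the same
standardization + selection at prediction time. ``build_dataset`` turns
labelled calibration sessions into the windowed 160-feature training
matrix; ``classify_stream`` runs a trained pipeline over a continuous ward
recording with non-overlapping windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import classifier as clf
from . import nca as nca_mod
from . import preprocessing as prep
from .config import PipelineConfig
from .features import FEATURE_NAMES, extract_many
from .types import CANONICAL_RATE_HZ, LabeledDataset, SensorTrace, ValidationError
from .ward import ActivityTimeline, TimelineEntry

log = logging.getLogger(__name__)


@dataclass
class CalibrationSession:
    """One subject's labelled recording of the six-activity protocol."""

    subject_id: str
    arm: SensorTrace
    leg: SensorTrace
    intervals: list


def preprocess_pair(
    arm: SensorTrace,
    leg: SensorTrace,
    config: PipelineConfig,
    overlap_fraction: float,
):
    """Resample both sites to 100 Hz, split total/dynamic, and window."""
    arm = prep.resample(arm, CANONICAL_RATE_HZ)
    leg = prep.resample(leg, CANONICAL_RATE_HZ)
    _, arm_dyn = prep.split_acceleration(arm, config.filter)
    _, leg_dyn = prep.split_acceleration(leg, config.filter)
    return prep.segment(
        arm,
        leg,
        window_samples=config.window.samples,
        overlap_fraction=overlap_fraction,
        arm_dynamic=arm_dyn,
        leg_dynamic=leg_dyn,
    )


def build_dataset(
    sessions: Sequence[CalibrationSession],
    config: Optional[PipelineConfig] = None,
    overlap_fraction: Optional[float] = None,
) -> LabeledDataset:
    """Windowed, labelled 160-feature dataset from calibration sessions.

    Training windows use 50% overlap by default; a window keeps a label only
    when a single interval fully covers it.
    """
    config = config or PipelineConfig()
    if overlap_fraction is None:
        overlap_fraction = config.window.overlap_train
    feats, labels, subjects = [], [], []
    for s in sessions:
        windows = preprocess_pair(s.arm, s.leg, config, overlap_fraction)
        labelled = prep.label_windows(windows, s.intervals, min_coverage=1.0)
        if not labelled:
            log.warning("session %s produced no labelled windows", s.subject_id)
            continue
        feats.append(extract_many(labelled, config.spectral))
        labels.extend(w.label.code for w in labelled)
        subjects.extend([s.subject_id] * len(labelled))
    if not feats:
        raise ValidationError("no labelled windows in any session")
    return LabeledDataset(
        features=np.vstack(feats),
        labels=np.asarray(labels),
        subject_ids=np.asarray(subjects, dtype=object),
        feature_names=FEATURE_NAMES,
    )


class ActivityPipeline:
    """Balance + standardize + select + classify, as one fit/predict unit."""

    def __init__(self, config: Optional[PipelineConfig] = None):
        self.config = config or PipelineConfig()
        self.nca_result: Optional[nca_mod.NcaResult] = None
        self.model: Optional[clf.AnnModel] = None
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None
        self.feature_mask: Optional[np.ndarray] = None

    def fit(
        self,
        dataset: LabeledDataset,
        seed: int = 0,
        fixed_selection: Optional[nca_mod.NcaResult] = None,
    ) -> "ActivityPipeline":
        """Fit on a raw (unbalanced, unstandardized) 160-feature dataset.

        ``fixed_selection`` bypasses the per-fit NCA with a precomputed
        selection (select-once mode for cross-validation comparisons).
        """
        cfg = self.config
        balanced = clf.balance_classes(
            dataset, seed=seed, static_dynamic_ratio=cfg.balance.static_dynamic_ratio
        )
        Xs, self.mean_, self.scale_ = nca_mod.standardize(balanced.features)
        std_ds = LabeledDataset(
            features=Xs,
            labels=balanced.labels,
            subject_ids=balanced.subject_ids,
            feature_names=list(balanced.feature_names),
        )
        if fixed_selection is not None:
            self.nca_result = fixed_selection
        else:
            self.nca_result = nca_mod.fit_nca(
                std_ds,
                lambda_reg=cfg.nca.lambda_reg,
                max_iterations=cfg.nca.max_iterations,
                seed=seed,
                threshold=cfg.nca.threshold,
                learning_rate=cfg.nca.learning_rate,
                decay=cfg.nca.decay,
                max_samples=cfg.nca.max_samples,
            )
        self.feature_mask = self.nca_result.selected_mask
        selected = std_ds.select_columns(self.feature_mask)
        self.model = clf.train(
            selected,
            hidden_nodes=cfg.ann.hidden_nodes,
            seed=seed,
            max_epochs=cfg.ann.max_epochs,
        )
        self.model.mean_ = self.mean_
        self.model.scale_ = self.scale_
        self.model.feature_mask = self.feature_mask
        return self

    def _check_fitted(self) -> None:
        if self.model is None:
            raise ValidationError("pipeline is not fitted")

    def predict(self, features: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Labels and probabilities for raw 160-feature rows."""
        self._check_fitted()
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.mean_.shape[0]:
            raise ValidationError(
                f"expected {self.mean_.shape[0]} raw features, got {features.shape[1]}"
            )
        Xs = (features - self.mean_) / self.scale_
        return clf.predict(self.model, Xs[:, self.feature_mask])

    def classify_stream(
        self,
        arm: Optional[SensorTrace],
        leg: Optional[SensorTrace],
        patient_id: str = "patient",
    ) -> ActivityTimeline:
        """Classify a continuous dual-site recording into a timeline.

        Non-overlapping windows (the postoperative convention). An empty
        window list yields an empty timeline with a warning.
        """
        self._check_fitted()
        if arm is None or leg is None:
            raise ValidationError(
                "classify_stream needs both sites; for single-sensor analyses "
                "use validation.sensor_ablation"
            )
        windows = preprocess_pair(arm, leg, self.config, self.config.window.overlap_classify)
        if not windows:
            log.warning("no complete windows in the common span; empty timeline")
            return ActivityTimeline(patient_id=patient_id, entries=[])
        feats = extract_many(windows, self.config.spectral)
        labels, proba = self.predict(feats)
        entries = [
            TimelineEntry(start_time=w.start_time, code=int(c), probability=float(p.max()))
            for w, c, p in zip(windows, labels, proba)
        ]
        return ActivityTimeline(patient_id=patient_id, entries=entries)
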