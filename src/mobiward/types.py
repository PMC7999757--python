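"""Core domain types for dual-site accelerometry and activity classification.

The activity taxonomy is fixed: six hospital-mobilization activities, three
static postures identified by segment orientation relative to gravity and
three dynamic, cyclical movements identified by their periodic acceleration
patterns. All acceleration values are expressed in units of g.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: code -> canonical activity name
ACTIVITY_NAMES = {
    1: "lying_in_bed",
    2: "sitting",
    3: "standing",
    4: "walking",
    5: "cycling",
    6: "walking_stairs",
}

STATIC_CODES = (1, 2, 3)
DYNAMIC_CODES = (4, 5, 6)
ALL_CODES = STATIC_CODES + DYNAMIC_CODES

SITES = ("arm", "leg")

#: canonical number of samples per classification window
WINDOW_SAMPLES = 256
#: canonical sampling rate, Hz (256 samples span 2.56 s)
CANONICAL_RATE_HZ = 100.0
#: seconds per classification window
WINDOW_SECONDS = WINDOW_SAMPLES / CANONICAL_RATE_HZ


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class ActivityLabel:
    """One of the six ward activities, identified by its integer code."""

    code: int

    def __post_init__(self) -> None:
        if self.code not in ACTIVITY_NAMES:
            raise ValidationError(f"unknown activity code {self.code!r}; valid codes are 1-6")

    @property
    def name(self) -> str:
        return ACTIVITY_NAMES[self.code]

    @property
    def category(self) -> str:
        return "static" if self.code in STATIC_CODES else "dynamic"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ActivityLabel({self.code}:{self.name})"


@dataclass
class SensorTrace:
    """A uniformly sampled tri-axial acceleration stream from one body site.

    Parameters
    ----------
    site
        ``"arm"`` or ``"leg"``.
    sample_rate_hz
        Sampling rate; must be at least 20 Hz so the spectral feature bands
        (top edge 25 Hz at the canonical 100 Hz rate) stay below Nyquist
        after resampling.
    start_time
        Wall-clock timestamp of the first sample. Local time-of-day matters:
        daily summaries are restricted to 7 a.m.-11 p.m.
    samples
        ``(n, 3)`` float array of (ax, ay, az) in g.
    """

    site: str
    sample_rate_hz: float
    start_time: pd.Timestamp
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(f"samples must be (n, 3), got shape {self.samples.shape}")
        if self.samples.shape[0] == 0:
            raise ValidationError("trace contains no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace contains non-finite acceleration values")
        if not self.sample_rate_hz > 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.sample_rate_hz < 20:
            raise ValidationError(
                f"sample_rate_hz {self.sample_rate_hz} < 20 Hz cannot support the feature bands"
            )
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate_hz

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)

    def times(self) -> pd.DatetimeIndex:
        """Per-sample timestamps."""
        offsets = np.arange(self.n_samples) / self.sample_rate_hz
        return self.start_time + pd.to_timedelta(offsets, unit="s")

    def rel_times(self) -> np.ndarray:
        """Seconds since ``start_time`` for every sample."""
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass(frozen=True)
class LabelInterval:
    """A half-open labelled time span ``[start_time, end_time)``."""

    start_time: pd.Timestamp
    end_time: pd.Timestamp
    label: ActivityLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))
        object.__setattr__(self, "end_time", pd.Timestamp(self.end_time))
        if self.end_time <= self.start_time:
            raise ValidationError(
                f"interval end {self.end_time} must be after start {self.start_time}"
            )

    @property
    def duration_s(self) -> float:
        return (self.end_time - self.start_time).total_seconds()


@dataclass
class WindowPair:
    """Time-aligned 256-sample arm and leg segments: the classification unit.

    ``arm_total``/``leg_total`` hold the raw (gravity + body) acceleration;
    ``arm_dynamic``/``leg_dynamic`` hold the high-pass filtered body
    acceleration, filled in by the preprocessing pipeline before feature
    extraction.
    """

    start_time: pd.Timestamp
    arm_total: np.ndarray
    leg_total: np.ndarray
    arm_dynamic: Optional[np.ndarray] = None
    leg_dynamic: Optional[np.ndarray] = None
    label: Optional[ActivityLabel] = None
    edge: bool = False  # overlaps the first/last second of the recording

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        for name in ("arm_total", "leg_total", "arm_dynamic", "leg_dynamic"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (WINDOW_SAMPLES, 3):
                raise ValidationError(
                    f"{name} must be ({WINDOW_SAMPLES}, 3), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @property
    def has_dynamic(self) -> bool:
        return self.arm_dynamic is not None and self.leg_dynamic is not None


@dataclass
class LabeledDataset:
    """A feature matrix with activity labels and subject identifiers."""

    features: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    feature_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.features.shape[0]
        if self.labels.shape[0] != n or self.subject_ids.shape[0] != n:
            raise ValidationError("features, labels and subject_ids must have equal length")
        if self.feature_names and len(self.feature_names) != self.features.shape[1]:
            raise ValidationError("feature_names length must match feature count")
        bad = set(np.unique(self.labels)) - set(ALL_CODES)
        if bad:
            raise ValidationError(f"labels contain unknown activity codes {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        """Row subset (boolean mask or integer index array)."""
        return LabeledDataset(
            features=self.features[index],
            labels=self.labels[index],
            subject_ids=self.subject_ids[index],
            feature_names=list(self.feature_names),
        )

    def select_columns(self, mask: np.ndarray) -> "LabeledDataset":
        """Column subset by boolean mask, names preserved."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != self.n_features:
            raise ValidationError("column mask length must match feature count")
        names = [n for n, keep in zip(self.feature_names, mask) if keep] if self.feature_names else []
        return LabeledDataset(
            features=self.features[:, mask],
            labels=self.labels,
            subject_ids=self.subject_ids,
            feature_names=names,
        )

    def class_counts(self) -> dict:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))
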