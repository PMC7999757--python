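"""Resampling, gravity/body-acceleration separation, and windowing.

The raw accelerometer signal is the sum of the gravitational component
(which encodes segment orientation and identifies static postures) and the
inertial "body" component (which carries the cyclical patterns of dynamic
movement). The two are separated with a high-pass filter at 0.8 Hz: the
unfiltered signal is kept as the *total* acceleration, the filtered one is
the *dynamic* acceleration. Streams are resampled to the canonical 100 Hz
grid so that one 256-sample window always spans 2.56 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from .types import (
    CANONICAL_RATE_HZ,
    WINDOW_SAMPLES,
    LabelInterval,
    SensorTrace,
    ValidationError,
    WindowPair,
)

log = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """High-pass filter used to isolate body (dynamic) acceleration.

    Only the 0.8 Hz cut-off is dictated by the problem (slow orientation
    changes below it are gravity, locomotor content above it is movement);
    the Butterworth family, 4th order and zero-phase application are this
    package's defaults, exposed for sensitivity checks. Zero-phase filtering
    avoids shifting the signal relative to its activity labels.
    """

    cutoff_hz: float = 0.8
    order: int = 4
    zero_phase: bool = True

    def validate(self, sample_rate_hz: float) -> None:
        if not 0 < self.cutoff_hz < sample_rate_hz / 2:
            raise ValidationError(
                f"cutoff {self.cutoff_hz} Hz must lie in (0, {sample_rate_hz / 2}) Hz"
            )
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")

    def sos(self, sample_rate_hz: float) -> np.ndarray:
        self.validate(sample_rate_hz)
        return sps.butter(self.order, self.cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")

    def response_magnitude(self, freq_hz: float, sample_rate_hz: float) -> float:
        """|H(f)| of the realized filter (squared when zero-phase)."""
        sos = self.sos(sample_rate_hz)
        _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=sample_rate_hz)
        mag = float(np.abs(h[0]))
        return mag ** 2 if self.zero_phase else mag


def resample(trace: SensorTrace, target_hz: float = CANONICAL_RATE_HZ) -> SensorTrace:
    """Resample to a uniform ``target_hz`` grid by linear interpolation.

    Duration is preserved to within one sample period. Upsampling by more
    than 4x is refused: it would fabricate bandwidth the sensor never
    recorded.
    """
    if target_hz <= 0:
        raise ValidationError("target_hz must be positive")
    if target_hz > 4 * trace.sample_rate_hz:
        raise ValidationError(
            f"refusing to upsample {trace.sample_rate_hz} Hz -> {target_hz} Hz (> 4x)"
        )
    if np.isclose(target_hz, trace.sample_rate_hz):
        return SensorTrace(
            site=trace.site,
            sample_rate_hz=float(target_hz),
            start_time=trace.start_time,
            samples=trace.samples.copy(),
        )
    t_old = trace.rel_times()
    n_new = int(np.floor(t_old[-1] * target_hz)) + 1
    t_new = np.arange(n_new) / target_hz
    out = np.column_stack([np.interp(t_new, t_old, trace.samples[:, j]) for j in range(3)])
    return SensorTrace(
        site=trace.site,
        sample_rate_hz=float(target_hz),
        start_time=trace.start_time,
        samples=out,
    )


def split_acceleration(
    trace: SensorTrace, spec: Optional[FilterSpec] = None
) -> Tuple[SensorTrace, SensorTrace]:
    """Separate total and dynamic (body) acceleration.

    Returns ``(total, dynamic)``: *total* is the input unchanged; *dynamic*
    is the per-axis high-pass output of the same length. Reflect padding is
    used at the edges (the zero-phase path delegates to
    ``scipy.signal.sosfiltfilt``'s odd-reflection padding).
    """
    spec = spec or FilterSpec()
    sos = spec.sos(trace.sample_rate_hz)
    transient = int(np.ceil(trace.sample_rate_hz / spec.cutoff_hz))
    if trace.n_samples < 3 * transient:
        raise ValidationError(
            f"trace of {trace.n_samples} samples is shorter than 3x the filter "
            f"transient ({transient} samples at {spec.cutoff_hz} Hz cutoff)"
        )
    if spec.zero_phase:
        dyn = sps.sosfiltfilt(sos, trace.samples, axis=0)
    else:
        padded = np.concatenate(
            [trace.samples[transient:0:-1], trace.samples, trace.samples[-2:-transient - 2:-1]]
        )
        dyn = sps.sosfilt(sos, padded, axis=0)[transient:transient + trace.n_samples]
    dynamic = SensorTrace(
        site=trace.site,
        sample_rate_hz=trace.sample_rate_hz,
        start_time=trace.start_time,
        samples=dyn,
    )
    return trace, dynamic


def window_count(n_samples: int, window_samples: int, overlap_fraction: float) -> int:
    """Number of full windows: floor((N - w)/step) + 1, step = round(w(1-overlap))."""
    if n_samples < window_samples:
        return 0
    step = int(round(window_samples * (1.0 - overlap_fraction)))
    if step < 1:
        raise ValidationError(f"overlap_fraction {overlap_fraction} leaves a step < 1 sample")
    return (n_samples - window_samples) // step + 1


def segment(
    arm: SensorTrace,
    leg: SensorTrace,
    window_samples: int = WINDOW_SAMPLES,
    overlap_fraction: float = 0.0,
    arm_dynamic: Optional[SensorTrace] = None,
    leg_dynamic: Optional[SensorTrace] = None,
    edge_seconds: float = 1.0,
) -> List[WindowPair]:
    """Cut time-aligned fixed-length windows from the two sites.

    Windows start at the latest common start time of the two traces;
    trailing partial windows are dropped. With 50% overlap consecutive
    windows share half their samples (training); with no overlap the windows
    tile the stream (postoperative classification). Windows overlapping the
    first or last ``edge_seconds`` of the common span are flagged ``edge``
    (filter transients), not dropped.
    """
    if not np.isclose(arm.sample_rate_hz, leg.sample_rate_hz):
        raise ValidationError("arm and leg traces must share one sample rate; resample first")
    if not 0 <= overlap_fraction < 1:
        raise ValidationError("overlap_fraction must be in [0, 1)")
    rate = arm.sample_rate_hz

    common_start = max(arm.start_time, leg.start_time)
    common_end = min(arm.end_time, leg.end_time)
    # traces share a uniform grid, so the span is an integer sample count up
    # to floating-point noise
    n_common = int(round((common_end - common_start).total_seconds() * rate)) + 1
    if n_common < window_samples:
        log.warning(
            "common span of %d samples is shorter than one %d-sample window; no windows emitted",
            max(n_common, 0), window_samples,
        )
        return []

    def offset(trace: SensorTrace) -> int:
        # nearest-sample alignment onto the common grid; sub-sample residual
        # below half a period (5 ms at 100 Hz) is ignored
        return int(round((common_start - trace.start_time).total_seconds() * rate))

    arm_o, leg_o = offset(arm), offset(leg)
    step = int(round(window_samples * (1.0 - overlap_fraction)))
    n_win = window_count(n_common, window_samples, overlap_fraction)
    edge_samples = int(round(edge_seconds * rate))

    pairs: List[WindowPair] = []
    for k in range(n_win):
        s = k * step
        sl = slice(s, s + window_samples)
        start_time = common_start + pd.Timedelta(seconds=s / rate)
        is_edge = s < edge_samples or (s + window_samples) > (n_common - edge_samples)
        pairs.append(
            WindowPair(
                start_time=start_time,
                arm_total=arm.samples[arm_o + s : arm_o + s + window_samples],
                leg_total=leg.samples[leg_o + s : leg_o + s + window_samples],
                arm_dynamic=None if arm_dynamic is None else arm_dynamic.samples[arm_o + s : arm_o + s + window_samples],
                leg_dynamic=None if leg_dynamic is None else leg_dynamic.samples[leg_o + s : leg_o + s + window_samples],
                edge=is_edge,
            )
        )
    return pairs


def label_windows(
    windows: Sequence[WindowPair],
    intervals: Sequence[LabelInterval],
    min_coverage: float = 1.0,
) -> List[WindowPair]:
    """Assign labels to windows covered by a single interval.

    A window receives a label iff one interval covers at least
    ``min_coverage`` of its span (default: full coverage, so windows
    straddling an activity transition are excluded — transition samples are
    the main source of labelling noise). Unlabellable windows are omitted
    from the output.
    """
    if not 0 < min_coverage <= 1:
        raise ValidationError("min_coverage must be in (0, 1]")
    out: List[WindowPair] = []
    for w in windows:
        w_start = w.start_time
        w_end = w.start_time + pd.Timedelta(seconds=WINDOW_SAMPLES / CANONICAL_RATE_HZ)
        span = (w_end - w_start).total_seconds()
        for iv in intervals:
            lo = max(w_start, iv.start_time)
            hi = min(w_end, iv.end_time)
            cov = max((hi - lo).total_seconds(), 0.0) / span
            if cov >= min_coverage:
                w.label = iv.label
                out.append(w)
                break
    return out
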