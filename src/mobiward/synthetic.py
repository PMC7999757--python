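"""Synthetic dual-site accelerometry and daily-summary cohorts.

No patient recordings are distributed with this package, so every pipeline
stage is exercised against a generator that emulates the study conditions:

* **Calibration sessions** — each subject performs the six activities for
  30 s each (protocol order: stand, sit, lie, walk, cycle, stairs) at
  100 Hz. Static postures are a site-specific gravity orientation plus
  sensor noise; dynamic activities add a cadence fundamental with two
  harmonics. Orientations are chosen so that the arm separates lying from
  sitting and the leg separates sitting from standing — the rationale for
  wearing two sensors — and the leg carries the dominant movement
  amplitude for all three dynamic activities.
* **Ward days** — a 07:00-anchored recording stitched from scheduled
  activity blocks with 2 s linear transitions; transition windows carry no
  ground-truth label.
* **Daily-summary cohorts** — patient-day activity minutes following the
  linear mixed recovery model (fixed effects: intercept, sex, day; random
  patient intercept; residual noise), for parameter-recovery studies.

Subject-level realism comes from seeded jitters: each subject gets a small
random sensor re-orientation per site, a personal cadence and a personal
movement amplitude. All generation is fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pipeline import CalibrationSession
from .types import (
    ACTIVITY_NAMES,
    ALL_CODES,
    CANONICAL_RATE_HZ,
    ActivityLabel,
    LabelInterval,
    SensorTrace,
    ValidationError,
)
from .ward import (
    DAY_START_HOUR,
    MAX_DAY_MINUTES,
    ActivityTimeline,
    DailySummary,
    TimelineEntry,
    WINDOW_MINUTES,
)

#: calibration protocol order: stand, sit, lie, walk, cycle, stairs
PROTOCOL_ORDER = (3, 2, 1, 4, 5, 6)


@dataclass(frozen=True)
class ActivityModel:
    """Signal model of one activity at both sensor sites.

    ``*_orientation`` is the gravity direction in the sensor frame (unit
    vector, g); ``*_amps`` are the amplitudes in g of the cadence
    fundamental and its first two harmonics. Static postures have zero
    cadence and zero amplitudes.
    """

    code: int
    arm_orientation: Tuple[float, float, float]
    leg_orientation: Tuple[float, float, float]
    cadence_hz: float = 0.0
    arm_amps: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    leg_amps: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("arm_orientation", "leg_orientation"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValidationError(f"{name} must be a unit vector")
        if self.cadence_hz == 0.0 and (any(self.arm_amps) or any(self.leg_amps)):
            raise ValidationError("static models must have zero harmonic amplitudes")

    @property
    def is_static(self) -> bool:
        return self.cadence_hz == 0.0


def default_models() -> Dict[int, ActivityModel]:
    """The six default activity models.

    Orientations (sensor frame: x anterior, y transverse, z longitudinal):
    standing puts gravity on both longitudinal axes; sitting flexes the leg
    to horizontal while the arm hangs vertical; lying puts both segments'
    transverse axes along gravity. Cadences: walking 1.8 Hz, stairs 1.4 Hz,
    cycling 1.2 Hz — field-plausible conventions, config-exposed. Stair
    climbing differs from level walking structurally, not just in tempo:
    a larger leg excursion with a pronounced vertical (second) harmonic and
    a near-quiet arm (hand on the railing), so the arm/leg amplitude ratio
    and the harmonic profile discriminate even for subjects whose personal
    cadences overlap.
    """
    return {
        1: ActivityModel(1, arm_orientation=(0, 1, 0), leg_orientation=(0, 1, 0)),
        2: ActivityModel(2, arm_orientation=(0, 0, 1), leg_orientation=(1, 0, 0)),
        3: ActivityModel(3, arm_orientation=(0, 0, 1), leg_orientation=(0, 0, 1)),
        4: ActivityModel(
            4,
            arm_orientation=(0, 0, 1),
            leg_orientation=(0, 0, 1),
            cadence_hz=1.8,
            arm_amps=(0.15, 0.06, 0.03),
            leg_amps=(0.40, 0.15, 0.08),
        ),
        5: ActivityModel(
            5,
            arm_orientation=(0, 0, 1),
            leg_orientation=(1, 0, 0),
            cadence_hz=1.2,
            arm_amps=(0.03, 0.01, 0.0),
            leg_amps=(0.35, 0.12, 0.05),
        ),
        6: ActivityModel(
            6,
            arm_orientation=(0, 0, 1),
            leg_orientation=(0, 0, 1),
            cadence_hz=1.4,
            arm_amps=(0.08, 0.04, 0.02),
            leg_amps=(0.50, 0.30, 0.10),
        ),
    }


@dataclass(frozen=True)
class SubjectJitter:
    """Inter-subject variation applied on top of the activity models."""

    orientation_deg: float = 8.0
    cadence_rel: float = 0.06
    amplitude_rel: float = 0.15


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _random_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    angle = np.deg2rad(rng.normal(0.0, sd_deg))
    return _rotation_matrix(axis, angle)


def _orthonormal_frame(g: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, g)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(g, ref)
    u /= np.linalg.norm(u)
    v = np.cross(g, u)
    return u, v


@dataclass
class _SubjectDraw:
    """One subject's seeded deviations from the nominal models."""

    arm_rot: np.ndarray
    leg_rot: np.ndarray
    cadence_factor: float
    amp_factor: float

    @staticmethod
    def sample(rng: np.random.Generator, jitter: SubjectJitter) -> "_SubjectDraw":
        return _SubjectDraw(
            arm_rot=_random_rotation(rng, jitter.orientation_deg),
            leg_rot=_random_rotation(rng, jitter.orientation_deg),
            cadence_factor=max(1.0 + rng.normal(0.0, jitter.cadence_rel), 0.5),
            amp_factor=max(1.0 + rng.normal(0.0, jitter.amplitude_rel), 0.2),
        )


def _site_signal(
    t: np.ndarray,
    orientation: np.ndarray,
    rot: np.ndarray,
    cadence_hz: float,
    amps: Sequence[float],
    phases: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gravity + harmonics + white noise for one site, (n, 3) in g."""
    g = rot @ np.asarray(orientation, dtype=float)
    sig = np.tile(g, (t.size, 1))
    if cadence_hz > 0:
        u, v = _orthonormal_frame(g)
        dirs = (u, g, v)  # fundamental in the movement plane, 2nd harmonic vertical
        for h, (amp, d) in enumerate(zip(amps, dirs)):
            if amp:
                sig += amp * np.sin(2 * np.pi * cadence_hz * (h + 1) * t + phases[h])[:, None] * d
    sig += rng.normal(0.0, noise_sd, size=sig.shape)
    return sig


def generate_calibration_session(
    subject_id: str,
    models: Optional[Dict[int, ActivityModel]] = None,
    duration_s: float = 30.0,
    rate_hz: float = CANONICAL_RATE_HZ,
    seed: int = 0,
    start_time="2020-06-15 09:00:00",
    jitter: Optional[SubjectJitter] = None,
) -> CalibrationSession:
    """One subject's labelled six-activity protocol recording.

    Each activity lasts ``duration_s`` (30 s in the protocol); blocks are
    concatenated in protocol order with aligned label intervals.
    """
    models = models or default_models()
    if set(models) != set(ALL_CODES):
        raise ValidationError("models must cover all six activities")
    jitter = jitter or SubjectJitter()
    rng = np.random.default_rng(seed)
    draw = _SubjectDraw.sample(rng, jitter)
    start_time = pd.Timestamp(start_time)

    n_block = int(round(duration_s * rate_hz))
    arm_parts, leg_parts, intervals = [], [], []
    t0 = 0.0
    for code in PROTOCOL_ORDER:
        m = models[code]
        t = t0 + np.arange(n_block) / rate_hz
        cadence = m.cadence_hz * draw.cadence_factor
        phases = rng.uniform(0, 2 * np.pi, size=3)
        arm_parts.append(
            _site_signal(
                t, m.arm_orientation, draw.arm_rot, cadence,
                np.asarray(m.arm_amps) * draw.amp_factor, phases, m.noise_sd, rng,
            )
        )
        leg_parts.append(
            _site_signal(
                t, m.leg_orientation, draw.leg_rot, cadence,
                np.asarray(m.leg_amps) * draw.amp_factor, phases, m.noise_sd, rng,
            )
        )
        intervals.append(
            LabelInterval(
                start_time=start_time + pd.Timedelta(seconds=t0),
                end_time=start_time + pd.Timedelta(seconds=t0 + duration_s),
                label=ActivityLabel(code),
            )
        )
        t0 += duration_s

    arm = SensorTrace("arm", rate_hz, start_time, np.vstack(arm_parts))
    leg = SensorTrace("leg", rate_hz, start_time, np.vstack(leg_parts))
    return CalibrationSession(subject_id=subject_id, arm=arm, leg=leg, intervals=intervals)


def generate_cohort_sessions(
    n_subjects: int = 31,
    seed: int = 0,
    models: Optional[Dict[int, ActivityModel]] = None,
    duration_s: float = 30.0,
    jitter: Optional[SubjectJitter] = None,
) -> List[CalibrationSession]:
    """Independent calibration sessions for a labelling cohort (default 31)."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        generate_calibration_session(
            subject_id=f"S{i + 1:02d}",
            models=models,
            duration_s=duration_s,
            seed=int(child.generate_state(1)[0] % (2**31)),
            jitter=jitter,
        )
        for i, child in enumerate(children)
    ]


#: default physical-therapy-informed ward-day schedules (code, minutes)
DAY_SCHEDULES: Dict[int, List[Tuple[int, float]]] = {
    1: [(1, 660), (2, 260), (3, 30), (4, 10)],
    2: [(1, 600), (2, 300), (3, 35), (4, 25)],
    3: [(1, 500), (2, 370), (3, 50), (4, 30), (5, 10)],
    4: [(1, 420), (2, 420), (3, 60), (4, 40), (5, 10), (6, 10)],
}

TRANSITION_SECONDS = 2.0


def generate_ward_day(
    patient_id: str,
    date,
    schedule: Sequence[Tuple[int, float]],
    models: Optional[Dict[int, ActivityModel]] = None,
    seed: int = 0,
    rate_hz: float = CANONICAL_RATE_HZ,
    jitter: Optional[SubjectJitter] = None,
) -> Tuple[SensorTrace, SensorTrace, ActivityTimeline]:
    """A ward-day recording stitched from scheduled activity blocks.

    The recording starts at 07:00 on ``date`` and covers the scheduled
    blocks back to back with ``TRANSITION_SECONDS`` linear cross-fades at
    each boundary. The returned ground-truth timeline contains one entry
    per non-overlapping 2.56 s window that lies fully inside a block's
    steady region; transition windows are unlabelled (omitted).
    """
    models = models or default_models()
    total_min = sum(m for _, m in schedule)
    if total_min > MAX_DAY_MINUTES:
        raise ValidationError(f"schedule of {total_min} min exceeds the {MAX_DAY_MINUTES}-min day")
    if not schedule:
        raise ValidationError("empty schedule")
    rng = np.random.default_rng(seed)
    jitter = jitter or SubjectJitter()
    draw = _SubjectDraw.sample(rng, jitter)
    start = pd.Timestamp(date).normalize() + pd.Timedelta(hours=DAY_START_HOUR)

    n_trans = int(round(TRANSITION_SECONDS * rate_hz))
    arm_parts, leg_parts = [], []
    boundaries = []  # (block_start_s, block_end_s, code)
    t0 = 0.0
    for code, minutes in schedule:
        m = models[code]
        n_block = int(round(minutes * 60 * rate_hz))
        # generate with a transition tail used to fade into the next block
        t = t0 + np.arange(n_block + n_trans) / rate_hz
        cadence = m.cadence_hz * draw.cadence_factor
        phases = rng.uniform(0, 2 * np.pi, size=3)
        a = _site_signal(t, m.arm_orientation, draw.arm_rot, cadence,
                         np.asarray(m.arm_amps) * draw.amp_factor, phases, m.noise_sd, rng)
        l = _site_signal(t, m.leg_orientation, draw.leg_rot, cadence,
                         np.asarray(m.leg_amps) * draw.amp_factor, phases, m.noise_sd, rng)
        arm_parts.append((a, n_block))
        leg_parts.append((l, n_block))
        boundaries.append((t0, t0 + minutes * 60, code))
        t0 += minutes * 60

    def stitch(parts) -> np.ndarray:
        out = [parts[0][0][: parts[0][1]]]
        for k in range(1, len(parts)):
            prev_tail = parts[k - 1][0][parts[k - 1][1] : parts[k - 1][1] + n_trans]
            cur, n_block = parts[k]
            ramp = np.linspace(0.0, 1.0, n_trans)[:, None]
            head = (1 - ramp) * prev_tail + ramp * cur[:n_trans]
            out.append(np.vstack([head, cur[n_trans:n_block]]))
        return np.vstack(out)

    arm = SensorTrace("arm", rate_hz, start, stitch(arm_parts))
    leg = SensorTrace("leg", rate_hz, start, stitch(leg_parts))

    # ground truth: windows fully inside a block's steady region
    win_s = WINDOW_MINUTES * 60
    entries = []
    n_windows = int(arm.n_samples // (win_s * rate_hz))
    for w in range(n_windows):
        ws, we = w * win_s, (w + 1) * win_s
        for i, (bs, be, code) in enumerate(boundaries):
            steady_start = bs + (TRANSITION_SECONDS if i > 0 else 0.0)
            if ws >= steady_start and we <= be:
                entries.append(
                    TimelineEntry(start_time=start + pd.Timedelta(seconds=ws), code=code)
                )
                break
    return arm, leg, ActivityTimeline(patient_id=patient_id, entries=entries)


# ---------------------------------------------------------------------------
# daily-summary cohorts (the mixed-model data-generating process)
# ---------------------------------------------------------------------------

#: stay-length distribution over ward nights: median 5, IQR 3-6
DEFAULT_STAY_PMF: Dict[int, float] = {
    1: 0.03, 2: 0.10, 3: 0.15, 4: 0.17, 5: 0.20, 6: 0.20, 7: 0.10, 8: 0.05,
}

#: per-activity minute-scale fixed effects (beta0, beta1 male, beta2 per day)
#: and variance components used by the cohort generator. Sitting has no entry:
#: it absorbs the complement of the 960-min day.
DEFAULT_FIXED_EFFECTS: Dict[int, Tuple[float, float, float]] = {
    1: (413.0, 11.0, -41.0),  # lying in bed
    3: (14.0, -2.0, 5.7),     # standing
    4: (0.0, 1.1, 2.0),       # walking
    5: (1.4, 4.2, 1.4),       # cycling
    6: (0.4, 0.6, 0.7),       # walking stairs
}
DEFAULT_SD_INTERCEPT: Dict[int, float] = {1: 70.0, 3: 12.0, 4: 4.0, 5: 4.0, 6: 1.5}
DEFAULT_SD_RESIDUAL: Dict[int, float] = {1: 70.0, 3: 12.0, 4: 4.0, 5: 4.0, 6: 1.5}


@dataclass
class CohortSpec:
    """Cohort structure and data-generating parameters for daily summaries."""

    n_patients: int = 29
    n_male: int = 22
    stay_pmf: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_STAY_PMF))
    max_observed_days: int = 7
    fixed_effects: Dict[int, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS)
    )
    sd_intercept: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SD_INTERCEPT))
    sd_residual: Dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SD_RESIDUAL))
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_male <= self.n_patients:
            raise ValidationError("n_male must be between 0 and n_patients")
        probs = np.array(list(self.stay_pmf.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("stay_pmf must be a probability distribution")
        if any(k < 1 for k in self.stay_pmf):
            raise ValidationError("stay lengths must be >= 1 night")


def generate_daily_summaries(spec: Optional[CohortSpec] = None) -> List[DailySummary]:
    """Simulate patient-day summaries from the mixed recovery model.

    Each modelled activity follows
    ``Y_ij = beta0 + beta1*male_i + beta2*(day_j - 1) + b_i + eps_ij``
    truncated below at 0; sitting takes the remainder of the complete
    960-min day so that conservation holds exactly. Deterministic per
    ``spec.seed``.
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    stays = np.array(list(spec.stay_pmf), dtype=int)
    probs = np.array([spec.stay_pmf[k] for k in stays], dtype=float)

    summaries: List[DailySummary] = []
    for i in range(spec.n_patients):
        sex = "male" if i < spec.n_male else "female"
        male = 1.0 if sex == "male" else 0.0
        n_days = int(min(rng.choice(stays, p=probs), spec.max_observed_days))
        b = {c: rng.normal(0.0, spec.sd_intercept[c]) for c in spec.fixed_effects}
        for day in range(1, n_days + 1):
            minutes = {}
            for c, (b0, b1, b2) in spec.fixed_effects.items():
                y = b0 + b1 * male + b2 * (day - 1) + b[c] + rng.normal(0.0, spec.sd_residual[c])
                minutes[c] = max(y, 0.0)
            used = sum(minutes.values())
            if used > MAX_DAY_MINUTES:
                scale = MAX_DAY_MINUTES / used
                minutes = {c: v * scale for c, v in minutes.items()}
                used = MAX_DAY_MINUTES
            minutes[2] = MAX_DAY_MINUTES - used  # sitting absorbs the remainder
            percentages = {c: 100.0 * minutes[c] / MAX_DAY_MINUTES for c in ALL_CODES}
            summaries.append(
                DailySummary(
                    patient_id=f"P{i + 1:02d}",
                    sex=sex,
                    day_index=day,
                    minutes={c: minutes[c] for c in ALL_CODES},
                    percentages=percentages,
                    observed_minutes=float(MAX_DAY_MINUTES),
                )
            )
    return summaries


def recovery_simulation(
    n_replicates: int = 200,
    spec: Optional[CohortSpec] = None,
    activity: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery study for the mixed-model slope.

    Generates ``n_replicates`` cohorts, refits the random-intercept ML
    model to the given activity's daily minutes, and reports the slope
    estimate, its Wald 95% CI and whether the CI covers the generating
    slope.
    """
    from .ward import fit_activity_trend  # local import to avoid cycle at module load

    spec = spec or CohortSpec()
    true_slope = spec.fixed_effects[activity][2]
    rows = []
    for r in range(n_replicates):
        rep_spec = replace(spec, seed=int((seed + 1) * 100003 + r) % (2**31))
        fit = fit_activity_trend(generate_daily_summaries(rep_spec), activity, "minutes")
        lo, hi = fit.ci["time"]
        rows.append(
            {
                "replicate": r,
                "slope_hat": fit.beta2,
                "ci_low": lo,
                "ci_high": hi,
                "covered": bool(lo <= true_slope <= hi),
                "converged": fit.converged,
                "n_obs": fit.n_obs,
            }
        )
    return pd.DataFrame(rows)
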