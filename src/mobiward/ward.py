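"""Daily ward summaries and the mixed-effects recovery model.

The clinical endpoint is the daily duration of each activity between
7 a.m. and 11 p.m. (at most 960 min). Each classified, non-overlapping
2.56 s window contributes 2.56/60 min to its activity. Day-to-day recovery
and the sex contrast are modelled per activity (on the minutes and the
percentage scale) with the linear mixed model

    Y_ij = beta0 + beta1 * male_i + beta2 * (day_ij - 1) + b_i + eps_ij,

where b_i ~ N(0, sigma_b^2) is a patient-level random intercept and the
model is fitted by maximum likelihood. beta0 is the expected Day-1 value
for a female patient, beta1 the male-female contrast and beta2 the per-day
slope (the recovery signal: e.g. minutes of lying in bed lost per
consecutive hospital day).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import (
    ACTIVITY_NAMES,
    ALL_CODES,
    CANONICAL_RATE_HZ,
    WINDOW_SAMPLES,
    ValidationError,
)

log = logging.getLogger(__name__)

WINDOW_MINUTES = WINDOW_SAMPLES / CANONICAL_RATE_HZ / 60.0  # 2.56 s in minutes
DAY_START_HOUR = 7
DAY_END_HOUR = 23
MAX_DAY_MINUTES = (DAY_END_HOUR - DAY_START_HOUR) * 60  # 960

SEXES = ("male", "female")

_NAME_TO_CODE = {v: k for k, v in ACTIVITY_NAMES.items()}


@dataclass(frozen=True)
class TimelineEntry:
    start_time: pd.Timestamp
    code: int
    probability: float = 1.0


@dataclass
class ActivityTimeline:
    """Per-window activity labels over a recording, non-overlapping windows."""

    patient_id: str
    entries: List[TimelineEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.start_time for e in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("timeline entries must be time-sorted")
        spacing = [(b - a).total_seconds() for a, b in zip(times, times[1:])]
        # small slack for nanosecond-rounded timestamps
        min_span = WINDOW_SAMPLES / CANONICAL_RATE_HZ - 1e-3
        if any(s < min_span for s in spacing):
            raise ValidationError("timeline windows overlap; classify with overlap 0")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class DailySummary:
    """Minutes and percentage per activity for one patient-day (7 a.m.-11 p.m.)."""

    patient_id: str
    sex: str
    day_index: int
    minutes: Dict[int, float]
    percentages: Optional[Dict[int, float]]
    observed_minutes: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.day_index < 1:
            raise ValidationError("day_index starts at 1 (first ward day)")
        if set(self.minutes) != set(ALL_CODES):
            raise ValidationError("minutes must cover all six activity codes")
        if any(v < -1e-9 for v in self.minutes.values()):
            raise ValidationError("negative activity minutes")
        if self.observed_minutes > MAX_DAY_MINUTES + 1e-6:
            raise ValidationError(f"observed_minutes exceeds {MAX_DAY_MINUTES}")
        # tolerance matches the declared CSV precision (1e-6 per value)
        total = sum(self.minutes.values())
        if abs(total - self.observed_minutes) > 1e-4:
            raise ValidationError(
                f"activity minutes sum to {total}, expected observed_minutes {self.observed_minutes}"
            )
        if self.observed_minutes > 0:
            if self.percentages is None or abs(sum(self.percentages.values()) - 100.0) > 1e-4:
                raise ValidationError("percentages must sum to 100 when the day has observations")


def summarize_day(
    timeline: ActivityTimeline,
    date,
    day_index: int,
    sex: str,
) -> DailySummary:
    """Aggregate one classified day into per-activity minutes and percentages.

    A window counts toward the day iff its *start* lies in [07:00, 23:00)
    local time on ``date``. Days with no windows in that span yield
    ``observed_minutes`` 0 and absent percentages (e.g. ICU discharge after
    11 p.m.).
    """
    date = pd.Timestamp(date).normalize()
    lo = date + pd.Timedelta(hours=DAY_START_HOUR)
    hi = date + pd.Timedelta(hours=DAY_END_HOUR)
    counts = {c: 0 for c in ALL_CODES}
    for e in timeline.entries:
        if lo <= e.start_time < hi:
            counts[e.code] += 1
    minutes = {c: counts[c] * WINDOW_MINUTES for c in ALL_CODES}
    observed = sum(minutes.values())
    percentages = (
        {c: 100.0 * minutes[c] / observed for c in ALL_CODES} if observed > 0 else None
    )
    return DailySummary(
        patient_id=timeline.patient_id,
        sex=sex,
        day_index=day_index,
        minutes=minutes,
        percentages=percentages,
        observed_minutes=observed,
    )


@dataclass
class MixedModelFit:
    """ML estimates of the recovery model for one response."""

    response: str
    beta0: float  # intercept: female Day-1 mean
    beta1: float  # male minus female
    beta2: float  # per-day slope
    ci: Dict[str, Tuple[float, float]]
    p_sex: float
    p_time: float
    var_random_intercept: float
    var_residual: float
    n_obs: int
    n_patients: int
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        for name, est in (("intercept", self.beta0), ("sex", self.beta1), ("time", self.beta2)):
            lo, hi = self.ci.get(name, (-np.inf, np.inf))
            if self.converged and not (lo <= est <= hi):
                raise ValidationError(f"CI for {name} does not bracket the estimate")


def summaries_to_frame(summaries: Sequence[DailySummary]) -> pd.DataFrame:
    """Long-format patient-day table used by the mixed-model fits."""
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "sex": s.sex,
            "male": 1.0 if s.sex == "male" else 0.0,
            "day_index": s.day_index,
            "time": float(s.day_index - 1),  # Day 1 -> 0, so beta0 is the Day-1 mean
            "observed_minutes": s.observed_minutes,
        }
        for c in ALL_CODES:
            row[f"min_{ACTIVITY_NAMES[c]}"] = s.minutes[c]
            row[f"pct_{ACTIVITY_NAMES[c]}"] = (
                s.percentages[c] if s.percentages is not None else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _resolve_response(activity, scale: str) -> str:
    if scale not in ("minutes", "percentage"):
        raise ValidationError("scale must be 'minutes' or 'percentage'")
    if isinstance(activity, int):
        name = ACTIVITY_NAMES.get(activity)
        if name is None:
            raise ValidationError(f"unknown activity code {activity}")
    else:
        name = activity
        if name not in _NAME_TO_CODE:
            raise ValidationError(f"unknown activity name {activity!r}")
    return ("min_" if scale == "minutes" else "pct_") + name


def fit_activity_trend(
    summaries: Sequence[DailySummary],
    activity,
    scale: str = "minutes",
    covariates: Sequence[str] = (),
) -> MixedModelFit:
    """Fit the random-intercept recovery model for one activity response.

    Maximum-likelihood fit (not REML) with Wald 95% CIs and p-values.
    ``covariates`` may name extra patient-day columns of the summary frame
    to enter as additional fixed effects (e.g. anthropometrics).
    Non-convergence is flagged on the result, not raised.
    """
    df = summaries_to_frame(summaries)
    col = _resolve_response(activity, scale)
    df = df.dropna(subset=[col])
    n_patients = df["patient_id"].nunique()
    if n_patients < 2:
        raise ValidationError("the random intercept needs >= 2 patients")
    if df.groupby("patient_id")["day_index"].nunique().max() < 2:
        raise ValidationError("at least one patient must contribute >= 2 days")

    fixed = ["male", "time", *covariates]
    exog = sm.add_constant(df[fixed], has_constant="add")
    converged, message = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(df[col], exog, groups=df["patient_id"])
            fit = model.fit(reml=False)
            converged = bool(getattr(fit, "converged", True))
        except Exception as exc:  # singular fits and the like
            converged, message = False, str(exc)
            fit = None

    if fit is None:
        nan_ci = {k: (np.nan, np.nan) for k in ("intercept", "sex", "time")}
        return MixedModelFit(
            response=col, beta0=np.nan, beta1=np.nan, beta2=np.nan, ci=nan_ci,
            p_sex=np.nan, p_time=np.nan, var_random_intercept=np.nan,
            var_residual=np.nan, n_obs=len(df), n_patients=n_patients,
            converged=False, message=message,
        )

    params = fit.params
    conf = fit.conf_int(alpha=0.05)
    ci = {
        "intercept": (float(conf.loc["const", 0]), float(conf.loc["const", 1])),
        "sex": (float(conf.loc["male", 0]), float(conf.loc["male", 1])),
        "time": (float(conf.loc["time", 0]), float(conf.loc["time", 1])),
    }
    return MixedModelFit(
        response=col,
        beta0=float(params["const"]),
        beta1=float(params["male"]),
        beta2=float(params["time"]),
        ci=ci,
        p_sex=float(fit.pvalues["male"]),
        p_time=float(fit.pvalues["time"]),
        var_random_intercept=float(np.asarray(fit.cov_re).ravel()[0]),
        var_residual=float(fit.scale),
        n_obs=int(len(df)),
        n_patients=int(n_patients),
        converged=converged,
        message=message,
    )


def trend_report(summaries: Sequence[DailySummary]) -> pd.DataFrame:
    """Fixed-effects table over all 12 responses (6 activities x 2 scales)."""
    rows = []
    for code in ALL_CODES:
        for scale in ("minutes", "percentage"):
            f = fit_activity_trend(summaries, code, scale)
            rows.append(
                {
                    "activity": ACTIVITY_NAMES[code],
                    "scale": scale,
                    "intercept": f.beta0,
                    "intercept_ci_low": f.ci["intercept"][0],
                    "intercept_ci_high": f.ci["intercept"][1],
                    "slope_per_day": f.beta2,
                    "slope_ci_low": f.ci["time"][0],
                    "slope_ci_high": f.ci["time"][1],
                    "p_time": f.p_time,
                    "male_contrast": f.beta1,
                    "sex_ci_low": f.ci["sex"][0],
                    "sex_ci_high": f.ci["sex"][1],
                    "p_sex": f.p_sex,
                    "n_obs": f.n_obs,
                    "n_patients": f.n_patients,
                    "converged": f.converged,
                }
            )
    return pd.DataFrame(rows)
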