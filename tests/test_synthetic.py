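"""The synthetic-data generators: structure, determinism, separability."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from mobiward import (
    ValidationError,
    build_dataset,
    generate_calibration_session,
    generate_cohort_sessions,
    generate_daily_summaries,
    generate_ward_day,
)
from mobiward.preprocessing import split_acceleration
from mobiward.synthetic import (
    DAY_SCHEDULES,
    PROTOCOL_ORDER,
    CohortSpec,
    SubjectJitter,
    default_models,
)
from mobiward.types import STATIC_CODES


class TestCalibrationSession:
    def test_structure(self):
        session = generate_calibration_session("S01", seed=0)
        assert session.arm.n_samples == 6 * 3000
        assert session.leg.n_samples == 6 * 3000
        assert len(session.intervals) == 6
        assert [iv.label.code for iv in session.intervals] == list(PROTOCOL_ORDER)
        total = sum(iv.duration_s for iv in session.intervals)
        assert total == pytest.approx(180.0)

    def test_lying_magnitude_near_one_g(self):
        """A static posture is gravity plus noise: mean |a| within 0.05 g of 1."""
        session = generate_calibration_session("S01", seed=1)
        lying = next(iv for iv in session.intervals if iv.label.code == 1)
        i0 = int((lying.start_time - session.arm.start_time).total_seconds() * 100)
        seg = session.arm.samples[i0 : i0 + 3000]
        assert np.mean(np.linalg.norm(seg, axis=1)) == pytest.approx(1.0, abs=0.05)

    def test_walking_leg_peak_at_cadence(self):
        """With jitter disabled the leg spectrum peaks at the 1.8 Hz cadence."""
        session = generate_calibration_session(
            "S01", seed=2, jitter=SubjectJitter(0.0, 0.0, 0.0)
        )
        walking = next(iv for iv in session.intervals if iv.label.code == 4)
        i0 = int((walking.start_time - session.leg.start_time).total_seconds() * 100)
        seg = session.leg.samples[i0 : i0 + 3000]
        # dominant non-DC frequency across axes
        f, p = sps.periodogram(seg - seg.mean(axis=0), fs=100.0, axis=0)
        peak_hz = f[np.argmax(p.sum(axis=1))]
        assert peak_hz == pytest.approx(1.8, abs=100 / 3000)

    def test_determinism(self):
        s1 = generate_calibration_session("S01", seed=7)
        s2 = generate_calibration_session("S01", seed=7)
        np.testing.assert_array_equal(s1.arm.samples, s2.arm.samples)
        np.testing.assert_array_equal(s1.leg.samples, s2.leg.samples)

    def test_static_dynamic_rms_separation(self):
        """Static blocks stay below 0.05 g dynamic RMS; dynamic above 0.1 g."""
        session = generate_calibration_session("S01", seed=3)
        _, dyn = split_acceleration(session.leg)
        for iv in session.intervals:
            i0 = int((iv.start_time - session.leg.start_time).total_seconds() * 100)
            core = dyn.samples[i0 + 200 : i0 + 2800]  # away from block edges
            rms = np.sqrt(np.mean(np.sum(core**2, axis=1)))
            if iv.label.code in STATIC_CODES:
                assert rms < 0.05, iv.label.name
            else:
                assert rms > 0.1, iv.label.name


class TestCohortSessions:
    def test_default_cohort_structure(self, corpus31):
        assert len(corpus31) == 31
        assert sum(len(s.intervals) for s in corpus31) == 186
        assert len({s.subject_id for s in corpus31}) == 31

    def test_windows_per_subject_activity(self, dataset31):
        """Every subject contributes >= 20 windows per activity at 50% overlap."""
        df = pd.DataFrame({"sid": dataset31.subject_ids, "y": dataset31.labels})
        counts = df.groupby(["sid", "y"]).size()
        assert counts.min() >= 20

    def test_determinism(self):
        a = generate_cohort_sessions(n_subjects=3, seed=11)
        b = generate_cohort_sessions(n_subjects=3, seed=11)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.arm.samples, s2.arm.samples)


class TestWardDay:
    def test_all_lying_day(self):
        arm, leg, truth = generate_ward_day("P01", "2020-06-20", [(1, 4.0)], seed=0)
        assert arm.start_time == pd.Timestamp("2020-06-20 07:00:00")
        assert len(truth) > 0
        assert all(e.code == 1 for e in truth.entries)

    def test_day4_less_lying_than_day1(self):
        lying1 = sum(m for c, m in DAY_SCHEDULES[1] if c == 1)
        lying4 = sum(m for c, m in DAY_SCHEDULES[4] if c == 1)
        assert lying4 < lying1

    def test_overlong_schedule_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            generate_ward_day("P01", "2020-06-20", [(1, 600), (2, 600)], seed=0)

    def test_transition_windows_unlabelled(self):
        """Windows straddling a block boundary are absent from ground truth."""
        arm, leg, truth = generate_ward_day(
            "P01", "2020-06-20", [(1, 2.0), (4, 2.0)], seed=1
        )
        n_windows = arm.n_samples // 256
        assert len(truth) < n_windows
        labelled_starts = {e.start_time for e in truth.entries}
        boundary = arm.start_time + pd.Timedelta(seconds=120)
        straddlers = [
            arm.start_time + pd.Timedelta(seconds=2.56 * k)
            for k in range(n_windows)
            if (t := 2.56 * k) < 122 and t + 2.56 > 120
        ]
        assert not (labelled_starts & set(straddlers))

    def test_closed_loop_classification(self, trained_pipeline):
        """A matched model recovers >= 90% of ground-truth windows on a day."""
        arm, leg, truth = generate_ward_day(
            "P01", "2020-06-20",
            [(1, 2.0), (2, 2.0), (4, 2.0), (3, 1.0), (5, 2.0), (6, 2.0)],
            seed=21,
        )
        timeline = trained_pipeline.classify_stream(arm, leg, patient_id="P01")
        predicted = {e.start_time: e.code for e in timeline.entries}
        hits = [predicted.get(e.start_time) == e.code for e in truth.entries]
        assert np.mean(hits) >= 0.90


class TestDailySummaries:
    def test_zero_variance_exact(self):
        spec = CohortSpec(seed=0)
        spec.sd_intercept = {k: 0.0 for k in spec.sd_intercept}
        spec.sd_residual = {k: 0.0 for k in spec.sd_residual}
        summaries = generate_daily_summaries(spec)
        day1_female = next(
            s for s in summaries if s.sex == "female" and s.day_index == 1
        )
        assert day1_female.minutes[1] == pytest.approx(413.0)
        day2_male = next(s for s in summaries if s.sex == "male" and s.day_index == 2)
        assert day2_male.minutes[1] == pytest.approx(413.0 + 11.0 - 41.0)

    def test_n_obs_is_total_stay(self):
        spec = CohortSpec(seed=1)
        summaries = generate_daily_summaries(spec)
        per_patient = {}
        for s in summaries:
            per_patient.setdefault(s.patient_id, []).append(s.day_index)
        assert len(per_patient) == 29
        for days in per_patient.values():
            assert days == list(range(1, len(days) + 1))
        assert len(summaries) == sum(len(d) for d in per_patient.values())

    def test_sex_split(self):
        summaries = generate_daily_summaries(CohortSpec(seed=2))
        sexes = {s.patient_id: s.sex for s in summaries}
        assert sum(v == "male" for v in sexes.values()) == 22
        assert sum(v == "female" for v in sexes.values()) == 7

    def test_determinism(self):
        a = generate_daily_summaries(CohortSpec(seed=5))
        b = generate_daily_summaries(CohortSpec(seed=5))
        assert [s.minutes for s in a] == [s.minutes for s in b]

    def test_invalid_spec_rejected(self):
        spec = CohortSpec(n_male=40)
        with pytest.raises(ValidationError):
            generate_daily_summaries(spec)
        spec = CohortSpec(stay_pmf={1: 0.5, 2: 0.4})
        with pytest.raises(ValidationError):
            generate_daily_summaries(spec)

    def test_conservation_and_bounds(self):
        for s in generate_daily_summaries(CohortSpec(seed=8)):
            assert sum(s.minutes.values()) == pytest.approx(s.observed_minutes)
            assert all(v >= 0 for v in s.minutes.values())
            assert sum(s.percentages.values()) == pytest.approx(100.0)
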