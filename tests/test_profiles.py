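"""CGM extrapolation schemes and parametric scenario profiles."""

import numpy as np
import pandas as pd
import pytest

from glycosim import (
    CgmDay,
    CgmSessionSet,
    GlucoseProfile,
    ScenarioSpec,
    id_extrapolate,
    profile_stats,
    read_cgm_csv,
    scenario_profile,
    ww_extrapolate,
)
from glycosim.profiles import averaged_daily_profiles


def _day(date, day_type, values):
    return CgmDay(pd.Timestamp(date), day_type, np.asarray(values, dtype=float))


def _constant_sessions(work_level=8.0, weekend_level=6.0, n_points=12):
    return CgmSessionSet(
        (
            _day("2014-03-03", "workday", [work_level] * n_points),
            _day("2014-03-04", "workday", [work_level] * n_points),
            _day("2014-03-08", "weekend", [weekend_level] * n_points),
        )
    )


class TestWwExtrapolate:
    def test_identical_constant_days_give_constant_profile(self):
        sessions = _constant_sessions(7.0, 7.0)
        profile = ww_extrapolate(sessions, 120)
        assert profile.bg.size == 120
        np.testing.assert_allclose(profile.bg, 7.0)

    def test_weekly_weighted_mean(self):
        profile = ww_extrapolate(_constant_sessions(8.0, 6.0), 7 * 17)
        assert profile.mbg == pytest.approx((5 * 8 + 2 * 6) / 7)

    def test_pointwise_averaging_of_workdays(self):
        sessions = CgmSessionSet(
            (
                _day("2014-03-03", "workday", [6.0, 6.0]),
                _day("2014-03-04", "workday", [10.0, 6.0]),
                _day("2014-03-08", "weekend", [5.0, 5.0]),
            )
        )
        avg = averaged_daily_profiles(sessions)
        np.testing.assert_allclose(avg["workday"], [8.0, 6.0])

    def test_missing_day_class_rejected(self):
        sessions = CgmSessionSet((_day("2014-03-03", "workday", [7.0]),))
        with pytest.raises(ValueError, match="weekend"):
            ww_extrapolate(sessions)

    def test_inconsistent_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            CgmSessionSet(
                (_day("2014-03-03", "workday", [7.0]), _day("2014-03-08", "weekend", [7.0, 7.0]))
            )


class TestIdExtrapolate:
    def test_single_day_repeats(self):
        sessions = CgmSessionSet((_day("2014-03-03", "workday", [7.5] * 4),))
        profile = id_extrapolate(sessions, 120)
        assert profile.bg.size == 120
        np.testing.assert_allclose(profile.bg, 7.5)

    def test_cyclic_mean_preserved(self):
        sessions = CgmSessionSet(
            tuple(
                _day(f"2014-03-0{i+3}", "workday", [m] * 4)
                for i, m in enumerate((6.0, 8.0, 10.0))
            )
        )
        assert id_extrapolate(sessions, 120).mbg == pytest.approx(8.0)

    def test_id_keeps_more_day_to_day_variation_than_ww(self):
        sessions = CgmSessionSet(
            (
                _day("2014-03-03", "workday", [6.0] * 4),
                _day("2014-03-04", "workday", [10.0] * 4),
                _day("2014-03-08", "weekend", [7.0] * 4),
                _day("2014-03-09", "weekend", [8.0] * 4),
            )
        )
        assert id_extrapolate(sessions, 120).sd >= ww_extrapolate(sessions, 120).sd


class TestScenarioProfile:
    def test_step_with_equal_levels_is_constant(self):
        spec = ScenarioSpec("step", baseline=7.0, level=7.0, change_day=40)
        np.testing.assert_allclose(scenario_profile(spec, 120).bg, 7.0)

    def test_ramp_endpoints_and_mean(self):
        spec = ScenarioSpec("ramp", baseline=22.2, level=5.6, duration_days=120)
        profile = scenario_profile(spec, 120)
        assert profile.bg[0] == pytest.approx(22.2)
        assert profile.bg[-1] == pytest.approx(5.6)
        assert profile.mbg == pytest.approx(13.9)

    def test_rectangle_exposure_sum(self):
        spec = ScenarioSpec("rectangle", baseline=5.6, level=22.2, duration_days=30)
        profile = scenario_profile(spec, 120)
        assert profile.bg.sum() == pytest.approx(22.2 * 30 + 5.6 * 90)

    def test_composite_frequencies(self):
        spec = ScenarioSpec("composite", base_day=(9.0,), hypo_day=(7.0,), frequency=1 / 3)
        profile = scenario_profile(spec, 12)
        assert (profile.bg == 7.0).sum() == 4
        zero = ScenarioSpec("composite", base_day=(9.0,), hypo_day=(7.0,), frequency=0.0)
        np.testing.assert_allclose(scenario_profile(zero, 12).bg, 9.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("step", baseline=-1.0, level=5.0)
        with pytest.raises(ValueError):
            ScenarioSpec("rectangle", level=5.0, duration_days=-3)
        with pytest.raises(ValueError):
            ScenarioSpec("sawtooth", level=5.0)


class TestProfileStats:
    def test_constant(self):
        stats = profile_stats(GlucoseProfile(np.full(10, 7.0)))
        assert stats == {"mbg": pytest.approx(7.0), "sd": pytest.approx(0.0)}

    def test_two_values_population_sd(self):
        stats = profile_stats(GlucoseProfile(np.array([5.0, 9.0])))
        assert stats["mbg"] == pytest.approx(7.0)
        assert stats["sd"] == pytest.approx(2.0)

    def test_midpoint_step_mean(self):
        spec = ScenarioSpec("step", baseline=22.2, level=5.6, change_day=60)
        assert profile_stats(scenario_profile(spec, 120))["mbg"] == pytest.approx(13.9)


class TestCgmCsvReader:
    def _write(self, tmp_path, frames):
        path = tmp_path / "cgm.csv"
        pd.concat(frames).to_csv(path, index=False)
        return path

    def _frame(self, date, values, minutes=5, day_type=None):
        ts = pd.date_range(date, periods=len(values), freq=f"{minutes}min")
        df = pd.DataFrame({"timestamp": ts, "glucose_mmol_l": values})
        if day_type:
            df["day_type"] = day_type
        return df

    def test_reads_full_days_and_calendar_labels(self, tmp_path):
        n = 288
        path = self._write(
            tmp_path,
            [
                self._frame("2014-03-03", np.full(n, 7.0)),  # Monday
                self._frame("2014-03-08", np.full(n, 6.0)),  # Saturday
            ],
        )
        sessions = read_cgm_csv(path)
        assert len(sessions.days) == 2
        assert {d.day_type for d in sessions.days} == {"workday", "weekend"}
        assert sessions.samples_per_day == 288

    def test_short_gap_interpolated_long_gap_drops_day(self, tmp_path):
        n = 288
        good = np.full(n, 7.0)
        good_frame = self._frame("2014-03-03", good)
        holey = self._frame("2014-03-04", np.linspace(6, 8, n)).drop(index=range(10, 20))
        lost = self._frame("2014-03-05", np.full(n, 9.0)).drop(index=range(50, 110))  # 5 h gap
        path = self._write(tmp_path, [good_frame, holey, lost])
        sessions = read_cgm_csv(path)
        dates = {d.date.day for d in sessions.days}
        assert dates == {3, 4}
        filled = [d for d in sessions.days if d.date.day == 4][0]
        assert np.all(np.isfinite(filled.glucose))
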