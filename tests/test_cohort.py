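"""Cohort population dynamics and the steady-state closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycosim import (
    CohortPopulation,
    GlucoseProfile,
    GlycationParams,
    advance_day,
    glycated_fraction,
    population_hba1c,
    simulate_course,
    steady_state_hba1c,
)


class TestGlycatedFraction:
    def test_zero_exposure(self, params):
        assert glycated_fraction(0.0, params) == 0.0

    def test_known_exposure(self, params):
        # 5.6 mmol/l held for 120 days
        assert glycated_fraction(5.6 * 120, params) == pytest.approx(0.0725, abs=1e-4)

    def test_saturates_at_one(self, params):
        assert glycated_fraction(1e9, params) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing(self, params):
        e = np.linspace(0, 5000, 200)
        f = [glycated_fraction(x, params) for x in e]
        assert np.all(np.diff(f) > 0)

    def test_negative_exposure_rejected(self, params):
        with pytest.raises(ValueError):
            glycated_fraction(-1.0, params)


class TestAdvanceDay:
    def test_single_day_scalar_update(self, params):
        """An existing unglycated cohort gains 1 - e^(-k_day * bg) in one day."""
        state = CohortPopulation.zero(params.lifespan_days)
        new = advance_day(state, 5.6, params)
        expected = -np.expm1(-params.k_day * 5.6)
        assert new.glycated_fraction_by_age[1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(6.2686e-4, rel=1e-4)

    def test_cohort_count_conserved(self, params):
        state = CohortPopulation.zero(params.lifespan_days)
        for _ in range(5):
            state = advance_day(state, 8.0, params)
        assert state.lifespan_days == params.lifespan_days
        assert state.total_cells == params.lifespan_days

    def test_lifespan_sweeps_in_steady_profile(self, params):
        """LS days of constant glucose from zero rebuild the steady age profile:
        age a carries (a - 1/2) days of exposure (half on the release day)."""
        state = CohortPopulation.zero(params.lifespan_days)
        for _ in range(params.lifespan_days):
            state = advance_day(state, 5.6, params)
        ages = state.ages_days
        expected = -np.expm1(-params.k_day * 5.6 * (ages - 0.5))
        np.testing.assert_allclose(state.glycated_fraction_by_age, expected, rtol=1e-12)

    def test_steady_state_is_fixed_point(self, params):
        state = CohortPopulation.steady_state(7.0, params)
        new = advance_day(state, 7.0, params)
        np.testing.assert_allclose(
            new.glycated_fraction_by_age, state.glycated_fraction_by_age, atol=1e-15
        )

    def test_non_positive_glucose_rejected(self, params):
        with pytest.raises(ValueError):
            advance_day(CohortPopulation.zero(120), 0.0, params)


class TestPopulationHba1c:
    def test_all_zero_fractions_hit_floor(self):
        v = population_hba1c(CohortPopulation.zero(120))
        assert v.ngsp_percent == pytest.approx(2.152)

    def test_constant_fractions_average_to_constant(self):
        state = CohortPopulation(np.full(10, 0.05), np.ones(10))
        v = population_hba1c(state)
        assert v.glycated_fraction == pytest.approx(0.05)
        assert v.ifcc_mmol_per_mol == pytest.approx(50.0)

    def test_cell_weighted_mean(self):
        state = CohortPopulation(np.array([0.02, 0.04]), np.array([1.0, 3.0]))
        assert population_hba1c(state).glycated_fraction == pytest.approx(0.035)

    def test_no_cells_rejected(self):
        with pytest.raises(ValueError):
            population_hba1c(CohortPopulation(np.array([0.1]), np.array([0.0])))


class TestSteadyState:
    def test_low_glucose_limit_approaches_floor(self, params):
        assert steady_state_hba1c(1e-9, params).ngsp_percent == pytest.approx(2.152, abs=1e-3)

    @pytest.mark.parametrize("mbg, ngsp", [(5.6, 5.51), (22.2, 14.54)])
    def test_closed_form_values(self, params, mbg, ngsp):
        assert steady_state_hba1c(mbg, params).ngsp_percent == pytest.approx(ngsp, abs=0.02)

    def test_monotone_in_mbg_k_and_lifespan(self):
        base = steady_state_hba1c(8.0, GlycationParams()).ngsp_percent
        assert steady_state_hba1c(9.0, GlycationParams()).ngsp_percent > base
        assert steady_state_hba1c(8.0, GlycationParams(k=1.4e-9)).ngsp_percent > base
        assert steady_state_hba1c(8.0, GlycationParams(lifespan_days=140)).ngsp_percent > base

    def test_non_positive_mbg_rejected(self, params):
        with pytest.raises(ValueError):
            steady_state_hba1c(0.0, params)


class TestSimulateCourse:
    def test_constant_profile_stays_constant(self, params):
        profile = GlucoseProfile(np.full(60, 5.6))
        course = simulate_course(profile, params, 5.6)
        ngsp = course["ngsp_percent"].to_numpy()
        assert np.ptp(ngsp) < 1e-9
        assert ngsp[0] == pytest.approx(5.51, abs=0.03)

    def test_output_length_matches_profile(self, params):
        course = simulate_course(GlucoseProfile(np.full(30, 7.0)), params, 7.0)
        assert len(course) == 30

    @given(st.floats(4.0, 22.0), st.floats(4.0, 22.0))
    @settings(max_examples=10, deadline=None)
    def test_pointwise_larger_glucose_larger_hba1c(self, lo, hi):
        """Pointwise-dominating glucose histories dominate in HbA1c."""
        params = GlycationParams()
        lo, hi = sorted((lo, hi))
        rng = np.random.default_rng(0)
        bg_lo = rng.uniform(4.0, lo + 1e-6, size=50)
        bg_hi = bg_lo + (hi - lo)
        a = simulate_course(GlucoseProfile(bg_lo), params, 4.0)["ngsp_percent"]
        b = simulate_course(GlucoseProfile(bg_hi), params, 4.0)["ngsp_percent"]
        assert np.all(b.to_numpy() >= a.to_numpy() - 1e-12)

    def test_fractions_bounded_and_floor_respected(self, params):
        rng = np.random.default_rng(1)
        profile = GlucoseProfile(rng.uniform(2.0, 30.0, 150))
        course = simulate_course(profile, params, 10.0, keep_states=True)
        assert (course["ngsp_percent"] >= 2.15).all()
        for state in course["state"]:
            f = state.glycated_fraction_by_age
            assert np.all((f >= 0) & (f <= 1))

    def test_piecewise_profile_matches_exposure_oracle(self, params):
        """Each cohort's fraction equals 1 - exp(-k_day * exposure), with the
        birth day weighted half, checked against a brute-force accumulation."""
        rng = np.random.default_rng(7)
        bg = rng.uniform(4.0, 15.0, params.lifespan_days)
        state = CohortPopulation.zero(params.lifespan_days)
        for g in bg:
            state = advance_day(state, float(g), params)
        L = params.lifespan_days
        for age in (1, 3, 57, 120):
            born = L - age  # 0-based index of the cohort's birth day
            exposure = 0.5 * bg[born] + bg[born + 1 :].sum()
            expected = -np.expm1(-params.k_day * exposure)
            assert state.glycated_fraction_by_age[age - 1] == pytest.approx(expected, rel=1e-10)

    def test_gapped_profile_rejected(self):
        with pytest.raises(ValueError, match="non-finite|gaps"):
            GlucoseProfile(np.array([5.0, np.nan, 6.0]))


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"k": 0.0}, {"k": -1e-9}, {"lifespan_days": 0}, {"step_days": 0.3}]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GlycationParams(**kwargs)

    def test_csv_roundtrip(self, params, tmp_path):
        state = CohortPopulation.steady_state(8.0, params)
        path = tmp_path / "state.csv"
        state.to_csv(path)
        back = CohortPopulation.from_csv(path)
        np.testing.assert_allclose(
            back.glycated_fraction_by_age, state.glycated_fraction_by_age, rtol=1e-12
        )
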