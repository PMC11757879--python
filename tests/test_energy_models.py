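"""METs model, slope cost, ACSM references, accumulation."""

import math

import numpy as np
import pytest

from trackmets import (
    DEFAULT_COEFFICIENTS,
    AthleteProfile,
    EmptyTrackError,
    ModelCoefficients,
    ParameterError,
    accumulate,
    acsm_run_vo2,
    acsm_rw_vo2,
    acsm_walk_vo2,
    cost_of_slope,
    mets_horizontal,
    mets_on_slope,
)
from trackmets.kinematics import Segment, TrackKinematics


def one_leg_kin(speed_kmh=10.0, slope_pct=0.0, duration_s=360.0, n_sub=1):
    """A TrackKinematics of n_sub identical sub-segments covering one leg."""
    d3 = speed_kmh / 3.6 * duration_s / n_sub
    grade = slope_pct / 100.0
    h = d3 / math.sqrt(1 + grade * grade)
    segs = [Segment(i, i + 1, h, h * grade, d3, duration_s / n_sub, speed_kmh, slope_pct)
            for i in range(n_sub)]
    return TrackKinematics(segments=segs,
                           total_distance_m=d3 * n_sub,
                           total_duration_s=duration_s)


class TestMetsHorizontal:
    @pytest.mark.parametrize("v,expected,tol", [
        (0.0, 1.2896, 1e-4),       # exp of the slow-branch intercept
        (17.4, 16.05, 0.01),       # fast branch at the fastest observed mean speed
        (10.0, 9.886, 1e-3),
    ])
    def test_direct_evaluation(self, v, expected, tol):
        assert mets_horizontal(v) == pytest.approx(expected, abs=tol)

    def test_branches_agree_at_threshold(self):
        c = DEFAULT_COEFFICIENTS
        slow = math.exp(c.eq1_slope * 8.69 + c.eq1_intercept)
        fast = math.exp(c.eq2_slope * 8.69 + c.eq2_intercept)
        assert slow == pytest.approx(9.074, abs=1e-3)
        assert fast == pytest.approx(9.074, abs=1e-3)
        assert abs(slow - fast) < 0.01

    def test_strictly_increasing_on_tabulated_range(self):
        v = np.linspace(0, 20, 401)
        m = np.array([mets_horizontal(x) for x in v])
        assert np.all(np.diff(m) > 0)

    def test_negative_speed_rejected(self):
        with pytest.raises(ParameterError):
            mets_horizontal(-1.0)


class TestCostOfSlope:
    def test_flat_costs_exactly_one(self):
        assert cost_of_slope(0.0) == 1.0

    @pytest.mark.parametrize("s,expected", [(10.0, 1.65573), (-10.0, 0.61731)])
    def test_direct_evaluation(self, s, expected):
        assert cost_of_slope(s) == pytest.approx(expected, abs=1e-5)

    def test_clipped_beyond_validity_range(self):
        assert cost_of_slope(60.0) == cost_of_slope(45.0)
        assert cost_of_slope(-60.0) == cost_of_slope(-45.0)

    def test_minimum_near_minus_19_percent_and_positive(self):
        c = DEFAULT_COEFFICIENTS
        vertex = -c.cost_b / (2 * c.cost_a)
        assert vertex == pytest.approx(-19.0, abs=0.1)
        s = np.linspace(-45, 45, 901)
        costs = np.array([cost_of_slope(x) for x in s])
        assert np.all(costs > 0)
        assert s[np.argmin(costs)] == pytest.approx(vertex, abs=0.1)


class TestMetsOnSlope:
    @pytest.mark.parametrize("v,s,expected,tol", [
        (10.0, 0.0, 9.886, 1e-3),
        (10.0, 10.0, 16.368, 5e-3),
        (0.0, 0.0, 1.2896, 1e-4),
    ])
    def test_product_of_components(self, v, s, expected, tol):
        assert mets_on_slope(v, s) == pytest.approx(expected, abs=tol)

    def test_monotone_in_slope_at_fixed_speed(self):
        assert mets_on_slope(10, 10) > mets_on_slope(10, 0) > mets_on_slope(10, -10)


class TestAcsm:
    def test_walk_flat_8kmh(self):
        v = acsm_walk_vo2(8.0, 0.0)
        assert v == pytest.approx(16.83, abs=0.01)
        assert round(v, 1) == 16.8

    def test_run_flat_8kmh(self):
        v = acsm_run_vo2(8.0, 0.0)
        assert v == pytest.approx(30.17, abs=0.01)
        assert round(v, 1) == 30.2

    @pytest.mark.parametrize("fn", [acsm_walk_vo2, acsm_run_vo2])
    def test_standing_is_resting_rate(self, fn):
        assert fn(0.0, 0.0) == pytest.approx(3.5)

    def test_graded_walk_and_run(self):
        assert acsm_walk_vo2(5.0, 0.05) == pytest.approx(19.33, abs=0.01)
        assert acsm_run_vo2(12.0, 0.05) == pytest.approx(52.5, abs=0.01)

    def test_rw_branches(self):
        assert acsm_rw_vo2(7.99, 0.0) == pytest.approx(16.82, abs=0.01)  # walking side
        assert acsm_rw_vo2(8.0, 0.0) == pytest.approx(30.17, abs=0.01)   # running side
        assert acsm_rw_vo2(5.0, 0.0) == acsm_walk_vo2(5.0, 0.0)

    def test_rw_jump_vs_mets_model_continuity(self):
        """The piecewise ACSM rate jumps ~13.3 ml/kg/min across 8 km/h on the
        flat; the METs model's rate is continuous there (its branches agree)."""
        jump = acsm_rw_vo2(8.0, 0.0) - acsm_rw_vo2(8.0 - 1e-9, 0.0)
        assert jump == pytest.approx(13.33, abs=0.01)
        eps = 1e-6
        mets_gap = abs(mets_horizontal(8.69 + eps) - mets_horizontal(8.69 - eps))
        assert mets_gap < 0.01

    def test_negative_speed_rejected(self):
        for fn in (acsm_walk_vo2, acsm_run_vo2, acsm_rw_vo2):
            with pytest.raises(ParameterError):
                fn(-0.1, 0.0)


class TestAccumulate:
    def test_single_leg_mets_method(self):
        summary = accumulate(one_leg_kin(10.0, 0.0, 360.0), "hypac")
        assert summary.total_met_hours == pytest.approx(0.9886, abs=1e-3)
        assert summary.vo2_ml_per_kg == pytest.approx(207.6, abs=0.2)
        assert summary.vo2_l is None and summary.energy_kcal is None

    def test_body_mass_scaling(self):
        summary = accumulate(one_leg_kin(10.0, 0.0, 360.0), "hypac", AthleteProfile(60.0))
        assert summary.vo2_l == pytest.approx(12.46, abs=0.02)
        assert summary.energy_kcal == pytest.approx(62.3, abs=0.1)

    def test_running_equation_applied_at_all_speeds(self):
        # acsm_run uses the running equation even below 8 km/h
        slow = accumulate(one_leg_kin(6.0, 0.0, 60.0), "acsm_run")
        assert slow.vo2_ml_per_kg == pytest.approx(acsm_run_vo2(6.0, 0.0), abs=1e-9)
        # 10 km/h flat for 6 min: 166.67 m/min * 0.2 + 3.5 = 36.83 ml/kg/min
        leg = accumulate(one_leg_kin(10.0, 0.0, 360.0), "acsm_run")
        assert leg.vo2_ml_per_kg == pytest.approx(221.0, abs=0.1)

    def test_rw_uses_walk_below_threshold(self):
        s = accumulate(one_leg_kin(6.0, 0.0, 60.0), "acsm_rw")
        assert s.vo2_ml_per_kg == pytest.approx(acsm_walk_vo2(6.0, 0.0), abs=1e-9)

    @pytest.mark.parametrize("method", ["hypac", "acsm_rw", "acsm_run"])
    @pytest.mark.parametrize("k", [2, 5, 16])
    def test_splitting_a_segment_is_additive(self, method, k):
        whole = accumulate(one_leg_kin(9.0, 5.0, 600.0, n_sub=1), method)
        split = accumulate(one_leg_kin(9.0, 5.0, 600.0, n_sub=k), method)
        assert split.vo2_ml_per_kg == pytest.approx(whole.vo2_ml_per_kg, rel=1e-9)
        assert split.total_met_hours == pytest.approx(whole.total_met_hours, rel=1e-9)

    def test_slope_ordering_of_totals(self):
        flat = accumulate(one_leg_kin(10.0, 0.0, 360.0), "hypac")
        up = accumulate(one_leg_kin(10.0, 10.0, 360.0), "hypac")
        down = accumulate(one_leg_kin(10.0, -10.0, 360.0), "hypac")
        assert up.vo2_ml_per_kg > flat.vo2_ml_per_kg > down.vo2_ml_per_kg

    def test_empty_kinematics_rejected(self):
        with pytest.raises(EmptyTrackError):
            accumulate(TrackKinematics(segments=[]), "hypac")

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError):
            accumulate(one_leg_kin(), "vo2max")


def test_coefficients_must_be_positive():
    with pytest.raises(ParameterError):
        ModelCoefficients(cost_a=-1.0)
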