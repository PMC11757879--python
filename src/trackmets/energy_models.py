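"""Metabolic models: METs from speed, slope cost, ACSM references, accumulation.

The core model estimates exercise intensity for horizontal travel from speed
with two log-linear regressions fitted to compendium METs tables, switching at
8.69 km/h where the two lines intersect::

    ln(METs) = 0.224528 · v + 0.254354      (v < 8.69 km/h)
    ln(METs) = 0.065439 · v + 1.636715      (v ≥ 8.69 km/h)

and corrects for gradient with a quadratic *cost of slope* — the ratio of
uphill/downhill VO₂ to horizontal VO₂ at the same speed, fitted to treadmill
gradient data spanning ±45 %::

    Cost(s) = 13.6524e-4 · s² + 5.1921e-2 · s + 1      (s = slope in %)

    METs_slope = METs_horizontal × Cost(s)

VO₂ follows from the 1 MET ≡ 3.5 ml O₂/kg/min convention (so 1 MET·h =
210 ml/kg), liters from body mass, kilocalories from 5 kcal per liter of O₂.

For reference, the ACSM walking (< 8 km/h) and running (≥ 8 km/h) equations
are included; their well-known discontinuity at exactly 8 km/h on the flat
(16.8 vs 30.2 ml/kg/min) is the inconsistency the piecewise METs model avoids.

Unit conventions at this boundary (mind the classic 100× bug): the METs-based
model takes slope in **percent**; the ACSM equations take grade as a
**decimal fraction** (0.05 = 5 %). Segments store percent; adapters convert.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Literal, Optional

from .errors import EmptyTrackError, ParameterError, ProfileError
from .kinematics import TrackKinematics
from .track_io import AthleteProfile

logger = logging.getLogger(__name__)

__all__ = [
    "Method",
    "METHODS",
    "ModelCoefficients",
    "DEFAULT_COEFFICIENTS",
    "SegmentEnergy",
    "ActivitySummary",
    "mets_horizontal",
    "cost_of_slope",
    "mets_on_slope",
    "acsm_walk_vo2",
    "acsm_run_vo2",
    "acsm_rw_vo2",
    "segment_energies",
    "accumulate",
]

Method = Literal["hypac", "acsm_rw", "acsm_run"]
METHODS: tuple[Method, ...] = ("hypac", "acsm_rw", "acsm_run")

#: Speed beyond the compendium's tabulated range; the fast regression line
#: extrapolates exponentially above this, so a warning is logged.
_EXTRAPOLATION_WARN_KMH = 20.0


@dataclass(frozen=True)
class ModelCoefficients:
    """Every published constant of the models in one immutable place.

    Defaults are the published values; replace a field only for sensitivity
    analyses, never for fitting.
    """

    eq1_slope: float = 0.224528        # per km/h, slow branch
    eq1_intercept: float = 0.254354    # ln METs
    eq2_slope: float = 0.065439        # per km/h, fast branch
    eq2_intercept: float = 1.636715    # ln METs
    speed_threshold_kmh: float = 8.69  # branch switch = intersection of the lines
    cost_a: float = 13.6524e-4         # per %^2
    cost_b: float = 5.1921e-2          # per %
    cost_c: float = 1.0                # Y-intercept: flat ground costs 1x
    met_vo2_ml_kg_min: float = 3.5     # 1 MET in ml O2 / kg / min
    kcal_per_l_o2: float = 5.0
    acsm_walk_speed_coef: float = 0.1  # ml/kg per m
    acsm_walk_grade_coef: float = 1.8
    acsm_run_speed_coef: float = 0.2
    acsm_run_grade_coef: float = 0.9
    acsm_rest: float = 3.5             # ml/kg/min
    acsm_threshold_kmh: float = 8.0
    slope_clip_pct: float = 45.0       # gradient range of the source data

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ParameterError(f"coefficient {f.name} must be strictly positive")


DEFAULT_COEFFICIENTS = ModelCoefficients()


def mets_horizontal(speed_kmh: float, coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Exercise intensity (METs) for horizontal travel at ``speed_kmh``.

    Piecewise log-linear in speed; the two branches agree to < 0.01 METs at
    the 8.69 km/h threshold, so the function is effectively continuous.
    """
    if speed_kmh < 0:
        raise ParameterError(f"speed must be non-negative, got {speed_kmh}")
    if speed_kmh > _EXTRAPOLATION_WARN_KMH:
        logger.warning("speed %.2f km/h beyond tabulated range (%g km/h); "
                       "METs model extrapolates", speed_kmh, _EXTRAPOLATION_WARN_KMH)
    if speed_kmh < coef.speed_threshold_kmh:
        return math.exp(coef.eq1_slope * speed_kmh + coef.eq1_intercept)
    return math.exp(coef.eq2_slope * speed_kmh + coef.eq2_intercept)


def cost_of_slope(slope_pct: float, coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Multiplicative VO₂ cost of a gradient, relative to the flat (= 1 at 0 %).

    Input is clipped to ±``coef.slope_clip_pct`` (the model's validity range);
    clips are logged, never silent.
    """
    s = slope_pct
    if abs(s) > coef.slope_clip_pct:
        logger.info("slope %.1f%% clipped to ±%.1f%%", s, coef.slope_clip_pct)
        s = math.copysign(coef.slope_clip_pct, s)
    return coef.cost_a * s * s + coef.cost_b * s + coef.cost_c


def mets_on_slope(speed_kmh: float, slope_pct: float,
                  coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Slope-adjusted METs: horizontal METs times the slope-cost multiplier."""
    return mets_horizontal(speed_kmh, coef) * cost_of_slope(slope_pct, coef)


def _mpm(speed_kmh: float) -> float:
    return speed_kmh * 1000.0 / 60.0


def acsm_walk_vo2(speed_kmh: float, slope_decimal: float = 0.0,
                  coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """ACSM walking VO₂ rate (ml/kg/min); grade is a decimal fraction."""
    if speed_kmh < 0:
        raise ParameterError(f"speed must be non-negative, got {speed_kmh}")
    v = _mpm(speed_kmh)
    return v * coef.acsm_walk_speed_coef + v * slope_decimal * coef.acsm_walk_grade_coef + coef.acsm_rest


def acsm_run_vo2(speed_kmh: float, slope_decimal: float = 0.0,
                 coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """ACSM running VO₂ rate (ml/kg/min); grade is a decimal fraction."""
    if speed_kmh < 0:
        raise ParameterError(f"speed must be non-negative, got {speed_kmh}")
    v = _mpm(speed_kmh)
    return v * coef.acsm_run_speed_coef + v * slope_decimal * coef.acsm_run_grade_coef + coef.acsm_rest


def acsm_rw_vo2(speed_kmh: float, slope_decimal: float = 0.0,
                coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Piecewise ACSM rate: walking below 8 km/h, running at and above."""
    if speed_kmh < coef.acsm_threshold_kmh:
        return acsm_walk_vo2(speed_kmh, slope_decimal, coef)
    return acsm_run_vo2(speed_kmh, slope_decimal, coef)


@dataclass(frozen=True)
class SegmentEnergy:
    """Energy bookkeeping for one segment under one method.

    For the METs-based method, ``vo2_ml_per_kg = met_hours × 3.5 × 60``; the
    ACSM methods produce rate × minutes directly and carry no METs fields.
    """

    i_start: int
    speed_kmh: float
    slope_pct: float
    method: Method
    met_hours: float
    vo2_ml_per_kg: float
    mets_horizontal: Optional[float] = None
    cost_slope: Optional[float] = None
    mets_slope: Optional[float] = None


@dataclass(frozen=True)
class ActivitySummary:
    """Whole-activity totals under one estimation method.

    ``vo2_l`` and ``energy_kcal`` require body mass and are ``None`` without
    an athlete profile.
    """

    method: Method
    total_met_hours: float
    vo2_ml_per_kg: float
    distance_m: float
    duration_s: float
    mean_speed_kmh: float
    n_segments: int
    vo2_l: Optional[float] = None
    energy_kcal: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def segment_energies(kin: TrackKinematics, method: Method,
                     coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> list[SegmentEnergy]:
    """Per-segment energy under ``method`` (no body-mass scaling)."""
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")
    out: list[SegmentEnergy] = []
    for seg in kin.segments:
        hours = seg.duration_s / 3600.0
        if method == "hypac":
            m_h = mets_horizontal(seg.speed_kmh, coef)
            cost = cost_of_slope(seg.slope_pct, coef)
            met_hours = m_h * cost * hours
            vo2 = met_hours * coef.met_vo2_ml_kg_min * 60.0
            out.append(SegmentEnergy(seg.i_start, seg.speed_kmh, seg.slope_pct, method,
                                     met_hours, vo2, m_h, cost, m_h * cost))
        else:
            clipped = math.copysign(min(abs(seg.slope_pct), coef.slope_clip_pct),
                                    seg.slope_pct)
            grade = clipped / 100.0  # ACSM equations take decimal grade, not percent
            rate = (acsm_run_vo2 if method == "acsm_run" else acsm_rw_vo2)(
                seg.speed_kmh, grade, coef)
            vo2 = rate * seg.duration_s / 60.0
            met_hours = vo2 / (coef.met_vo2_ml_kg_min * 60.0)
            out.append(SegmentEnergy(seg.i_start, seg.speed_kmh, seg.slope_pct, method,
                                     met_hours, vo2))
    return out


def accumulate(
    kin: TrackKinematics,
    method: Method,
    profile: Optional[AthleteProfile] = None,
    coef: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> ActivitySummary:
    """Sum per-segment energies into an :class:`ActivitySummary`.

    ``acsm_run`` applies the running equation at *all* segment speeds
    (including walking ones); ``acsm_rw`` switches walk/run at 8 km/h.
    """
    if not kin.segments:
        raise EmptyTrackError("no segments to accumulate (all dropped or empty track)")
    energies = segment_energies(kin, method, coef)
    met_hours = sum(e.met_hours for e in energies)
    vo2 = sum(e.vo2_ml_per_kg for e in energies)
    vo2_l = kcal = None
    if profile is not None:
        vo2_l = vo2 * profile.body_mass_kg / 1000.0
        kcal = vo2_l * coef.kcal_per_l_o2
    dist, dur = kin.total_distance_m, kin.total_duration_s
    return ActivitySummary(
        method=method,
        total_met_hours=met_hours,
        vo2_ml_per_kg=vo2,
        distance_m=dist,
        duration_s=dur,
        mean_speed_kmh=(dist / 1000.0) / (dur / 3600.0) if dur > 0 else 0.0,
        n_segments=len(kin.segments),
        vo2_l=vo2_l,
        energy_kcal=kcal,
    )


def require_mass(profile: Optional[AthleteProfile]) -> AthleteProfile:
    """Raise :class:`ProfileError` unless a profile with body mass is given."""
    if profile is None:
        raise ProfileError("body mass required to report liters of O2 or kcal")
    return profile
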