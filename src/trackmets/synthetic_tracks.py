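"""Seeded synthetic GPS tracks with closed-form expected energy outputs.

A course is a list of legs, each with a constant 3-D speed, slope and
duration — emulating a mixed downhill/uphill/flat route sampled at 1 Hz.
Points are laid out along a meridian from the origin, so the meters→degrees
conversion is latitude-independent (1° of arc = 111,194.93 m on the
6,371 km sphere) and tests avoid cos(lat) confounds. The horizontal step is
sized so the *3-D* speed equals the specified speed and rise/run equals the
specified slope, matching the kinematics convention that speed uses 3-D
distance.

Each leg's duration is quantized to a whole number of sampling intervals
(``round(duration / interval)``), and the analytic expected summaries use the
quantized durations, so a noise-free track round-trips through the pipeline
exactly (up to floating-point error).

Gaussian noise (one seeded generator per bundle) can be added to positions
(in meters, converted to degrees) and elevations; this emulates white GPS
jitter only, not multipath or autocorrelated drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np

from .energy_models import (
    DEFAULT_COEFFICIENTS,
    METHODS,
    ActivitySummary,
    Method,
    ModelCoefficients,
    accumulate,
    acsm_run_vo2,
    acsm_rw_vo2,
    cost_of_slope,
    mets_horizontal,
)
from .errors import ParameterError
from .kinematics import EARTH_RADIUS_M, segment_track
from .track_io import Track, TrackPoint

__all__ = [
    "LegSpec",
    "SyntheticBundle",
    "generate",
    "expected_summary",
    "pipeline_roundtrip_check",
    "METERS_PER_DEGREE",
]

#: Meters per degree of arc on the reference sphere (meridian direction).
METERS_PER_DEGREE = 2.0 * math.pi * EARTH_RADIUS_M / 360.0

_T0 = datetime(2024, 1, 1, 0, 0, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class LegSpec:
    """One constant-speed, constant-slope leg of a synthetic course."""

    speed_kmh: float
    slope_pct: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ParameterError(f"leg speed must be positive, got {self.speed_kmh}")
        if not -45.0 <= self.slope_pct <= 45.0:
            raise ParameterError(f"leg slope {self.slope_pct}% outside ±45%")
        if self.duration_s <= 0:
            raise ParameterError(f"leg duration must be positive, got {self.duration_s}")


@dataclass
class SyntheticBundle:
    """A generated track plus its analytic, noise-free expected summaries."""

    track: Track
    expected: dict[Method, ActivitySummary]
    spec: list[LegSpec]
    seed: int
    noise_pos_m: float
    noise_ele_m: float
    sample_interval_s: float


def _quantized(leg: LegSpec, interval: float) -> tuple[int, float]:
    """Number of samples for a leg and the quantized duration they span."""
    n = max(1, int(round(leg.duration_s / interval)))
    return n, n * interval


def expected_summary(legs: list[LegSpec], method: Method,
                     sample_interval_s: float = 1.0,
                     coef: ModelCoefficients = DEFAULT_COEFFICIENTS) -> ActivitySummary:
    """Closed-form activity summary for a noise-free course (no body mass)."""
    met_hours = vo2 = dist = dur = 0.0
    n_segments = 0
    for leg in legs:
        n, d = _quantized(leg, sample_interval_s)
        hours = d / 3600.0
        if method == "hypac":
            mh = mets_horizontal(leg.speed_kmh, coef) * cost_of_slope(leg.slope_pct, coef) * hours
            met_hours += mh
            vo2 += mh * coef.met_vo2_ml_kg_min * 60.0
        else:
            rate_fn = acsm_run_vo2 if method == "acsm_run" else acsm_rw_vo2
            v = rate_fn(leg.speed_kmh, leg.slope_pct / 100.0, coef) * d / 60.0
            vo2 += v
            met_hours += v / (coef.met_vo2_ml_kg_min * 60.0)
        dist += leg.speed_kmh / 3.6 * d
        dur += d
        n_segments += n
    return ActivitySummary(
        method=method, total_met_hours=met_hours, vo2_ml_per_kg=vo2,
        distance_m=dist, duration_s=dur,
        mean_speed_kmh=(dist / 1000.0) / (dur / 3600.0),
        n_segments=n_segments,
    )


def generate(
    spec: list[LegSpec],
    sample_interval_s: float = 1.0,
    noise_pos_m: float = 0.0,
    noise_ele_m: float = 0.0,
    seed: int = 0,
    origin: tuple[float, float] = (35.0, 139.0),
    start_elevation_m: float = 100.0,
    name: str = "synthetic",
) -> SyntheticBundle:
    """Generate a synthetic 1-Hz-style GPS track with known energy totals.

    Identical ``(spec, seed, …)`` arguments produce byte-identical tracks.
    """
    if not spec:
        raise ParameterError("need at least one leg")
    if sample_interval_s <= 0:
        raise ParameterError("sample interval must be positive")
    if noise_pos_m < 0 or noise_ele_m < 0:
        raise ParameterError("noise standard deviations must be non-negative")

    lat, lon = origin
    ele = start_elevation_m
    t = _T0
    points = [TrackPoint(t, lat, lon, ele)]
    for leg in spec:
        n, _ = _quantized(leg, sample_interval_s)
        d3_step = leg.speed_kmh / 3.6 * sample_interval_s
        grade = leg.slope_pct / 100.0
        h_step = d3_step / math.sqrt(1.0 + grade * grade)
        v_step = h_step * grade
        for _ in range(n):
            lat += h_step / METERS_PER_DEGREE
            ele += v_step
            t += timedelta(seconds=sample_interval_s)
            points.append(TrackPoint(t, lat, lon, ele))

    if noise_pos_m > 0 or noise_ele_m > 0:
        rng = np.random.default_rng(seed)
        coslat0 = math.cos(math.radians(origin[0]))
        noisy = []
        for p in points:
            dlat = rng.normal(0.0, noise_pos_m) / METERS_PER_DEGREE if noise_pos_m else 0.0
            dlon = (rng.normal(0.0, noise_pos_m) / (METERS_PER_DEGREE * coslat0)
                    if noise_pos_m else 0.0)
            dele = rng.normal(0.0, noise_ele_m) if noise_ele_m else 0.0
            noisy.append(TrackPoint(p.timestamp, p.lat + dlat, p.lon + dlon,
                                    p.elevation_m + dele))
        points = noisy

    track = Track(points=points, name=name, source="synthetic")
    expected = {m: expected_summary(spec, m, sample_interval_s) for m in METHODS}
    return SyntheticBundle(track, expected, list(spec), seed,
                           noise_pos_m, noise_ele_m, sample_interval_s)


def pipeline_roundtrip_check(bundle: SyntheticBundle, tolerance_rel: float = 1e-3) -> dict:
    """Run the full pipeline on the bundle's track and compare with expectations.

    Returns a report dict; deviations beyond ``tolerance_rel`` are flagged in
    the report, never raised — noisy bundles are *expected* to deviate.
    """
    kin = segment_track(bundle.track)
    per_method: dict[str, dict] = {}
    max_dev = 0.0
    for m in METHODS:
        measured = accumulate(kin, m)
        exp = bundle.expected[m]
        dev = abs(measured.vo2_ml_per_kg - exp.vo2_ml_per_kg) / exp.vo2_ml_per_kg
        max_dev = max(max_dev, dev)
        per_method[m] = {
            "expected_vo2_ml_per_kg": exp.vo2_ml_per_kg,
            "measured_vo2_ml_per_kg": measured.vo2_ml_per_kg,
            "rel_deviation": dev,
            "within_tolerance": dev <= tolerance_rel,
        }
    return {
        "tolerance_rel": tolerance_rel,
        "max_rel_deviation": max_dev,
        "all_within_tolerance": max_dev <= tolerance_rel,
        "per_method": per_method,
        "n_segments": len(kin.segments),
    }
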