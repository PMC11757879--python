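"""Track → per-segment distance, duration, speed, slope.

Each adjacent pair of points becomes a :class:`Segment`. The horizontal
component is a great-circle (haversine) distance; the 3-D distance combines it
with the elevation delta by Pythagoras — at 1 Hz walking/running scales
(hops < 10 m) the planar-vs-spherical discrepancy is far below GPS noise.

Two conventions to keep straight:

* **speed** uses the 3-D distance (distance actually traveled);
* **slope** is 100 × vertical / horizontal, i.e. rise over *horizontal* run,
  in percent.

Degenerate data is filtered rather than fatal: zero-duration segments (real
devices emit duplicate timestamps) and implausible speeds (GPS "teleports",
default threshold 40 km/h) are dropped and counted. A purely vertical step
gets the slope clip bound (±45 %, the validity range of the slope-cost model)
with the sign of the elevation change, never an infinite slope.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from .errors import EmptyTrackError, IncompleteElevationError, ParameterError
from .track_io import Track, TrackPoint

__all__ = [
    "EARTH_RADIUS_M",
    "Segment",
    "TrackKinematics",
    "haversine_m",
    "segment_track",
    "smooth_elevation",
]

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in meters on a sphere of radius 6,371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ParameterError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ParameterError(f"longitude {lon} outside [-180, 180]")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


@dataclass(frozen=True)
class Segment:
    """Kinematics of one adjacent-point interval (``i_end = i_start + 1``)."""

    i_start: int
    i_end: int
    horizontal_m: float
    vertical_m: float
    distance3d_m: float
    duration_s: float
    speed_kmh: float
    slope_pct: float


@dataclass
class TrackKinematics:
    """All kept segments of a track plus drop counters and totals."""

    segments: list[Segment]
    n_dropped_zero_duration: int = 0
    n_dropped_outlier: int = 0
    total_distance_m: float = 0.0
    total_duration_s: float = 0.0
    elevation_gain_m: float = 0.0

    def __len__(self) -> int:
        return len(self.segments)

    def to_rows(self) -> list[dict]:
        """One dict per segment, for CSV/DataFrame export."""
        return [vars(s).copy() for s in self.segments]


def segment_track(
    track: Track,
    *,
    outlier_speed_max_kmh: float = 40.0,
    slope_clip_pct: float = 45.0,
) -> TrackKinematics:
    """Convert a fully-elevated track into per-segment kinematics.

    Raises
    ------
    EmptyTrackError
        Fewer than 2 points.
    IncompleteElevationError
        Any point lacks elevation (annotate the track first).
    """
    if len(track.points) < 2:
        raise EmptyTrackError("need at least 2 points to form a segment")
    missing = [i for i, p in enumerate(track.points) if p.elevation_m is None]
    if missing:
        raise IncompleteElevationError(missing)

    segments: list[Segment] = []
    n_zero = n_outlier = 0
    gain = 0.0
    for i in range(len(track.points) - 1):
        a, b = track.points[i], track.points[i + 1]
        dt = (b.timestamp - a.timestamp).total_seconds()
        if dt <= 0.0:
            n_zero += 1
            continue
        h = haversine_m(a.lat, a.lon, b.lat, b.lon)
        v = b.elevation_m - a.elevation_m  # type: ignore[operator]
        d3 = math.hypot(h, v)
        # snap to 1e-6 km/h (far below GPS resolution) so that knife-edge
        # speeds land deterministically on model branch thresholds
        speed = round((d3 / 1000.0) / (dt / 3600.0), 6)
        if speed > outlier_speed_max_kmh:
            n_outlier += 1
            continue
        if h > 0.0:
            slope = round(100.0 * v / h, 6)
        elif v != 0.0:
            slope = math.copysign(slope_clip_pct, v)
        else:
            slope = 0.0
        segments.append(Segment(i, i + 1, h, v, d3, dt, speed, slope))
        if v > 0.0:
            gain += v

    return TrackKinematics(
        segments=segments,
        n_dropped_zero_duration=n_zero,
        n_dropped_outlier=n_outlier,
        total_distance_m=sum(s.distance3d_m for s in segments),
        total_duration_s=sum(s.duration_s for s in segments),
        elevation_gain_m=gain,
    )


def smooth_elevation(track: Track, window: int) -> Track:
    """Centered moving-median elevation smoothing with edge truncation.

    ``window`` must be odd; 1 is the identity. Off by default throughout the
    pipeline — raw device elevations are the reference behavior.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd integer >= 1, got {window}")
    if window == 1:
        return track.with_points(list(track.points))
    if any(p.elevation_m is None for p in track.points):
        raise IncompleteElevationError(
            [i for i, p in enumerate(track.points) if p.elevation_m is None],
            "cannot smooth a track with missing elevations",
        )
    half = window // 2
    eles = [p.elevation_m for p in track.points]
    new_points = []
    for i, p in enumerate(track.points):
        lo, hi = max(0, i - half), min(len(eles), i + half + 1)
        new_points.append(TrackPoint(p.timestamp, p.lat, p.lon, statistics.median(eles[lo:hi])))
    return track.with_points(new_points)
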