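"""Elevation providers and track annotation.

Slope computation needs an elevation at every point. When the device did not
record one (or should be overridden, e.g. by national-survey terrain data),
elevations come from a pluggable provider: any object with a
``lookup(lat, lon) -> float | None`` method, returning ``None`` for
coordinates it does not cover. The in-memory :class:`ElevationGrid` provider
makes the whole pipeline testable offline; a thin adapter around a web
altitude API can satisfy the same contract.

Grid file dialect (deliberately simple, plain text)::

    origin_lat,origin_lon,cell_deg
    35.0,139.0,0.001
    100.0,101.0,102.0
    110.0,111.0,112.0

Line 1 is a literal header, line 2 the three grid parameters, then one CSV row
of elevations per grid row. ``values[i, j]`` sits at latitude
``origin_lat + i*cell_deg``, longitude ``origin_lon + j*cell_deg`` (cell
centers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Protocol, runtime_checkable

import numpy as np

from .errors import IncompleteElevationError, ParameterError
from .track_io import Track, TrackPoint

logger = logging.getLogger(__name__)

__all__ = [
    "ElevationGrid",
    "ElevationProvider",
    "grid_lookup",
    "annotate_track",
    "read_grid_csv",
    "write_grid_csv",
]


@runtime_checkable
class ElevationProvider(Protocol):
    """Deterministic point-elevation source; ``None`` signals no coverage."""

    def lookup(self, lat: float, lon: float) -> Optional[float]:
        ...


@dataclass
class ElevationGrid:
    """Regular lat/lon raster of elevations, queried by interpolation.

    Parameters
    ----------
    origin_lat, origin_lon
        Coordinates of the center of cell ``(0, 0)``, in degrees.
    cell_deg
        Grid spacing in degrees (> 0), identical in both axes.
    values
        2-D array of elevations in meters, row index = latitude.
    interpolation
        ``"bilinear"`` (default) or ``"nearest"``.
    """

    origin_lat: float
    origin_lon: float
    cell_deg: float
    values: np.ndarray
    interpolation: Literal["bilinear", "nearest"] = "bilinear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_deg <= 0:
            raise ParameterError(f"cell_deg must be positive, got {self.cell_deg}")
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ParameterError("grid must be 2-D with at least 2x2 cells")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("grid contains non-finite values")

    def lookup(self, lat: float, lon: float) -> Optional[float]:
        return grid_lookup(self, lat, lon)


def grid_lookup(grid: ElevationGrid, lat: float, lon: float) -> Optional[float]:
    """Interpolated elevation at (lat, lon), or ``None`` outside coverage.

    Coverage is the bounding box of the cell *centers*; inside it, bilinear
    interpolation among the four surrounding centers (exact for any field
    linear in lat and lon). Returns a plain float, never raises for
    out-of-range queries, so callers can fall back to device elevation.
    """
    nrow, ncol = grid.values.shape
    r = (lat - grid.origin_lat) / grid.cell_deg
    c = (lon - grid.origin_lon) / grid.cell_deg
    if not (0.0 <= r <= nrow - 1 and 0.0 <= c <= ncol - 1):
        return None
    if grid.interpolation == "nearest":
        return float(grid.values[round(r), round(c)])
    r0 = min(int(np.floor(r)), nrow - 2)
    c0 = min(int(np.floor(c)), ncol - 2)
    fr, fc = r - r0, c - c0
    v = grid.values
    z = (v[r0, c0] * (1 - fr) * (1 - fc)
         + v[r0 + 1, c0] * fr * (1 - fc)
         + v[r0, c0 + 1] * (1 - fr) * fc
         + v[r0 + 1, c0 + 1] * fr * fc)
    return float(z)


def annotate_track(
    track: Track,
    provider: ElevationProvider,
    policy: Literal["fill_missing", "override_all"] = "fill_missing",
) -> Track:
    """Return a new track with elevations from ``provider``.

    ``fill_missing`` touches only points whose elevation is absent;
    ``override_all`` replaces every elevation the provider covers. Points the
    provider cannot cover retain their prior elevation; if any point still
    lacks elevation afterwards an :class:`IncompleteElevationError` lists the
    indices, since slope cannot be computed for them.

    ``fill_missing`` is idempotent, and ``override_all`` followed by
    ``fill_missing`` equals ``override_all``.
    """
    if policy not in ("fill_missing", "override_all"):
        raise ParameterError(f"unknown annotation policy {policy!r}")
    new_points: list[TrackPoint] = []
    n_uncovered = 0
    missing: list[int] = []
    for i, p in enumerate(track.points):
        ele = p.elevation_m
        if policy == "override_all" or ele is None:
            looked = provider.lookup(p.lat, p.lon)
            if looked is None:
                n_uncovered += 1
            else:
                ele = looked
        if ele is None:
            missing.append(i)
        new_points.append(TrackPoint(p.timestamp, p.lat, p.lon, ele))
    if n_uncovered:
        logger.info("elevation provider did not cover %d of %d points",
                    n_uncovered, len(track.points))
    if missing:
        raise IncompleteElevationError(missing)
    return track.with_points(new_points)


def read_grid_csv(path: str | Path) -> ElevationGrid:
    """Load an :class:`ElevationGrid` from the plain-text dialect above."""
    lines = Path(path).read_text(encoding="utf-8").strip().splitlines()
    if len(lines) < 3:
        raise ParameterError(f"{path}: grid file needs a header, parameters, and value rows")
    header = [h.strip() for h in lines[0].split(",")]
    if header != ["origin_lat", "origin_lon", "cell_deg"]:
        raise ParameterError(f"{path}: first line must be 'origin_lat,origin_lon,cell_deg'")
    try:
        origin_lat, origin_lon, cell_deg = (float(x) for x in lines[1].split(","))
        values = np.array([[float(x) for x in line.split(",")] for line in lines[2:]])
    except ValueError as exc:
        raise ParameterError(f"{path}: unparseable grid value: {exc}") from exc
    return ElevationGrid(origin_lat, origin_lon, cell_deg, values)


def write_grid_csv(grid: ElevationGrid, path: str | Path) -> None:
    out = ["origin_lat,origin_lon,cell_deg",
           f"{grid.origin_lat!r},{grid.origin_lon!r},{grid.cell_deg!r}"]
    out += [",".join(repr(float(v)) for v in row) for row in grid.values]
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
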