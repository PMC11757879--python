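"""GPS track input/output.

Reads GPX 1.1 (topografix ``<trk>/<trkseg>/<trkpt>``) and plain CSV tracks,
writes CSV and GPX, and enforces track well-formedness (coordinate bounds,
timezone-resolved timestamps, non-decreasing time order).

Conventions
-----------
* Timestamps without a timezone designator are interpreted as UTC. GPX mandates
  UTC; for CSV a warning is logged when the offset had to be assumed.
* Only ``<trk>`` content is read; ``<rte>`` and ``<wpt>`` are ignored (the
  pipeline consumes a recorded activity, not a planned route). Multiple
  ``<trkseg>`` elements are concatenated in file order and the boundaries are
  logged.
* Duplicate consecutive timestamps are kept — zero-duration segments are
  dropped later by the kinematics stage, so parsing stays non-destructive.

CSV dialect: RFC 4180, UTF-8, header ``timestamp,lat,lon,elevation_m``
(``elevation`` accepted on read; the column may be absent or empty). Written
precision: 1e-7 degrees, 0.01 m, 1 ms — lossless round-trips at those
precisions, and a re-write of a just-read file is byte-stable.
"""

from __future__ import annotations

import csv
import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, Literal, Optional

from .errors import (
    EmptyTrackError,
    GPXParseError,
    OrderingError,
    ParameterError,
    SchemaError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrackPoint",
    "Track",
    "AthleteProfile",
    "read_gpx",
    "read_csv",
    "write_csv",
    "write_gpx",
]

_GPX_NS = "http://www.topografix.com/GPX/1/1"


def _parse_timestamp(text: str, *, assume_utc_warn: bool = False) -> datetime:
    """Parse an ISO 8601 timestamp; naive values are taken as UTC."""
    t = text.strip()
    if t.endswith(("Z", "z")):
        t = t[:-1] + "+00:00"
    try:
        dt = datetime.fromisoformat(t)
    except ValueError as exc:
        raise ParameterError(f"unparseable timestamp {text!r}") from exc
    if dt.tzinfo is None:
        if assume_utc_warn:
            logger.warning("timestamp %r has no UTC offset; assuming UTC", text)
        dt = dt.replace(tzinfo=timezone.utc)
    return dt


@dataclass(frozen=True)
class TrackPoint:
    """A single timestamped geodetic fix.

    ``elevation_m`` may be ``None`` until the track is annotated by an
    elevation provider.
    """

    timestamp: datetime
    lat: float
    lon: float
    elevation_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ParameterError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ParameterError(f"longitude {self.lon} outside [-180, 180]")
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))


@dataclass
class Track:
    """An ordered sequence of track points from one recording."""

    points: list[TrackPoint] = field(default_factory=list)
    name: str = ""
    source: Literal["gpx", "csv", "synthetic"] = "synthetic"

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self) -> Iterator[TrackPoint]:
        return iter(self.points)

    def validate_order(self) -> None:
        """Raise :class:`OrderingError` if timestamps ever decrease."""
        pts = self.points
        for i in range(1, len(pts)):
            if pts[i].timestamp < pts[i - 1].timestamp:
                raise OrderingError(i)

    def has_full_elevation(self) -> bool:
        return all(p.elevation_m is not None for p in self.points)

    def with_points(self, points: list[TrackPoint]) -> "Track":
        return replace(self, points=points)


@dataclass
class AthleteProfile:
    """Athlete body mass as worn (apparatus, shoes and gear included).

    Total oxygen volume and kilocalories scale with body mass; everything else
    in the pipeline is per-kilogram.
    """

    body_mass_kg: float
    id: str = ""

    def __post_init__(self) -> None:
        if not 20.0 < self.body_mass_kg < 300.0:
            raise ParameterError(f"body mass {self.body_mass_kg} kg outside plausible (20, 300)")
        if not 40.0 < self.body_mass_kg < 150.0:
            logger.warning("body mass %.1f kg outside typical (40, 150) range", self.body_mass_kg)


def _local(tag: str) -> str:
    """Strip an XML namespace from a tag name."""
    return tag.rsplit("}", 1)[-1]


def read_gpx(path: str | Path) -> Track:
    """Read the first ``<trk>`` of a GPX 1.1 file into a :class:`Track`.

    Points with a missing ``<time>`` are rejected (the pipeline needs
    durations); missing ``<ele>`` is allowed and left for elevation
    annotation.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise GPXParseError(f"{path}: malformed XML: {exc}") from exc

    root = tree.getroot()
    trk = next((el for el in root.iter() if _local(el.tag) == "trk"), None)
    if trk is None:
        raise EmptyTrackError(f"{path}: no <trk> element")

    name = ""
    points: list[TrackPoint] = []
    seg_starts: list[int] = []
    for el in trk:
        if _local(el.tag) == "name" and el.text:
            name = el.text.strip()
        elif _local(el.tag) == "trkseg":
            seg_starts.append(len(points))
            for pt in el:
                if _local(pt.tag) != "trkpt":
                    continue
                idx = len(points)
                try:
                    lat = float(pt.attrib["lat"])
                    lon = float(pt.attrib["lon"])
                except (KeyError, ValueError) as exc:
                    raise GPXParseError(f"{path}: trkpt {idx}: bad lat/lon attributes") from exc
                ele: Optional[float] = None
                time_text: Optional[str] = None
                for child in pt:
                    if _local(child.tag) == "ele" and child.text:
                        ele = float(child.text)
                    elif _local(child.tag) == "time" and child.text:
                        time_text = child.text
                if time_text is None:
                    raise GPXParseError(f"{path}: trkpt {idx} has no <time> element")
                points.append(TrackPoint(_parse_timestamp(time_text), lat, lon, ele))

    if not points:
        raise EmptyTrackError(f"{path}: track contains no trackpoints")
    if len(seg_starts) > 1:
        logger.info("%s: %d track segments concatenated (boundaries at indices %s)",
                    path, len(seg_starts), seg_starts[1:])

    track = Track(points=points, name=name or path.stem, source="gpx")
    track.validate_order()
    return track


_CSV_COLUMNS = ("timestamp", "lat", "lon", "elevation_m")


def read_csv(path: str | Path) -> Track:
    """Read a track from CSV with columns ``timestamp,lat,lon[,elevation_m]``."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        fields = [f.strip() for f in reader.fieldnames]
        ele_col = next((c for c in ("elevation_m", "elevation") if c in fields), None)
        missing = [c for c in ("timestamp", "lat", "lon") if c not in fields]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

        points: list[TrackPoint] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                ele_text = (row.get(ele_col) or "").strip() if ele_col else ""
                points.append(TrackPoint(
                    timestamp=_parse_timestamp(row["timestamp"], assume_utc_warn=True),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    elevation_m=float(ele_text) if ele_text else None,
                ))
            except (TypeError, ValueError, ParameterError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc

    if not points:
        raise EmptyTrackError(f"{path}: no data rows")
    track = Track(points=points, name=path.stem, source="csv")
    track.validate_order()
    return track


def _format_point(p: TrackPoint) -> list[str]:
    ts = p.timestamp.astimezone(timezone.utc).isoformat(timespec="milliseconds")
    ts = ts.replace("+00:00", "Z")
    return [
        ts,
        f"{p.lat:.7f}",
        f"{p.lon:.7f}",
        "" if p.elevation_m is None else f"{p.elevation_m:.2f}",
    ]


def write_csv(track: Track, path: str | Path) -> None:
    """Write a track as CSV, lossless to 1e-7 degrees / 0.01 m / 1 ms."""
    if not track.points:
        raise EmptyTrackError("refusing to write a track with no points")
    track.validate_order()
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for p in track.points:
            writer.writerow(_format_point(p))


def write_gpx(track: Track, path: str | Path) -> None:
    """Write a track as a minimal GPX 1.1 document (one trk, one trkseg)."""
    if not track.points:
        raise EmptyTrackError("refusing to write a track with no points")
    track.validate_order()
    buf = io.StringIO()
    buf.write('<?xml version="1.0" encoding="UTF-8"?>\n')
    buf.write(f'<gpx version="1.1" creator="trackmets" xmlns="{_GPX_NS}">\n')
    buf.write(" <trk>\n")
    if track.name:
        buf.write(f"  <name>{track.name}</name>\n")
    buf.write("  <trkseg>\n")
    for p in track.points:
        ts, lat, lon, ele = _format_point(p)
        buf.write(f'   <trkpt lat="{lat}" lon="{lon}">\n')
        if ele:
            buf.write(f"    <ele>{ele}</ele>\n")
        buf.write(f"    <time>{ts}</time>\n")
        buf.write("   </trkpt>\n")
    buf.write("  </trkseg>\n </trk>\n</gpx>\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
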