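from datetime import datetime, timedelta, timezone

import pytest

from trackmets import Track, TrackPoint, table2_fixture

T0 = datetime(2024, 1, 1, tzinfo=timezone.utc)


def make_track(rows, name="test", source="synthetic"):
    """Build a Track from (seconds, lat, lon, ele) tuples."""
    pts = [TrackPoint(T0 + timedelta(seconds=s), lat, lon, ele) for s, lat, lon, ele in rows]
    return Track(points=pts, name=name, source=source)


@pytest.fixture
def table2():
    return table2_fixture()


@pytest.fixture
def gpx_text():
    return """<?xml version="1.0" encoding="UTF-8"?>
<gpx version="1.1" creator="unit-test" xmlns="http://www.topografix.com/GPX/1/1">
 <trk><name>loop</name><trkseg>
  <trkpt lat="35.0000000" lon="139.0000000"><ele>100.00</ele><time>2024-01-01T00:00:00Z</time></trkpt>
  <trkpt lat="35.0000300" lon="139.0000000"><ele>100.50</ele><time>2024-01-01T00:00:01Z</time></trkpt>
  <trkpt lat="35.0000600" lon="139.0000000"><ele>101.00</ele><time>2024-01-01T00:00:02Z</time></trkpt>
 </trkseg></trk>
</gpx>
"""
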