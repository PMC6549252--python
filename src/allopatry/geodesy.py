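"""Degree/decimal-minute coordinate parsing and great-circle distance matrices.

Sampling-site coordinates for geothermal isolates are conventionally reported
as hemisphere-prefixed degrees and decimal minutes, e.g. ``N63°53.278′W022°03.405′``.
This module converts them to decimal degrees and builds pairwise great-circle
distance matrices on a sphere of mean Earth radius R = 6371.0088 km (haversine
formula).  Spherical distances differ from ellipsoidal geodesics by well under
0.5 %, which is immaterial for matrices spanning thousands of kilometres.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0088
"""IUGG mean Earth radius, km."""

MAX_DISTANCE_KM = math.pi * EARTH_RADIUS_KM
"""Antipodal (maximum possible) great-circle distance."""


class CoordinateError(ValueError):
    """Raised when a coordinate string cannot be parsed or is out of range."""


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere in decimal degrees.

    lat is restricted to [-90, 90]; lon is normalized to (-180, 180].
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise CoordinateError(f"non-finite coordinate ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise CoordinateError(f"latitude {self.lat} outside [-90, 90]")
        lon = self.lon
        # normalize into (-180, 180]
        lon = ((lon + 180.0) % 360.0) - 180.0
        if lon == -180.0:
            lon = 180.0
        object.__setattr__(self, "lon", lon)


# hemisphere, integer degrees (leading zeros allowed), decimal minutes, prime or apostrophe
_HALF = r"([NSEW])\s*(\d{1,3})°\s*(\d{1,2}(?:\.\d+)?)\s*[′']"
_COORD_RE = re.compile(rf"^\s*{_HALF}\s*{_HALF}\s*$")


def parse_coordinate(text: str) -> GeoPoint:
    """Parse ``<N|S>deg°min′<E|W>deg°min′`` into decimal degrees.

    Decimal degrees = degrees + minutes/60; S and W hemispheres negate.
    The latitude half must come first.  ASCII apostrophes are accepted in
    place of the prime mark, and leading zeros (``W025°…``) are fine.

    Raises
    ------
    CoordinateError
        If the string does not match the format, minutes are >= 60, the
        hemisphere letters are wrong, or degrees are out of range.
    """
    m = _COORD_RE.match(text)
    if m is None:
        raise CoordinateError(
            f"cannot parse coordinate {text!r}: expected form like N37°46.385′W025°18.21′"
        )
    h1, d1, m1, h2, d2, m2 = m.groups()
    if h1 not in "NS":
        raise CoordinateError(f"coordinate {text!r}: first half must be N or S, got {h1!r}")
    if h2 not in "EW":
        raise CoordinateError(f"coordinate {text!r}: second half must be E or W, got {h2!r}")

    def half(deg_s: str, min_s: str, hemi: str, limit: int, token: str) -> float:
        deg = int(deg_s)
        minutes = float(min_s)
        if minutes >= 60.0:
            raise CoordinateError(f"coordinate {text!r}: minutes {minutes} >= 60 in {token!r}")
        value = deg + minutes / 60.0
        if value > limit:
            raise CoordinateError(f"coordinate {text!r}: {value}° exceeds {limit}° in {token!r}")
        return -value if hemi in "SW" else value

    lat = half(d1, m1, h1, 90, f"{h1}{d1}°{m1}′")
    lon = half(d2, m2, h2, 180, f"{h2}{d2}°{m2}′")
    return GeoPoint(lat=lat, lon=lon)


def format_coordinate(point: GeoPoint, min_decimals: int = 6) -> str:
    """Format a GeoPoint back to degree/decimal-minute notation."""

    def half(value: float, pos: str, neg: str, deg_width: int) -> str:
        hemi = pos if value >= 0 else neg
        value = abs(value)
        deg = int(value)
        minutes = (value - deg) * 60.0
        if round(minutes, min_decimals) >= 60.0:  # carry from rounding
            deg += 1
            minutes = 0.0
        return f"{hemi}{deg:0{deg_width}d}°{minutes:.{min_decimals}f}′"

    return half(point.lat, "N", "S", 2) + half(point.lon, "E", "W", 3)


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance in km on a sphere of radius R=6371.0088 km.

    Symmetric, zero for identical points, bounded by pi*R.  The haversine
    argument is clamped into [0, 1] so antipodal/rounding edge cases stay finite.
    """
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    s_lat = math.sin((la2 - la1) / 2.0)
    s_lon = math.sin((lo2 - lo1) / 2.0)
    h = s_lat * s_lat + math.cos(la1) * math.cos(la2) * s_lon * s_lon
    h = min(1.0, max(0.0, h))
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def geographic_distance_matrix(sites) -> "LabeledMatrix":  # noqa: F821
    """Pairwise great-circle distance matrix (km) for a site table.

    Every requested site must carry coordinates; sites without them are
    reported by name in a single error rather than silently dropped.
    """
    from .fixtures_io import LabeledMatrix  # cycle: fixtures_io uses parse_coordinate

    records = list(sites)
    missing = [r.name for r in records if r.lat is None or r.lon is None]
    if missing:
        raise CoordinateError(
            "sites lacking coordinates cannot enter the geographic matrix: "
            + ", ".join(missing)
        )
    if len(records) < 2:
        raise ValueError("need at least 2 sites for a distance matrix")
    points = [GeoPoint(r.lat, r.lon) for r in records]
    n = len(points)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = great_circle_km(points[i], points[j])
            values[i, j] = values[j, i] = d
    return LabeledMatrix([r.name for r in records], values, kind="distance_km")
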