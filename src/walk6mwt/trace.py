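"""Trace data model, geodesic primitives and 1 Hz resampling.

A six-minute-walk-test recording is an ordered time series of GNSS fixes.
Each fix carries position (latitude, longitude, altitude), the horizontal
accuracy radius reported by the phone's operating system ("confidence
interval"), and optional heading, travelling speed, cumulative step count
and mean acceleration magnitude over the preceding second.

Distances use a spherical Earth of radius 6 371 000 m; planar math
(tracking filters, turning angles) runs in a local east-north-up frame
obtained by equirectangular projection about the first fix, which is
accurate to well under 0.1 % at walk scale (< 2 km).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

PATH_TYPES = (
    "regular",
    "stop_and_go",
    "back_and_forth",
    "circles0",
    "circles1",
    "circles2",
    "circles3",
    "unknown",
)
LABELS = ("conventional", "unconventional", "unknown")

#: path types a walker following the app instructions may produce
CONVENTIONAL_PATH_TYPES = ("regular", "stop_and_go")


@dataclass(frozen=True)
class GnssSample:
    """One positioning record with its quality channels.

    Parameters
    ----------
    t : float
        Timestamp in seconds since an arbitrary epoch. Monotonicity is
        intended but not guaranteed in raw data.
    lat, lon : float
        Position in degrees; validated against [-90, 90] / [-180, 180].
    alt : float or None
        Altitude in meters; ``None`` when the fix was not computed from
        satellites (cell/WiFi positioning omits altitude).
    acc : float
        Horizontal accuracy (confidence-interval) radius in meters, >= 0.
    heading : float or None
        Direction the device faces, degrees clockwise from north in
        [0, 360).
    speed : float or None
        Travelling speed in m/s, >= 0.
    steps : int or None
        Cumulative step count. Raw recordings may violate monotonicity.
    accel_mag : float or None
        Mean acceleration magnitude over the preceding second, m/s^2.
    """

    t: float
    lat: float
    lon: float
    alt: Optional[float] = None
    acc: float = 0.0
    heading: Optional[float] = None
    speed: Optional[float] = None
    steps: Optional[int] = None
    accel_mag: Optional[float] = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.acc < 0:
            raise ValueError(f"accuracy radius {self.acc} must be >= 0")
        if self.speed is not None and self.speed < 0:
            raise ValueError(f"speed {self.speed} must be >= 0")
        if self.steps is not None and self.steps < 0:
            raise ValueError(f"steps {self.steps} must be >= 0")
        if self.heading is not None and not 0.0 <= self.heading < 360.0:
            object.__setattr__(self, "heading", self.heading % 360.0)


@dataclass
class WalkTrace:
    """An ordered sequence of GNSS samples plus test metadata."""

    samples: list[GnssSample]
    participant_id: str = ""
    path_type: str = "unknown"
    label: str = "unknown"
    reference_distance_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.path_type not in PATH_TYPES:
            raise ValueError(f"unknown path_type {self.path_type!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        if len(self.samples) < 2:
            return 0.0
        return self.samples[-1].t - self.samples[0].t

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    def latlon(self) -> np.ndarray:
        """(n, 2) array of latitude, longitude in degrees."""
        return np.array([[s.lat, s.lon] for s in self.samples], dtype=float)

    def with_samples(self, samples: Sequence[GnssSample]) -> "WalkTrace":
        return replace(self, samples=list(samples))


@dataclass(frozen=True)
class EnuPoint:
    """Planar point in meters east (x) and north (y) of the trace origin."""

    x: float
    y: float


def haversine_m(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in meters between two (lat, lon) pairs."""
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            raise ValueError(f"coordinate ({lat}, {lon}) out of range")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


def path_length_m(latlon: np.ndarray) -> float:
    """Sum of consecutive great-circle distances along an (n, 2) lat/lon array."""
    latlon = np.asarray(latlon, dtype=float)
    if latlon.ndim != 2 or latlon.shape[0] < 2:
        return 0.0
    lat = np.radians(latlon[:, 0])
    lon = np.radians(latlon[:, 1])
    dphi = np.diff(lat)
    dlam = np.diff(lon)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(dlam / 2.0) ** 2
    return float(np.sum(2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))))


def bearing_deg(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Initial great-circle bearing from ``a`` to ``b``, degrees in [0, 360).

    North = 0, east = 90. Used as a positional fallback when the GNSS
    heading channel is absent. Raises for coincident points, where the
    bearing is undefined.
    """
    if a == b:
        raise ValueError("bearing undefined for coincident points")
    lat1, lon1 = map(math.radians, a)
    lat2, lon2 = map(math.radians, b)
    dlam = lon2 - lon1
    y = math.sin(dlam) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlam)
    return math.degrees(math.atan2(y, x)) % 360.0


def to_enu(trace: WalkTrace) -> list[EnuPoint]:
    """Project a trace to a local east-north frame about its first sample.

    Equirectangular: x = R * dlon_rad * cos(lat0), y = R * dlat_rad.
    The first sample maps to (0, 0).
    """
    if len(trace) == 0:
        raise ValueError("cannot project an empty trace")
    xy = latlon_to_enu(trace.latlon())
    return [EnuPoint(float(x), float(y)) for x, y in xy]


def latlon_to_enu(latlon: np.ndarray, origin: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Vectorized equirectangular projection; returns (n, 2) meters (x east, y north)."""
    latlon = np.asarray(latlon, dtype=float)
    if origin is None:
        origin = (latlon[0, 0], latlon[0, 1])
    lat0, lon0 = origin
    coslat0 = math.cos(math.radians(lat0))
    x = EARTH_RADIUS_M * np.radians(latlon[:, 1] - lon0) * coslat0
    y = EARTH_RADIUS_M * np.radians(latlon[:, 0] - lat0)
    return np.column_stack([x, y])


def enu_to_latlon(xy: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    """Inverse of :func:`latlon_to_enu` about ``origin`` (lat, lon degrees)."""
    xy = np.asarray(xy, dtype=float)
    lat0, lon0 = origin
    coslat0 = math.cos(math.radians(lat0))
    lat = lat0 + np.degrees(xy[:, 1] / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(xy[:, 0] / (EARTH_RADIUS_M * coslat0))
    return np.column_stack([lat, lon])


def _interp_channel(
    t0: float, t1: float, v0: Optional[float], v1: Optional[float], tg: float, max_gap_s: float
) -> Optional[float]:
    # linear across short gaps, hold-last across long ones
    if v0 is None:
        return v1 if t1 - t0 <= max_gap_s else None
    if v1 is None or t1 - t0 > max_gap_s or t1 == t0:
        return v0
    w = (tg - t0) / (t1 - t0)
    return v0 + w * (v1 - v0)


def resample_1hz(trace: WalkTrace, max_gap_s: float = 5.0) -> WalkTrace:
    """Resample a trace onto an integer-second 1 Hz grid.

    Positions (and altitude) are linearly interpolated across gaps up to
    ``max_gap_s`` and held at the last value across longer gaps (missing
    stretches are padded). The accuracy radius at a grid point is the
    pessimistic maximum of the two bracketing raw values. Heading is
    recomputed from consecutive grid positions and speed as grid-step
    distance over 1 s, because neither channel survives interpolation
    across the 0/360 wrap or irregular sampling.

    Raises if timestamps are not strictly increasing; run the exclusion
    filters first.
    """
    if len(trace) < 2:
        raise ValueError("resampling needs at least 2 samples")
    t = trace.times()
    if np.any(np.diff(t) <= 0):
        raise ValueError(
            "timestamps not strictly increasing; apply exclusion filters before resampling"
        )
    t_start = math.ceil(t[0])
    t_end = math.floor(t[-1])
    if t_end < t_start:
        raise ValueError("trace shorter than one second of grid")
    grid = np.arange(t_start, t_end + 1, dtype=float)

    samples = trace.samples
    out: list[GnssSample] = []
    j = 0
    for tg in grid:
        while j + 1 < len(samples) and samples[j + 1].t <= tg:
            j += 1
        s0 = samples[j]
        s1 = samples[min(j + 1, len(samples) - 1)]
        gap = s1.t - s0.t
        if gap > 0 and gap <= max_gap_s:
            w = (tg - s0.t) / gap
            lat = s0.lat + w * (s1.lat - s0.lat)
            lon = s0.lon + w * (s1.lon - s0.lon)
        else:  # long gap (or at the end): pad with the last value
            lat, lon = s0.lat, s0.lon
        alt = _interp_channel(s0.t, s1.t, s0.alt, s1.alt, tg, max_gap_s)
        acc = max(s0.acc, s1.acc) if gap > 0 else s0.acc
        accel = _interp_channel(s0.t, s1.t, s0.accel_mag, s1.accel_mag, tg, max_gap_s)
        stp = _interp_channel(
            s0.t,
            s1.t,
            None if s0.steps is None else float(s0.steps),
            None if s1.steps is None else float(s1.steps),
            tg,
            max_gap_s,
        )
        out.append(
            GnssSample(
                t=float(tg),
                lat=float(lat),
                lon=float(lon),
                alt=None if alt is None else float(alt),
                acc=float(acc),
                heading=None,
                speed=None,
                steps=None if stp is None else int(round(stp)),
                accel_mag=None if accel is None else float(accel),
            )
        )

    # recompute heading and speed on the grid
    final: list[GnssSample] = []
    prev_heading: Optional[float] = None
    for i, s in enumerate(out):
        if i + 1 < len(out):
            nxt = out[i + 1]
            a, b = (s.lat, s.lon), (nxt.lat, nxt.lon)
            heading = bearing_deg(a, b) if a != b else prev_heading
        else:
            heading = prev_heading
        if i > 0:
            speed = haversine_m((out[i - 1].lat, out[i - 1].lon), (s.lat, s.lon)) / 1.0
        else:
            speed = None
        final.append(replace(s, heading=heading, speed=speed))
        prev_heading = heading
    if len(final) >= 2 and final[0].speed is None:
        final[0] = replace(final[0], speed=final[1].speed)
    return trace.with_samples(final)
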