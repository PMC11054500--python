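"""The 52-element signal-quality feature vector of a walk trace.

Seven characteristic series are derived from the filtered trace:

====================  ========================================================
curve                 turning angle at each interior fix (degrees, 0 = straight)
crows                 consecutive great-circle distances (m)
speed                 GNSS speed channel, positional fallback distance/dt (m/s)
quality               reported accuracy radius (m)
heading               GNSS heading channel, positional bearing fallback (deg)
deltaheading          circular difference of consecutive headings, (-180, 180]
fs                    timestamp deltas (s)
====================  ========================================================

Each series contributes seven statistics — mean, median, standard
deviation, IQR, autocorrelation first-peak value and lag, and sample
entropy — for a 49-feature grid. Three summative features complete the
vector: the percentage of fixes with accuracy radius above 15 m
(q_above_tr), the percentage with speed above 4 m/s (s_above_tr), and the
difference between the unfiltered and filtered baseline distance
(delta_distance), which flags traces where the exclusion rules removed
path-inflating noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .estimators import distance_baseline
from .trace import WalkTrace, bearing_deg, latlon_to_enu

logger = logging.getLogger(__name__)

CHARACTERISTICS = ("curve", "crows", "speed", "quality", "heading", "deltaheading", "fs")
STATS = ("mean", "median", "std", "iqr", "ac1_value", "ac1_lag", "sampen")
SUMMATIVE = ("q_above_tr", "s_above_tr", "delta_distance")

#: the 52 feature names, in stable order
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{c}_{s}" for c in CHARACTERISTICS for s in STATS
) + SUMMATIVE

ACCURACY_THRESHOLD_M = 15.0
SPEED_THRESHOLD_MPS = 4.0


def curviness_series(points: np.ndarray) -> np.ndarray:
    """Turning angle at each interior point of a planar polyline, degrees.

    0 means collinear (straight walking), 180 an immediate U-turn.
    Repeated points contribute 0. Returns an empty array below 3 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return np.empty(0)
    v1 = pts[1:-1] - pts[:-2]
    v2 = pts[2:] - pts[1:-1]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    cosang = np.zeros(len(v1))
    dot = np.einsum("ij,ij->i", v1, v2)
    cosang[ok] = np.clip(dot[ok] / (n1[ok] * n2[ok]), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[~ok] = 0.0
    return ang


def delta_heading_series(headings: np.ndarray) -> np.ndarray:
    """Consecutive heading differences wrapped to (-180, 180] degrees."""
    h = np.asarray(headings, dtype=float)
    if h.size < 2:
        return np.empty(0)
    d = np.diff(h)
    d = -((-d + 180.0) % 360.0 - 180.0)  # maps to (-180, 180]
    return d


def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    ``r`` defaults to 0.2 times the series standard deviation. A constant
    series has entropy 0 by convention. When no template of length m + 1
    matches (A = 0) the value is capped at ln(B) + ln(10) so downstream
    statistics stay finite.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for SampEn with m={m}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        d = cdist(templ, templ, metric="chebyshev")
        return int(((d <= r).sum() - templ.shape[0]) // 2)

    B = _count(m)
    A = _count(m + 1)
    if B == 0:
        return 0.0
    if A == 0:
        return math.log(B) + math.log(10.0)
    return -math.log(A / B)


def autocorr_first_peak(series: np.ndarray) -> tuple[float, int]:
    """Value and lag of the first local maximum of the autocorrelation.

    Biased normalized autocorrelation over lags 1..n//2; the first lag
    whose value strictly exceeds the previous lag's and is >= the next
    counts as the peak. Zero-variance or too-short series, or no peak,
    give (0, 0).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 3:
        return 0.0, 0
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0, 0
    full = np.correlate(xc, xc, mode="full")[n - 1 :] / denom  # lags 0..n-1
    max_lag = n // 2
    ac = full[: max_lag + 1]
    for lag in range(2, max_lag):
        if ac[lag] > ac[lag - 1] and ac[lag] >= ac[lag + 1]:
            return float(ac[lag]), lag
    return 0.0, 0


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def _series_stats(name: str, x: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    if x.size == 0:
        logger.warning("series %s empty; its statistics are set to 0", name)
        return {f"{name}_{s}": 0.0 for s in STATS}
    out[f"{name}_mean"] = float(np.mean(x))
    out[f"{name}_median"] = float(np.median(x))
    out[f"{name}_std"] = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    out[f"{name}_iqr"] = _iqr(x)
    v, lag = autocorr_first_peak(x)
    out[f"{name}_ac1_value"] = v
    out[f"{name}_ac1_lag"] = float(lag)
    try:
        out[f"{name}_sampen"] = sample_entropy(x)
    except ValueError:
        logger.warning("series %s too short for sample entropy; set to 0", name)
        out[f"{name}_sampen"] = 0.0
    return out


def _speed_series(trace: WalkTrace) -> np.ndarray:
    vals = []
    samples = trace.samples
    for i, s in enumerate(samples):
        if s.speed is not None:
            vals.append(s.speed)
        elif i > 0:
            dt = s.t - samples[i - 1].t
            if dt > 0:
                from .trace import haversine_m

                vals.append(haversine_m((samples[i - 1].lat, samples[i - 1].lon), (s.lat, s.lon)) / dt)
    return np.asarray(vals, dtype=float)


def _heading_series(trace: WalkTrace) -> np.ndarray:
    vals = []
    samples = trace.samples
    for i, s in enumerate(samples):
        if s.heading is not None:
            vals.append(s.heading)
        elif i > 0:
            a = (samples[i - 1].lat, samples[i - 1].lon)
            b = (s.lat, s.lon)
            if a != b:
                vals.append(bearing_deg(a, b))
    return np.asarray(vals, dtype=float)


@dataclass(frozen=True)
class FeatureVector:
    """Named, ordered mapping of the 52 quality features of one trace."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError("feature vector must hold exactly the 52 named features in order")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES])


def extract_features(filtered: WalkTrace, unfiltered: WalkTrace) -> FeatureVector:
    """Compute the 52 quality features of a trace.

    Characteristic series come from the filtered trace; delta_distance
    compares baseline distances of the unfiltered and filtered traces.
    """
    if len(filtered) == 0 or len(unfiltered) == 0:
        raise ValueError("both filtered and unfiltered traces must be non-empty")
    latlon = filtered.latlon()
    xy = latlon_to_enu(latlon)
    t = filtered.times()

    lat = np.radians(latlon[:, 0])
    lon = np.radians(latlon[:, 1])
    if latlon.shape[0] >= 2:
        from .trace import EARTH_RADIUS_M

        dphi = np.diff(lat)
        dlam = np.diff(lon)
        h = np.sin(dphi / 2) ** 2 + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(dlam / 2) ** 2
        crows = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        crows = np.empty(0)

    series = {
        "curve": curviness_series(xy),
        "crows": crows,
        "speed": _speed_series(filtered),
        "quality": np.array([s.acc for s in filtered.samples], dtype=float),
        "heading": _heading_series(filtered),
        "fs": np.diff(t) if t.size >= 2 else np.empty(0),
    }
    series["deltaheading"] = delta_heading_series(series["heading"])

    values: dict[str, float] = {}
    for c in CHARACTERISTICS:
        values.update(_series_stats(c, series[c]))

    quality = series["quality"]
    speed = series["speed"]
    values["q_above_tr"] = (
        100.0 * float(np.mean(quality > ACCURACY_THRESHOLD_M)) if quality.size else 0.0
    )
    values["s_above_tr"] = (
        100.0 * float(np.mean(speed > SPEED_THRESHOLD_MPS)) if speed.size else 0.0
    )
    values["delta_distance"] = (
        distance_baseline(unfiltered).distance_m - distance_baseline(filtered).distance_m
    )
    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(ordered)
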