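"""Behavior-context features from smartwatch and ambient smart-home streams.

Three digital markers give context to each EMA prompt, all computed over the
30-minute window ending at the prompt (or response) time:

* **activity level** — per-minute-normalized total acceleration magnitude
  from the watch, or the count of motion-sensor firings in the ambient
  protocol;
* **at-home fraction** — fraction of the window spent at home.  Home is
  inferred from GPS as the modal night-time (2 AM – 9 AM) location on an
  ~11 m grid; in the ambient protocol a participant is out of home after an
  external door opens and closes followed by at least 5 minutes without
  motion events;
* **change-point nearness** — ``exp(-Δ/τ)`` where Δ is the time to the
  nearest detected activity change point.  Change points (shifts in the
  underlying level of the activity series, a proxy for transitions between
  activities) are found by exact penalized least-squares mean-shift
  segmentation (PELT search).

A feature that cannot be computed (no sensor coverage) is reported as the
NaN sentinel :data:`CONTEXT_UNAVAILABLE` and dropped pairwise from
correlations downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXT_UNAVAILABLE",
    "EARTH_RADIUS_M",
    "HomeLocation",
    "ContextFeatures",
    "AmbientEvents",
    "HomeUndeterminableError",
    "infer_home",
    "distance_bearing",
    "at_home_fraction",
    "at_home_fraction_ambient",
    "activity_level_watch",
    "activity_level_ambient",
    "out_of_home_intervals",
    "detect_change_points",
    "pelt_mean_shift",
    "default_penalty",
    "cp_nearness",
    "read_accel_stream",
    "read_location_stream",
    "read_ambient_stream",
]

#: Sentinel for "context unavailable": excluded pairwise from correlations.
CONTEXT_UNAVAILABLE = float("nan")

EARTH_RADIUS_M = 6_371_000.0

#: Spatial snap grid for the home vote, in degrees (~11 m at mid latitudes).
HOME_GRID_DEG = 1e-4
#: Radius within which a location fix counts as "at home" (meters).
HOME_RADIUS_M = 50.0
#: Night window used for home inference (clock hours, half-open).
NIGHT_WINDOW = (2, 9)
#: Context window length (minutes).
WINDOW_MIN = 30.0
#: Maximum staleness for carrying the last fix into an uncovered window.
MAX_STALE_MIN = 120.0


class HomeUndeterminableError(ValueError):
    """Raised when no night-window location fixes exist to vote for a home."""


@dataclass(frozen=True)
class HomeLocation:
    latitude: float
    longitude: float
    support_count: int

    def __post_init__(self) -> None:
        if self.support_count < 1:
            raise ValueError("support_count must be >= 1")


@dataclass(frozen=True)
class ContextFeatures:
    """The three behavior-context markers for one window ending at a prompt."""

    at_time: object
    activity_level: float
    at_home_fraction: float
    cp_nearness: float
    window_minutes: float = WINDOW_MIN


@dataclass
class AmbientEvents:
    """Column-oriented ambient smart-home event stream (sorted by time)."""

    times: np.ndarray  # epoch seconds, float
    kinds: np.ndarray  # "motion" | "door"
    states: np.ndarray  # "on"/"off" (motion), "open"/"closed" (door)
    sensor_ids: np.ndarray

    def motion_on_times(self) -> np.ndarray:
        mask = (self.kinds == "motion") & (self.states == "on")
        return self.times[mask]


def _epoch_s(t) -> float:
    """Scalar time (datetime, datetime64, or numeric seconds) → float seconds."""
    if isinstance(t, (int, float, np.floating, np.integer)):
        return float(t)
    return float(pd.Timestamp(t).value) / 1e9


def _epoch_s_array(times) -> np.ndarray:
    arr = np.asarray(times)
    if arr.dtype.kind in "Mm" or arr.dtype == object:
        return pd.to_datetime(pd.Series(arr)).astype("int64").to_numpy() / 1e9
    return arr.astype(float)


def infer_home(times, lat, lon) -> HomeLocation:
    """Infer home as the modal night-time (2 AM – 9 AM) location.

    Fixes in the night window are snapped to a grid of
    :data:`HOME_GRID_DEG` degrees (~11 m); the cell with the most fixes wins
    (ties broken toward the south-west cell, so the result does not depend on
    input order) and the returned coordinate is the centroid of that cell's
    fixes.
    """
    ts = pd.to_datetime(pd.Series(np.asarray(times)))
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    hours = ts.dt.hour.to_numpy()
    night = (hours >= NIGHT_WINDOW[0]) & (hours < NIGHT_WINDOW[1])
    if not night.any():
        raise HomeUndeterminableError(
            "no location fixes between 2 AM and 9 AM; home undeterminable"
        )
    glat = np.round(lat[night] / HOME_GRID_DEG).astype(np.int64)
    glon = np.round(lon[night] / HOME_GRID_DEG).astype(np.int64)
    cells = np.stack([glat, glon], axis=1)
    uniq, inverse, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
    best = np.lexsort((uniq[:, 1], uniq[:, 0], -counts))[0]
    sel = inverse == best
    # sort before averaging so the centroid is exactly order-invariant
    return HomeLocation(
        latitude=float(np.sort(lat[night][sel]).mean()),
        longitude=float(np.sort(lon[night][sel]).mean()),
        support_count=int(counts[best]),
    )


def distance_bearing(lat1, lon1, lat2, lon2):
    """Great-circle distance (m) and initial bearing (degrees in [0, 360)).

    Haversine formula on a sphere of radius :data:`EARTH_RADIUS_M`; the
    bearing is measured clockwise from true north and defined as 0 for
    coincident points.  Accepts scalars or arrays (broadcast).
    """
    p1, l1, p2, l2 = (np.radians(np.asarray(x, float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    dist = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    theta = np.arctan2(
        np.sin(dlam) * np.cos(p2),
        np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam),
    )
    bearing = np.where(dist > 0, np.degrees(theta) % 360.0, 0.0)
    if np.ndim(dist) == 0:
        return float(dist), float(bearing)
    return dist, bearing


def at_home_fraction(
    fix_times,
    lat,
    lon,
    home: HomeLocation,
    t,
    radius_m: float = HOME_RADIUS_M,
    window_min: float = WINDOW_MIN,
    max_stale_min: float = MAX_STALE_MIN,
) -> float:
    """Fraction of the window ``(t - window, t]`` spent at home.

    Each inter-fix interval inside the window is labeled "home" iff its
    starting fix lies within ``radius_m`` of home; the last fix's label is
    carried forward to ``t``.  When no fix falls inside the window, the last
    fix before it is carried forward, up to ``max_stale_min`` minutes of
    staleness.  Returns :data:`CONTEXT_UNAVAILABLE` if no usable fix exists
    at or before ``t``.
    """
    ft = _epoch_s_array(fix_times)
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    t_s = _epoch_s(t)
    t0 = t_s - window_min * 60.0
    hi = np.searchsorted(ft, t_s, side="right")
    lo = np.searchsorted(ft, t0, side="right")  # first fix strictly inside window
    if hi == 0:
        return CONTEXT_UNAVAILABLE
    start = lo
    if lo > 0:
        start = lo - 1  # carry the last pre-window fix forward
        if lo == hi and (t0 - ft[lo - 1]) > max_stale_min * 60.0:
            return CONTEXT_UNAVAILABLE
    if start == hi:
        return CONTEXT_UNAVAILABLE
    times = np.clip(ft[start:hi], t0, t_s)
    d, _ = distance_bearing(lat[start:hi], lon[start:hi], home.latitude, home.longitude)
    is_home = np.atleast_1d(d) <= radius_m
    edges = np.append(times, t_s)
    durations = np.diff(edges)
    covered = durations.sum()
    if covered <= 0:
        # single fix exactly at t: label the instant by that fix
        return 1.0 if bool(np.atleast_1d(is_home)[-1]) else 0.0
    return float(durations[is_home].sum() / covered)


def at_home_fraction_ambient(
    away_intervals: Sequence[tuple], t, window_min: float = WINDOW_MIN
) -> float:
    """At-home fraction in ``(t - window, t]`` given out-of-home intervals."""
    t_s = _epoch_s(t)
    t0 = t_s - window_min * 60.0
    away = 0.0
    for a, b in away_intervals:
        a_s, b_s = max(_epoch_s(a), t0), min(_epoch_s(b), t_s)
        if b_s > a_s:
            away += b_s - a_s
    return 1.0 - away / (window_min * 60.0)


def activity_level_watch(
    sample_times, magnitudes, t, window_min: float = WINDOW_MIN
) -> float:
    """Per-minute-normalized total acceleration over ``(t - window, t]``.

    The sum of acceleration magnitudes in the window divided by the window
    length in minutes, which makes streams sampled at different rates
    comparable once each is normalized the same way.  Returns 0.0 when the
    stream covers the window but no sample falls inside, and
    :data:`CONTEXT_UNAVAILABLE` when the stream does not cover the window.
    """
    st = _epoch_s_array(sample_times)
    mag = np.asarray(magnitudes, float)
    t_s = _epoch_s(t)
    t0 = t_s - window_min * 60.0
    lo = np.searchsorted(st, t0, side="right")
    hi = np.searchsorted(st, t_s, side="right")
    if hi == lo:
        covers = lo > 0 and hi < len(st)
        return 0.0 if covers else CONTEXT_UNAVAILABLE
    return float(mag[lo:hi].sum() / window_min)


def activity_level_ambient(events: AmbientEvents, t, window_min: float = WINDOW_MIN) -> float:
    """Count of motion-sensor firings ("on" events) in ``(t - window, t]``."""
    mt = events.motion_on_times()
    t_s = _epoch_s(t)
    lo = np.searchsorted(mt, t_s - window_min * 60.0, side="right")
    hi = np.searchsorted(mt, t_s, side="right")
    return float(hi - lo)


def out_of_home_intervals(
    events: AmbientEvents, min_quiet_min: float = 5.0
) -> list[tuple[float, float]]:
    """Out-of-home intervals from door and motion events.

    An away interval opens when an external door is opened and closed and at
    least ``min_quiet_min`` minutes pass with no motion events; it runs from
    the door close to the next motion event (or the end of the stream, with
    a warning).  Intervals are disjoint and never cover a motion event.
    """
    order = np.argsort(events.times, kind="stable")
    times = events.times[order]
    kinds = events.kinds[order]
    states = events.states[order]
    motion_times = times[(kinds == "motion") & (states == "on")]
    door_idx = np.flatnonzero(kinds == "door")
    intervals: list[tuple[float, float]] = []
    stream_end = times[-1] if len(times) else None
    i = 0
    last_end = -np.inf
    while i < len(door_idx):
        j = door_idx[i]
        if states[j] != "open":
            i += 1
            continue
        # find matching close on the same sensor
        close = None
        for k in door_idx[i + 1:]:
            if states[k] == "closed":
                close = times[k]
                break
        if close is None:
            warnings.warn(
                "unmatched door open; treating the open time as departure",
                stacklevel=2,
            )
            close = times[j]
        if close < last_end:
            i += 1
            continue
        nxt = np.searchsorted(motion_times, close, side="right")
        next_motion = motion_times[nxt] if nxt < len(motion_times) else None
        quiet_s = min_quiet_min * 60.0
        if next_motion is None:
            if stream_end - close >= quiet_s:
                warnings.warn(
                    "away interval closed at stream end (no return motion)",
                    stacklevel=2,
                )
                intervals.append((close, stream_end))
                last_end = stream_end
        elif next_motion - close >= quiet_s:
            intervals.append((close, next_motion))
            last_end = next_motion
        i += 1
    return intervals


def default_penalty(x: np.ndarray) -> float:
    """Default segmentation penalty ``3·log(n)·var̂``.

    The noise variance is estimated robustly from first differences
    (median absolute difference scaled for Gaussian noise) so that the level
    shifts being sought do not inflate the estimate.
    """
    x = np.asarray(x, float)
    n = len(x)
    diffs = np.abs(np.diff(x))
    sigma = 1.4826 * np.median(diffs) / math.sqrt(2.0)
    var = max(sigma * sigma, 1e-12)
    return 3.0 * math.log(max(n, 2)) * var


_pelt_jit = None


def _jit_kernel():
    """Lazily compile the PELT inner loop with numba when available."""
    global _pelt_jit
    if _pelt_jit is not None:
        return _pelt_jit
    try:
        import numba
    except ImportError:
        _pelt_jit = False
        return _pelt_jit

    @numba.njit(cache=False)
    def kernel(x, penalty):  # pragma: no cover - numerically identical to numpy path
        n = x.shape[0]
        cs = np.zeros(n + 1)
        cs2 = np.zeros(n + 1)
        for i in range(n):
            cs[i + 1] = cs[i] + x[i]
            cs2[i + 1] = cs2[i] + x[i] * x[i]
        F = np.zeros(n + 1)
        F[0] = -penalty
        prev = np.zeros(n + 1, np.int64)
        cands = np.zeros(n + 1, np.int64)
        vals = np.zeros(n + 1)
        m = 1
        for t in range(1, n + 1):
            best = 1e300
            bs = 0
            for ci in range(m):
                s = cands[ci]
                d = cs[t] - cs[s]
                v = F[s] + cs2[t] - cs2[s] - d * d / (t - s)
                vals[ci] = v
                if v < best:
                    best = v
                    bs = s
            Ft = best + penalty
            F[t] = Ft
            prev[t] = bs
            k = 0
            for ci in range(m):
                if vals[ci] <= Ft:
                    cands[k] = cands[ci]
                    k += 1
            cands[k] = t
            m = k + 1
        out = np.empty(n, np.int64)
        c = 0
        t = n
        while t > 0:
            s = prev[t]
            if s > 0:
                out[c] = s
                c += 1
            t = s
        return out[:c][::-1]

    _pelt_jit = kernel
    return _pelt_jit


def pelt_mean_shift(x, penalty: float, engine: str = "auto") -> list[int]:
    """Exact penalized mean-shift segmentation (PELT search).

    Minimizes the total within-segment sum of squared deviations from the
    segment mean plus ``penalty`` per change point, over all segmentations.
    Pruning never discards an optimal candidate for this additive cost, so
    the result equals exhaustive search.  Returns sorted 0-based indices of
    the first sample of each new segment.

    ``engine="auto"`` uses a numba-compiled kernel when numba is installed
    (same arithmetic, same result); ``engine="numpy"`` forces the pure
    numpy/python reference path.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 4:
        warnings.warn("series shorter than 4 points; no change points", stacklevel=2)
        return []
    if engine == "auto":
        kernel = _jit_kernel()
        if kernel:
            return [int(i) for i in kernel(x, float(penalty))]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(s: np.ndarray, t: int) -> np.ndarray:
        length = t - s
        seg_sum = cs[t] - cs[s]
        return cs2[t] - cs2[s] - seg_sum * seg_sum / length

    F = np.empty(n + 1)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    cands = np.array([0], dtype=np.int64)
    for t in range(1, n + 1):
        f_cand = F[cands] + seg_cost(cands, t)
        i = int(np.argmin(f_cand))
        F[t] = f_cand[i] + penalty
        prev[t] = cands[i]
        keep = f_cand <= F[t]
        cands = np.append(cands[keep], t)
    bps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            bps.append(s)
        t = s
    return bps[::-1]


def detect_change_points(values, penalty: float | None = None, times=None):
    """Detect mean shifts in a regularly sampled feature series.

    Parameters
    ----------
    values
        Series values on a regular time grid (e.g. per-minute or binned
        activity level).
    penalty
        Linear penalty per change point; default :func:`default_penalty`.
    times
        Optional grid timestamps; when given, detected break positions are
        returned as timestamps instead of indices.

    Returns sorted break positions; empty (with a warning) for series
    shorter than 4 points.
    """
    x = np.asarray(values, float)
    if penalty is None:
        penalty = default_penalty(x) if len(x) > 1 else 1.0
    idx = pelt_mean_shift(x, penalty)
    if times is None:
        return idx
    times = np.asarray(times)
    return [times[i] for i in idx]


def cp_nearness(t, change_points, tau_min: float = 15.0) -> float:
    """Exponential nearness ``exp(-Δ/τ)`` to the closest change point.

    Δ is the absolute gap in minutes to the nearest change point; the value
    is 1.0 at a change point and decays toward 0 away from one.  With no
    change points the far-field sentinel 0.0 is returned.
    """
    if tau_min <= 0:
        raise ValueError("tau_min must be positive")
    cps = _epoch_s_array(change_points) if len(change_points) else np.empty(0)
    if cps.size == 0:
        return 0.0
    delta_min = np.min(np.abs(cps - _epoch_s(t))) / 60.0
    return float(math.exp(-delta_min / tau_min))


def read_accel_stream(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a watch acceleration CSV (timestamp, magnitude) → (epoch s, g)."""
    df = pd.read_csv(path)
    t = pd.to_datetime(df["timestamp"]).astype("int64").to_numpy() / 1e9
    order = np.argsort(t, kind="stable")
    return t[order], df["magnitude"].to_numpy(float)[order]


def read_location_stream(path: str | Path):
    """Read a location CSV (timestamp, latitude, longitude[, altitude])."""
    df = pd.read_csv(path)
    t = pd.to_datetime(df["timestamp"]).astype("int64").to_numpy() / 1e9
    order = np.argsort(t, kind="stable")
    alt = df["altitude"].to_numpy(float)[order] if "altitude" in df else None
    return (
        t[order],
        df["latitude"].to_numpy(float)[order],
        df["longitude"].to_numpy(float)[order],
        alt,
    )


def read_ambient_stream(path: str | Path) -> AmbientEvents:
    """Read an ambient CSV (timestamp, sensor_id, kind, state)."""
    df = pd.read_csv(path, dtype={"sensor_id": str, "kind": str, "state": str})
    t = pd.to_datetime(df["timestamp"]).astype("int64").to_numpy() / 1e9
    order = np.argsort(t, kind="stable")
    return AmbientEvents(
        times=t[order],
        kinds=df["kind"].to_numpy(object)[order],
        states=df["state"].to_numpy(object)[order],
        sensor_ids=df["sensor_id"].to_numpy(object)[order],
    )
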