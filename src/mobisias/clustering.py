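"""Time-based spatiotemporal clustering of GPS streams into significant places.

The algorithm processes location fixes in time order.  A running cluster
``cl`` absorbs each new fix that lies within a distance threshold ``d`` of
the cluster centroid.  A single far fix is not trusted immediately: it is
parked as a *pending location* ``pl`` so that a lone spurious outlier inside
a stay is discarded rather than splitting the stay.  Only when a second
consecutive far fix arrives is the current cluster closed — and emitted as a
significant place (a *stay*) if its occupied duration exceeds the time
threshold ``t`` — and a new cluster started from the pending fix.

Defaults are d = 60 m and t = 600 s.  Sampling gaps are detected from
inter-fix intervals; spans longer than the removable threshold (30 min) are
excised from cluster durations (the cluster is split at them and each
fragment is tested against ``t`` independently).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geo import EARTH_RADIUS_M, haversine_m
from .io import ParticipantTrace

__all__ = [
    "Stay",
    "Gap",
    "ClusterState",
    "cluster_distance",
    "step",
    "extract_stays",
    "DEFAULT_D_M",
    "DEFAULT_T_S",
    "GAP_DETECT_S",
    "GAP_REMOVABLE_S",
]

DEFAULT_D_M = 60.0
DEFAULT_T_S = 600.0
GAP_DETECT_S = 300.0      # inter-fix interval above which a Gap is recorded
GAP_REMOVABLE_S = 1800.0  # above which the span is removed from the study


@dataclass(frozen=True)
class Stay:
    """A significant place visit: centroid, time span, occupied duration."""

    lat: float
    lon: float
    start: int
    end: int
    occupied_s: float
    member_count: int


@dataclass(frozen=True)
class Gap:
    """A span of missing GPS samples, classified by duration regime."""

    start: int
    end: int
    regime: str  # "short" | "resolvable" | "removable"

    @property
    def duration_s(self) -> float:
        return float(self.end - self.start)


def gap_regime(duration_s: float, detect_s: float = GAP_DETECT_S,
               removable_s: float = GAP_REMOVABLE_S) -> str:
    if duration_s <= detect_s:
        return "short"
    if duration_s <= removable_s:
        return "resolvable"
    return "removable"


class ClusterState:
    """Mutable state of the streaming clusterer.

    ``times``/``lats``/``lons`` hold the current cluster members; ``pending``
    is the parked far fix (or None); ``places`` accumulates emitted stays.
    Running coordinate sums keep the centroid O(1) per step.
    """

    __slots__ = ("times", "lats", "lons", "sum_lat", "sum_lon", "pending", "places")

    def __init__(self):
        self.times: list[int] = []
        self.lats: list[float] = []
        self.lons: list[float] = []
        self.sum_lat = 0.0
        self.sum_lon = 0.0
        self.pending: tuple[int, float, float] | None = None
        self.places: list[Stay] = []

    def centroid(self) -> tuple[float, float]:
        n = len(self.times)
        if n == 0:
            raise ValueError("empty cluster has no centroid")
        return self.sum_lat / n, self.sum_lon / n

    def _absorb(self, t: int, lat: float, lon: float) -> None:
        self.times.append(t)
        self.lats.append(lat)
        self.lons.append(lon)
        self.sum_lat += lat
        self.sum_lon += lon

    def _clear(self) -> None:
        self.times.clear()
        self.lats.clear()
        self.lons.clear()
        self.sum_lat = 0.0
        self.sum_lon = 0.0


def cluster_distance(state: ClusterState, lat: float, lon: float) -> float:
    """Haversine distance from the cluster's arithmetic-mean centroid to a fix."""
    clat, clon = state.centroid()
    return haversine_m((clat, clon), (lat, lon))


def _finalize(state: ClusterState, t_s: float, removable_s: float) -> None:
    """Emit the current cluster as stay(s) if long enough.

    Internal sampling gaps above ``removable_s`` split the cluster; each
    fragment's wall-clock span is tested against ``t_s`` independently, so
    removed periods never count towards occupied duration.
    """
    times = state.times
    n = len(times)
    if n == 0:
        return
    # fragment boundaries at removable internal gaps
    starts = [0]
    for i in range(1, n):
        if times[i] - times[i - 1] > removable_s:
            starts.append(i)
    starts.append(n)
    for a, b in zip(starts[:-1], starts[1:]):
        span = times[b - 1] - times[a]
        if span > t_s:
            m = b - a
            state.places.append(
                Stay(
                    lat=sum(state.lats[a:b]) / m,
                    lon=sum(state.lons[a:b]) / m,
                    start=int(times[a]),
                    end=int(times[b - 1]),
                    occupied_s=float(span),
                    member_count=m,
                )
            )


def step(
    state: ClusterState,
    t: int,
    lat: float,
    lon: float,
    d: float = DEFAULT_D_M,
    t_s: float = DEFAULT_T_S,
    removable_s: float = GAP_REMOVABLE_S,
) -> ClusterState:
    """Process one fix through the streaming clustering rule (in place).

    An empty cluster absorbs the first fix unconditionally.  Otherwise: a
    near fix (within ``d`` of the centroid) is absorbed and clears any
    pending fix; a first far fix is parked as pending; a second far fix
    closes the cluster (emitting it if longer than ``t_s``), restarts the
    cluster from the pending fix, and then absorbs the new fix if it is
    within ``d`` of the restarted cluster, else parks it as pending.
    """
    if state.times and t <= state.times[-1]:
        raise ValueError("out-of-order timestamp passed to step()")
    if not state.times:
        state._absorb(t, lat, lon)
        state.pending = None
        return state
    if cluster_distance(state, lat, lon) < d:
        state._absorb(t, lat, lon)
        state.pending = None
        return state
    if state.pending is None:
        state.pending = (t, lat, lon)
        return state
    # pending present and the new fix is also far: the user really moved
    _finalize(state, t_s, removable_s)
    pt, plat, plon = state.pending
    state._clear()
    state._absorb(pt, plat, plon)
    state.pending = None
    if cluster_distance(state, lat, lon) < d:
        state._absorb(t, lat, lon)
    else:
        state.pending = (t, lat, lon)
    return state


def extract_stays(
    trace: ParticipantTrace,
    d: float = DEFAULT_D_M,
    t: float = DEFAULT_T_S,
    gap_detect_s: float = GAP_DETECT_S,
    removable_s: float = GAP_REMOVABLE_S,
) -> tuple[list[Stay], list[Gap]]:
    """Cluster a whole trace into stays and detect sampling gaps.

    Folds :func:`step` over the trace, then flushes the final open cluster
    (emitting it if its occupied duration exceeds ``t``).  Gaps are all
    inter-fix intervals above ``gap_detect_s``, classified as resolvable
    (mergeable/transition) or removable (> ``removable_s``, excluded from
    the analysis).
    """
    times = trace.times
    lats = trace.lats
    lons = trace.lons
    n = len(times)
    state = ClusterState()
    if n == 0:
        return [], []

    # tight loop: inlined step() logic (identical semantics, lower overhead)
    c_times = state.times
    c_lats = state.lats
    c_lons = state.lons
    sum_lat = 0.0
    sum_lon = 0.0
    pending = None
    radians = math.radians
    sin = math.sin
    cos = math.cos
    asin = math.asin
    sqrt = math.sqrt
    R2 = 2.0 * EARTH_RADIUS_M
    for i in range(n):
        ti = int(times[i])
        la = float(lats[i])
        lo = float(lons[i])
        m = len(c_times)
        if m == 0:
            c_times.append(ti); c_lats.append(la); c_lons.append(lo)
            sum_lat = la; sum_lon = lo
            pending = None
            continue
        clat = sum_lat / m
        clon = sum_lon / m
        la1 = radians(clat); la2 = radians(la)
        h = sin((la2 - la1) / 2.0) ** 2 + cos(la1) * cos(la2) * sin(
            (radians(lo) - radians(clon)) / 2.0
        ) ** 2
        dist = R2 * asin(sqrt(h) if h < 1.0 else 1.0)
        if dist < d:
            c_times.append(ti); c_lats.append(la); c_lons.append(lo)
            sum_lat += la; sum_lon += lo
            pending = None
            continue
        if pending is None:
            pending = (ti, la, lo)
            continue
        state.sum_lat = sum_lat
        state.sum_lon = sum_lon
        _finalize(state, t, removable_s)
        pt, plat, plon = pending
        c_times.clear(); c_lats.clear(); c_lons.clear()
        c_times.append(pt); c_lats.append(plat); c_lons.append(plon)
        sum_lat = plat; sum_lon = plon
        pending = None
        if haversine_m((plat, plon), (la, lo)) < d:
            c_times.append(ti); c_lats.append(la); c_lons.append(lo)
            sum_lat += la; sum_lon += lo
        else:
            pending = (ti, la, lo)
    state.sum_lat = sum_lat
    state.sum_lon = sum_lon
    _finalize(state, t, removable_s)

    gaps: list[Gap] = []
    if n > 1:
        dts = np.diff(times)
        for i in np.nonzero(dts > gap_detect_s)[0]:
            dur = float(dts[i])
            gaps.append(
                Gap(
                    start=int(times[i]),
                    end=int(times[i + 1]),
                    regime=gap_regime(dur, gap_detect_s, removable_s),
                )
            )
    return state.places, gaps
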