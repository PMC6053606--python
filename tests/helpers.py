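"""Shared test helpers: interval/timeline builders and the clustering oracle."""

from __future__ import annotations

from datetime import date as _date, datetime, timezone

import numpy as np

from mobisias.geo import haversine_vec_m, offset_latlon
from mobisias.io import ParticipantTrace
from mobisias.labeling import DayTimeline, LabeledInterval

DAY_S = 86400
BASE_DATE = _date(2018, 3, 5)  # a Monday


def epoch_of(date: _date) -> int:
    return int(datetime(date.year, date.month, date.day, tzinfo=timezone.utc).timestamp())


def make_day(
    spec: list[tuple[str, float, float]],
    removed: list[tuple[float, float]] = (),
    date: _date = BASE_DATE,
    observed: tuple[float, float] | None = None,
    places: dict[int, str] | None = None,
) -> DayTimeline:
    """Build a DayTimeline from (class, start_h, end_h) entries.

    ``places`` optionally maps entry index -> place_id; Transition entries
    never get one.  ``observed`` defaults to the span of the entries.
    """
    day0 = epoch_of(date)
    ivs = []
    for i, (cls, a, b) in enumerate(spec):
        pid = None
        if cls != "Transition":
            pid = (places or {}).get(i, f"pl-{cls}")
        ivs.append(LabeledInterval(cls, day0 + int(a * 3600), day0 + int(b * 3600), pid))
    rem = [(day0 + int(a * 3600), day0 + int(b * 3600)) for a, b in removed]
    bounds = [iv.start for iv in ivs] + [iv.end for iv in ivs] + [x for r in rem for x in r]
    if observed is not None:
        obs = (day0 + int(observed[0] * 3600), day0 + int(observed[1] * 3600))
    elif bounds:
        obs = (min(bounds), max(bounds))
    else:
        obs = None
    return DayTimeline(
        participant_id="t", date=date, day_start=day0,
        intervals=ivs, removed=rem, observed_span=obs,
    )


# ---------------------------------------------------------------------------
# brute-force clustering oracle: maximal time windows whose points all lie
# within d of the window centroid, kept when the occupied span exceeds t


def _window_valid(lats, lons, i, j, d) -> bool:
    cl = lats[i : j + 1].mean()
    co = lons[i : j + 1].mean()
    return bool((haversine_vec_m(cl, co, lats[i : j + 1], lons[i : j + 1]) < d).all())


def oracle_stays(trace: ParticipantTrace, d: float, t: float):
    """Greedy left-to-right enumeration of maximal valid windows."""
    times, lats, lons = trace.times, trace.lats, trace.lons
    n = len(times)
    out = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and _window_valid(lats, lons, i, j + 1, d):
            j += 1
        if times[j] - times[i] > t:
            out.append((int(times[i]), int(times[j])))
            i = j + 1
        else:
            i += 1
    return out


def random_episode_trace(rng: np.random.Generator, max_pts: int = 350,
                         interval: int = 150) -> ParticipantTrace:
    """Stationary episodes (8 m jitter) linked by fast movement legs."""
    lat0, lon0 = 38.03, -78.51
    pts_t, pts_la, pts_lo = [], [], []
    t = 0
    cx = cy = 0.0
    for _ in range(int(rng.integers(2, 7))):
        dur = int(rng.integers(4, 16)) * interval
        for _ in range(dur // interval + 1):
            if len(pts_t) >= max_pts:
                break
            jx, jy = rng.normal(0, 8, 2)
            la, lo = offset_latlon(lat0, lon0, cx + jx, cy + jy)
            pts_t.append(t)
            pts_la.append(float(la))
            pts_lo.append(float(lo))
            t += interval
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(rng.integers(1, 5))):
            if len(pts_t) >= max_pts:
                break
            cx += 200 * np.cos(ang)
            cy += 200 * np.sin(ang)
            la, lo = offset_latlon(lat0, lon0, cx, cy)
            pts_t.append(t)
            pts_la.append(float(la))
            pts_lo.append(float(lo))
            t += interval
        cx += 200 * np.cos(ang)
        cy += 200 * np.sin(ang)
    return ParticipantTrace(
        "r", np.asarray(pts_t, dtype=np.int64) + 1_500_000_000,
        np.asarray(pts_la), np.asarray(pts_lo),
    )
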