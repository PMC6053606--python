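"""Semantic labeling: stays -> 10-class labeled daily timelines.

Each stay centroid is matched to a place in the :class:`~mobisias.places.PlaceMap`
(footprint containment, then nearest place within a match radius, then an
out-of-town / nearest fallback).  ``Home`` is the house-tagged place where a
participant accumulates the most stay time between 10 pm and 9 am over the
whole study; all other house-tagged places map to ``OtherHouses``.  Sampling
gaps are resolved into merges (same class on both flanks), ``Transition``
intervals (different classes), or removed spans (gaps over 30 minutes, and
gaps with only one flank).  Timelines are finally cut at midnight into
per-day timelines tagged weekday/weekend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date, datetime, timezone

import numpy as np

from .clustering import Gap, Stay
from .places import Place, PlaceMap, UnknownTagError

__all__ = [
    "CLASSES",
    "NON_TRANSITION_CLASSES",
    "SemanticClass",
    "PlaceMatch",
    "LabeledInterval",
    "LabeledTimeline",
    "DayTimeline",
    "label_stay",
    "infer_home",
    "assign_classes",
    "resolve_gaps",
    "split_by_day",
    "build_timeline",
]

#: The closed 10-class semantic vocabulary.
CLASSES = (
    "Home",
    "OtherHouses",
    "Education",
    "Leisure",
    "Food",
    "Supermarket",
    "Religious",
    "Service",
    "OutOfTown",
    "Transition",
)
NON_TRANSITION_CLASSES = CLASSES[:-1]
SemanticClass = str

_TAG_TO_CLASS = {
    "education": "Education",
    "leisure": "Leisure",
    "food": "Food",
    "supermarket": "Supermarket",
    "religious": "Religious",
    "service": "Service",
}

DEFAULT_MATCH_RADIUS_M = 75.0
#: Nocturnal window for home inference: 10 pm - 9 am (hours of day).
HOME_WINDOW = (22.0, 33.0)  # wraps midnight: [22h, 24h) U [0h, 9h)

DAY_S = 86400


@dataclass(frozen=True)
class PlaceMatch:
    """Result of matching a stay centroid against the place map."""

    place_id: str | None
    tag: str | None
    out_of_town: bool


@dataclass(frozen=True)
class LabeledInterval:
    cls: SemanticClass
    start: int
    end: int
    place_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("interval start must precede end")
        if self.cls == "Transition" and self.place_id is not None:
            raise ValueError("Transition intervals carry no place_id")

    @property
    def duration_s(self) -> float:
        return float(self.end - self.start)


@dataclass
class LabeledTimeline:
    """A participant's resolved study timeline."""

    participant_id: str
    intervals: list[LabeledInterval]
    removed: list[tuple[int, int]]
    home_place_id: str | None
    merged_gaps: list[Gap] = field(default_factory=list)
    transition_gaps: list[Gap] = field(default_factory=list)
    observed_span: tuple[int, int] | None = None


@dataclass
class DayTimeline:
    """One calendar day of a resolved timeline."""

    participant_id: str
    date: _date
    day_start: int  # epoch seconds at local midnight
    intervals: list[LabeledInterval]
    removed: list[tuple[int, int]]
    observed_span: tuple[int, int] | None

    @property
    def is_weekend(self) -> bool:
        return self.date.weekday() >= 5

    @property
    def day_of_week(self) -> int:
        """Monday = 0 ... Sunday = 6."""
        return self.date.weekday()


def label_stay(
    stay: Stay,
    place_map: PlaceMap,
    match_radius_m: float = DEFAULT_MATCH_RADIUS_M,
) -> PlaceMatch:
    """Match a stay centroid to a place.

    Containment in a footprint wins (nearest centroid, ties by smallest
    place_id); otherwise the nearest place within ``match_radius_m``; then,
    if the centroid lies beyond the town radius, an out-of-town marker;
    otherwise the nearest place regardless of radius.
    """
    if len(place_map) == 0:
        raise ValueError("place map is empty")
    dists = place_map.distances_m(stay.lat, stay.lon)
    inside = dists <= place_map.footprint_radii()
    cand = np.nonzero(inside)[0] if inside.any() else None
    if cand is None:
        order = np.argsort(dists, kind="stable")
        nearest = place_map.places[int(order[0])]
        if dists[order[0]] <= match_radius_m:
            cand_place = nearest
        elif place_map.is_out_of_town(stay.lat, stay.lon):
            return PlaceMatch(None, None, out_of_town=True)
        else:
            cand_place = nearest
    else:
        # nearest contained footprint; exact ties -> smallest place_id
        dmin = dists[cand].min()
        tied = [place_map.places[int(i)] for i in cand if dists[i] == dmin]
        cand_place = min(tied, key=lambda p: p.place_id)
    return PlaceMatch(cand_place.place_id, cand_place.tag,
                      out_of_town=place_map.is_out_of_town(cand_place.lat, cand_place.lon))


def _overlap_with_home_window(start: int, end: int) -> float:
    """Seconds of [start, end) falling inside the nightly 10 pm - 9 am window."""
    total = 0.0
    w0, w1 = HOME_WINDOW[0] * 3600.0, HOME_WINDOW[1] * 3600.0
    day0 = (start // DAY_S) - 1
    day1 = (end // DAY_S) + 1
    for day in range(int(day0), int(day1) + 1):
        a = day * DAY_S + w0
        b = day * DAY_S + w1
        total += max(0.0, min(end, b) - max(start, a))
    return total


def infer_home(
    stays: list[Stay],
    matches: list[PlaceMatch],
    place_map: PlaceMap,
) -> str | None:
    """The house-tagged place with the most cumulative 10 pm - 9 am stay time.

    Returns None (home unknown) when no house-tagged stay overlaps the
    nocturnal window; house stays then all label as OtherHouses.
    """
    totals: dict[str, float] = {}
    for stay, match in zip(stays, matches):
        if match.place_id is None or match.tag != "house" or match.out_of_town:
            continue
        sec = _overlap_with_home_window(stay.start, stay.end)
        if sec > 0:
            totals[match.place_id] = totals.get(match.place_id, 0.0) + sec
    if not totals:
        return None
    best = max(totals.values())
    return min(pid for pid, v in totals.items() if v == best)


def assign_classes(
    stays: list[Stay],
    matches: list[PlaceMatch],
    home: str | None,
) -> list[LabeledInterval]:
    """Map matched stays to semantic-class intervals (stays only)."""
    out: list[LabeledInterval] = []
    for stay, match in zip(stays, matches):
        if match.out_of_town or match.place_id is None:
            cls = "OutOfTown"
        elif match.tag == "house":
            cls = "Home" if (home is not None and match.place_id == home) else "OtherHouses"
        else:
            try:
                cls = _TAG_TO_CLASS[match.tag]
            except KeyError:
                raise UnknownTagError(f"unknown place tag {match.tag!r}") from None
        out.append(LabeledInterval(cls, stay.start, stay.end, match.place_id))
    return out


def resolve_gaps(
    participant_id: str,
    stay_intervals: list[LabeledInterval],
    gaps: list[Gap],
    observed_span: tuple[int, int] | None = None,
    home_place_id: str | None = None,
    boundary_tol_s: float = 1.0,
) -> LabeledTimeline:
    """Resolve sampling gaps into merges, transitions, and removed spans.

    Between consecutive stays: a resolvable gap spanning the whole
    inter-stay span with the same class on both flanks merges the two stays
    (and the gap) into one interval; otherwise removable-regime gap portions
    become removed spans and everything else becomes ``Transition``.  Gaps
    with only one flank (before the first or after the last stay) are
    treated as removed.
    """
    stays = sorted(stay_intervals, key=lambda iv: iv.start)
    res_gaps = [g for g in gaps if g.regime == "resolvable"]
    rem_gaps = [g for g in gaps if g.regime == "removable"]
    merged_gaps: list[Gap] = []
    transition_gaps: list[Gap] = []

    if observed_span is None and stays:
        observed_span = (stays[0].start, stays[-1].end)

    intervals: list[LabeledInterval] = []
    removed: list[tuple[int, int]] = []

    def _gap_overlaps(gset: list[Gap], a: int, b: int) -> list[tuple[int, int]]:
        out = []
        for g in gset:
            lo, hi = max(g.start, a), min(g.end, b)
            if hi > lo:
                out.append((lo, hi))
        return sorted(out)

    def _fill_span(a: int, b: int, boundary: bool) -> None:
        """Label [a, b) as removed/Transition pieces."""
        if b - a <= 0:
            return
        cut = _gap_overlaps(rem_gaps, a, b)
        if boundary:
            cut = sorted(cut + _gap_overlaps(res_gaps, a, b))
        pos = a
        for lo, hi in cut:
            if lo > pos:
                intervals.append(LabeledInterval("Transition", pos, lo))
            removed.append((lo, hi))
            pos = hi
        if pos < b:
            intervals.append(LabeledInterval("Transition", pos, b))

    # mark resolvable gaps lying strictly inside a stay as merged (the
    # clusterer already carried the cluster across them)
    for g in res_gaps:
        if any(s.start <= g.start and g.end <= s.end for s in stays):
            merged_gaps.append(g)

    if not stays:
        if observed_span is not None:
            _fill_span(observed_span[0], observed_span[1], boundary=True)
        return LabeledTimeline(participant_id, intervals, removed, home_place_id,
                               merged_gaps, transition_gaps, observed_span)

    t0, t1 = observed_span
    _fill_span(t0, stays[0].start, boundary=True)
    intervals.append(stays[0])
    for prev, nxt in zip(stays[:-1], stays[1:]):
        a, b = prev.end, nxt.start
        span_res = [
            g for g in res_gaps
            if abs(g.start - a) <= boundary_tol_s and abs(g.end - b) <= boundary_tol_s
        ]
        span_rem = _gap_overlaps(rem_gaps, a, b)
        if span_res and not span_rem and prev.cls == nxt.cls:
            # same class across a resolvable gap: merge prev + gap + next
            merged_gaps.append(span_res[0])
            last = intervals.pop()
            pid = last.place_id if last.place_id == nxt.place_id else None
            intervals.append(LabeledInterval(last.cls, last.start, nxt.end, pid))
            continue
        if span_res:
            transition_gaps.append(span_res[0])
        _fill_span(a, b, boundary=False)
        intervals.append(nxt)
    _fill_span(stays[-1].end, t1, boundary=True)

    intervals.sort(key=lambda iv: iv.start)
    removed.sort()
    return LabeledTimeline(participant_id, intervals, removed, home_place_id,
                           merged_gaps, transition_gaps, observed_span)


def _clip_intervals(intervals, a: int, b: int):
    out = []
    for iv in intervals:
        lo, hi = max(iv.start, a), min(iv.end, b)
        if hi > lo:
            out.append(LabeledInterval(iv.cls, lo, hi, iv.place_id))
    return out


def split_by_day(timeline: LabeledTimeline) -> list[DayTimeline]:
    """Cut a resolved timeline at midnight into per-day timelines.

    Timestamps are interpreted as local study time; fragments retain their
    class and place.
    """
    if timeline.observed_span is None:
        return []
    t0, t1 = timeline.observed_span
    first_day = int(t0 // DAY_S)
    last_day = int((t1 - 1) // DAY_S)
    days: list[DayTimeline] = []
    for day in range(first_day, last_day + 1):
        a, b = day * DAY_S, (day + 1) * DAY_S
        obs = (max(t0, a), min(t1, b))
        if obs[1] <= obs[0]:
            continue
        ivs = _clip_intervals(timeline.intervals, a, b)
        rem = [
            (max(lo, a), min(hi, b))
            for lo, hi in timeline.removed
            if min(hi, b) > max(lo, a)
        ]
        days.append(
            DayTimeline(
                participant_id=timeline.participant_id,
                date=datetime.fromtimestamp(a, tz=timezone.utc).date(),
                day_start=a,
                intervals=ivs,
                removed=rem,
                observed_span=obs,
            )
        )
    return days


def build_timeline(
    participant_id: str,
    stays: list[Stay],
    gaps: list[Gap],
    place_map: PlaceMap,
    observed_span: tuple[int, int] | None = None,
    match_radius_m: float = DEFAULT_MATCH_RADIUS_M,
) -> LabeledTimeline:
    """Full labeling stage: match places, infer home, assign classes, resolve gaps."""
    matches = [label_stay(s, place_map, match_radius_m) for s in stays]
    home = infer_home(stays, matches, place_map)
    stay_ivs = assign_classes(stays, matches, home)
    return resolve_gaps(participant_id, stay_ivs, gaps, observed_span, home)
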