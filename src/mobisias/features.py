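"""Daily mobility features: staying time, visit distribution, entropy, transitions.

The daily feature vector has 204 named entries in a fixed documented order:

* 40 staying-time fractions (10 classes x 4 epochs: daily, 8 am-4 pm,
  4 pm-12 am, 12 am-8 am),
* 80 visit-distribution occupancies (10 classes x 8 three-hour bins),
* 1 location entropy (Shannon, natural log, over semantic classes),
* 81 unidirectional transition counts (ordered pairs of the 9 non-Transition
  classes; a self-pair counts only when two *distinct* places of the same
  class are visited back to back),
* 1 weekend flag and 1 day-of-week index (Monday = 0).

Fractions with an empty denominator (the epoch fully removed/unobserved) are
imputed 0 in the model vector; a parallel observed-mask records which
entries were measurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labeling import CLASSES, NON_TRANSITION_CLASSES, DayTimeline

__all__ = [
    "EPOCHS",
    "FEATURE_NAMES",
    "N_FEATURES",
    "staying_time",
    "location_entropy",
    "transition_count",
    "transition_counts",
    "visit_occupancy",
    "visit_density",
    "daily_vector",
    "FeatureTable",
    "build_feature_table",
]

#: Epoch windows in hours of day (start, end).
EPOCHS = {
    "daily": (0.0, 24.0),
    "morning": (8.0, 16.0),
    "evening": (16.0, 24.0),
    "night": (0.0, 8.0),
}
_BIN_H = 3.0
_N_BINS = 8

_STAY_NAMES = [f"stay_frac_{c}_{e}" for c in CLASSES for e in EPOCHS]
_OCC_NAMES = [f"occ_{c}_b{i}" for c in CLASSES for i in range(_N_BINS)]
_TRANS_NAMES = [
    f"trans_{a}__{b}" for a in NON_TRANSITION_CLASSES for b in NON_TRANSITION_CLASSES
]
FEATURE_NAMES: list[str] = _STAY_NAMES + _OCC_NAMES + ["entropy"] + _TRANS_NAMES + [
    "is_weekend",
    "day_of_week",
]
N_FEATURES = len(FEATURE_NAMES)  # 204


def _overlap(intervals, a: float, b: float, cls: str | None = None) -> float:
    """Total seconds of intervals (optionally of one class) within [a, b)."""
    total = 0.0
    for iv in intervals:
        if cls is not None and iv.cls != cls:
            continue
        lo = iv.start if iv.start > a else a
        hi = iv.end if iv.end < b else b
        if hi > lo:
            total += hi - lo
    return total


def _span_overlap(spans, a: float, b: float) -> float:
    total = 0.0
    for lo, hi in spans:
        lo, hi = max(lo, a), min(hi, b)
        if hi > lo:
            total += hi - lo
    return total


def staying_time(day: DayTimeline, cls: str, epoch: str) -> tuple[float, float]:
    """(fraction, minutes) of ``epoch`` spent in class ``cls``.

    The fraction denominator is the epoch length minus removed and
    unobserved time inside the epoch; it is NaN when that denominator is
    zero (fully unobserved epoch).
    """
    h0, h1 = EPOCHS[epoch]
    a = day.day_start + h0 * 3600.0
    b = day.day_start + h1 * 3600.0
    minutes = _overlap(day.intervals, a, b, cls) / 60.0
    denom = (b - a) - _span_overlap(day.removed, a, b)
    if day.observed_span is not None:
        o0, o1 = day.observed_span
        denom -= max(0.0, min(o0, b) - a)  # unobserved before first fix
        denom -= max(0.0, b - max(o1, a))  # unobserved after last fix
    else:
        denom = 0.0
    if denom <= 0:
        return float("nan"), minutes
    return minutes * 60.0 / denom, minutes


def location_entropy(intervals) -> float:
    """Shannon entropy (natural log) of time shares across semantic classes.

    ``Transition`` time is excluded.  NaN when no labeled non-Transition
    time exists.
    """
    shares: dict[str, float] = {}
    for iv in intervals:
        if iv.cls == "Transition":
            continue
        shares[iv.cls] = shares.get(iv.cls, 0.0) + iv.duration_s
    total = sum(shares.values())
    if total <= 0:
        return float("nan")
    h = 0.0
    for v in shares.values():
        p = v / total
        if p > 0:
            h -= p * math.log(p)
    return h


def _visit_sequence(day: DayTimeline):
    """Non-Transition intervals in order, with adjacency broken at removed spans."""
    items = [("iv", iv.start, iv) for iv in day.intervals] + [
        ("rm", lo, (lo, hi)) for lo, hi in day.removed
    ]
    items.sort(key=lambda x: x[1])
    seq: list = []  # LabeledInterval or None (break)
    for kind, _, obj in items:
        if kind == "rm":
            seq.append(None)
        elif obj.cls != "Transition":
            seq.append(obj)
    return seq


def transition_counts(day: DayTimeline) -> dict[tuple[str, str], int]:
    """Unidirectional class-pair transition counts for one day.

    Intervening ``Transition`` intervals are ignored; removed spans break
    adjacency.  Consecutive intervals at the same place (e.g. a stay split
    at midnight) are a continuation, not a transition; a same-class pair
    counts only when the places differ.
    """
    counts: dict[tuple[str, str], int] = {}
    prev = None
    for item in _visit_sequence(day):
        if item is None:
            prev = None
            continue
        if prev is not None:
            same_place = (
                prev.place_id is not None and prev.place_id == item.place_id
            )
            if not same_place:
                key = (prev.cls, item.cls)
                counts[key] = counts.get(key, 0) + 1
        prev = item
    return counts


def transition_count(day: DayTimeline, from_cls: str, to_cls: str) -> int:
    return transition_counts(day).get((from_cls, to_cls), 0)


def visit_occupancy(day: DayTimeline, cls: str) -> np.ndarray:
    """Fraction of each 3-hour bin occupied by ``cls`` (8 values)."""
    out = np.zeros(_N_BINS)
    for i in range(_N_BINS):
        a = day.day_start + i * _BIN_H * 3600.0
        b = a + _BIN_H * 3600.0
        out[i] = _overlap(day.intervals, a, b, cls) / (_BIN_H * 3600.0)
    return out


def visit_density(
    start_hours: np.ndarray,
    grid_hours: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Epanechnikov KDE of visit start times over the 24 h clock.

    ``start_hours`` are times of day in hours; the estimate wraps at 24 h
    (the sample is replicated at +/- 24 h and the density evaluated on
    [0, 24)).  Bandwidth follows Silverman's rule.  Returns (grid, density);
    the density integrates to 1 over [0, 24).  Requires >= 2 points.
    """
    x = np.asarray(start_hours, dtype=float) % 24.0
    if x.size < 2:
        raise ValueError("visit_density requires at least 2 visit times")
    if grid_hours is None:
        grid_hours = np.linspace(0.0, 24.0, 241)
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * x.size ** (-0.2)
    if bw <= 0:
        bw = 0.5
    rep = np.concatenate([x - 24.0, x, x + 24.0])
    u = (grid_hours[:, None] - rep[None, :]) / bw
    k = np.where(np.abs(u) <= 1.0, 0.75 * (1.0 - u**2), 0.0)
    dens = k.sum(axis=1) / (x.size * bw)
    return np.asarray(grid_hours), dens


def daily_vector(day: DayTimeline) -> tuple[np.ndarray, np.ndarray]:
    """(features, observed_mask) for one day, in :data:`FEATURE_NAMES` order.

    Unmeasurable fractions are imputed 0 in the feature vector and flagged
    False in the mask (the mask is diagnostics, never a model input).
    """
    vec = np.zeros(N_FEATURES)
    mask = np.ones(N_FEATURES, dtype=bool)
    i = 0
    for c in CLASSES:
        for e in EPOCHS:
            frac, _ = staying_time(day, c, e)
            if math.isnan(frac):
                mask[i] = False
            else:
                vec[i] = frac
            i += 1
    for c in CLASSES:
        vec[i : i + _N_BINS] = visit_occupancy(day, c)
        i += _N_BINS
    h = location_entropy(day.intervals)
    if math.isnan(h):
        mask[i] = False
    else:
        vec[i] = h
    i += 1
    counts = transition_counts(day)
    for a in NON_TRANSITION_CLASSES:
        for b in NON_TRANSITION_CLASSES:
            vec[i] = counts.get((a, b), 0)
            i += 1
    vec[i] = 1.0 if day.is_weekend else 0.0
    vec[i + 1] = float(day.day_of_week)
    return vec, mask


@dataclass
class FeatureTable:
    """Cohort feature matrices.

    ``features``: model features, one row per (participant, date).
    ``mask``: parallel observed-flags.
    ``minutes``: per-day staying minutes per class x epoch plus entropy and
    day-type, used for the association analyses (which report minutes, not
    fractions).
    """

    features: pd.DataFrame
    mask: pd.DataFrame
    minutes: pd.DataFrame

    def to_csv(self, path) -> None:
        self.features.to_csv(path)


def build_feature_table(day_timelines: dict[str, list[DayTimeline]]) -> FeatureTable:
    """Assemble the cohort feature table from per-participant day timelines."""
    rows, masks, minute_rows, index = [], [], [], []
    for pid, days in day_timelines.items():
        for day in days:
            vec, m = daily_vector(day)
            rows.append(vec)
            masks.append(m)
            mrow: dict[str, float] = {
                "is_weekend": float(day.is_weekend),
                "entropy": location_entropy(day.intervals),
            }
            for c in CLASSES:
                for e in EPOCHS:
                    mrow[f"min_{c}_{e}"] = staying_time(day, c, e)[1]
            minute_rows.append(mrow)
            index.append((pid, day.date))
    idx = pd.MultiIndex.from_tuples(index, names=["participant_id", "date"])
    features = pd.DataFrame(np.array(rows).reshape(len(rows), N_FEATURES),
                            index=idx, columns=FEATURE_NAMES)
    mask = pd.DataFrame(np.array(masks).reshape(len(rows), N_FEATURES),
                        index=idx, columns=FEATURE_NAMES)
    minutes = pd.DataFrame(minute_rows, index=idx)
    return FeatureTable(features=features, mask=mask, minutes=minutes)
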