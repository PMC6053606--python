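"""Synthetic campus cohort generator with ground truth.

Emulates a two-week, 228-student campus study: a place map (campus-scale
town with houses, education, leisure, food, supermarket, religious and
service places plus an out-of-town cluster), SIAS totals drawn from a
truncated normal (mean 29.91, SD 9.1, range 11-54), and per-participant
daily routines whose expected dwell times shift with the latent SIAS score
in the directions the analysis stage is meant to recover:

* more evening (4 pm-12 am) home time with higher SIAS,
* less evening/weekend leisure, food and friends'-house time,
* more supermarket (and religious/service) time,
* fewer distinct routine places (narrower mobility repertoire),
* a Friday/Saturday-evening leisure surge for low-SIAS participants
  (a day-of-week effect that only daily features can see).

Traces are emitted on the nominal 150 s sampling grid with isotropic
Gaussian GPS jitter (default sigma = 10 m); transitions are constant-speed
straight lines.  Ground-truth stays, transitions and injected gaps are
recorded so every downstream stage can be tested against a known answer.
The generator is an emulation of the study conditions, not a fit to any
real cohort.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import date as _date, datetime, timedelta, timezone

import numpy as np
from scipy.stats import truncnorm

from .geo import haversine_m, offset_latlon
from .io import NOMINAL_INTERVAL_S, ParticipantTrace
from .places import Place, PlaceMap

__all__ = [
    "MapConfig",
    "EffectConfig",
    "GapConfig",
    "NoiseConfig",
    "CohortConfig",
    "BehaviorProfile",
    "GroundTruthStay",
    "ParticipantGroundTruth",
    "CohortBundle",
    "generate_map",
    "sample_sias",
    "build_profile",
    "simulate_day",
    "inject_gaps",
    "generate_cohort",
    "true_class",
    "SIAS_MEAN",
    "SIAS_SD",
]

logger = logging.getLogger(__name__)

SIAS_MEAN = 29.91
SIAS_SD = 9.1
DAY_S = 86400

_WALK_MS = 1.4   # walking, short campus hops
_BIKE_MS = 3.5   # bike/bus, 1.2-2.5 km
_DRIVE_MS = 12.0  # driving, beyond 2.5 km (e.g. out-of-town trips)

_PLACE_RADIUS = {
    "house": 25.0,
    "education": 60.0,
    "leisure": 35.0,
    "food": 25.0,
    "supermarket": 45.0,
    "religious": 35.0,
    "service": 30.0,
}

# typical single-visit durations (minutes) used to turn expected dwell
# minutes into visit probabilities / counts
_TYPICAL_MIN = {
    "leisure": 45.0,
    "food": 35.0,
    "supermarket": 20.0,
    "religious": 55.0,
    "service": 20.0,
    "otherhouses": 60.0,
}


@dataclass(frozen=True)
class MapConfig:
    n_houses: int | None = None  # default: n_participants + 12
    n_education: int = 5
    n_leisure: int = 6
    n_food: int = 6
    n_supermarket: int = 2
    n_religious: int = 2
    n_service: int = 3
    n_out_of_town: int = 3
    town_center: tuple[float, float] = (38.035, -78.507)
    town_radius_m: float = 8000.0
    core_extent_m: float = 1500.0
    min_separation_m: float = 180.0
    out_of_town_km: tuple[float, float] = (12.0, 20.0)


@dataclass(frozen=True)
class EffectConfig:
    """Slopes linking standardized SIAS (z) to expected dwell minutes.

    The defaults are the generator's "strong" preset, sized to the order of
    the study's reported weekday/weekend group differences.
    """

    leisure_evening_wd: float = -10.0
    leisure_we: float = -18.0
    # morning leisure shifts the other way: high-SIAS students move leisure
    # into the low-social-demand morning hours
    leisure_morning_we: float = 3.0
    food_wd: float = -4.5
    food_we: float = -5.0
    supermarket_wd: float = 2.5
    supermarket_we: float = 3.5
    religious: float = 2.2
    service: float = 1.8
    otherhouses_wd: float = -4.0
    otherhouses_we: float = -14.0
    education_we: float = 18.0
    outoftown_prob_we: float = 0.09
    entropy_narrowing: float = 1.2
    friday_leisure_base: float = 0.9
    friday_leisure_slope: float = 0.45
    # how fast day-to-day routine variability shrinks with SIAS z
    day_variability: float = 0.3

    @classmethod
    def zero(cls) -> "EffectConfig":
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__})


@dataclass(frozen=True)
class GapConfig:
    """Missing-data model: Poisson gap starts, mixed duration regimes."""

    rate_per_day: float = 0.3
    # mixture over (short 2-5 min, resolvable 6-28 min, removable 32-80 min)
    regime_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)
    # heterogeneous sensing quality: some days are "patchy" (phone off and
    # on all day), losing much of the record to removable gaps
    patchy_day_prob: float = 0.15
    patchy_rate_per_day: float = 12.0
    patchy_regime_probs: tuple[float, float, float] = (0.2, 0.35, 0.45)
    forced: tuple[tuple[int, int], ...] = ()

    @classmethod
    def none(cls) -> "GapConfig":
        return cls(rate_per_day=0.0, patchy_day_prob=0.0)


@dataclass(frozen=True)
class NoiseConfig:
    jitter_sigma_m: float = 10.0
    gaps: GapConfig = field(default_factory=GapConfig)


@dataclass(frozen=True)
class CohortConfig:
    n_participants: int = 228
    n_days: int = 14
    start_date: _date = _date(2018, 3, 5)  # a Monday
    map: MapConfig = field(default_factory=MapConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    sias_mean: float = SIAS_MEAN
    sias_sd: float = SIAS_SD
    sias_min: int = 11
    sias_max: int = 54
    cutoff: int = 34


@dataclass(frozen=True)
class GroundTruthStay:
    place_id: str
    cls: str
    start: int
    end: int


@dataclass
class ParticipantGroundTruth:
    stays: list[GroundTruthStay] = field(default_factory=list)
    transitions: list[tuple[int, int]] = field(default_factory=list)
    gaps: list[tuple[int, int]] = field(default_factory=list)
    home_place_id: str | None = None


@dataclass
class CohortBundle:
    """A generated cohort: map, scores, traces, and ground truth."""

    config: CohortConfig
    seed: int
    place_map: PlaceMap
    sias: dict[str, int]
    traces: dict[str, ParticipantTrace]
    ground_truth: dict[str, ParticipantGroundTruth]

    def digest(self) -> str:
        """SHA-256 over the serialized cohort (determinism check)."""
        h = hashlib.sha256()
        for pid in sorted(self.sias):
            h.update(pid.encode())
            h.update(str(self.sias[pid]).encode())
            tr = self.traces[pid]
            h.update(tr.times.tobytes())
            h.update(np.round(tr.lats, 7).tobytes())
            h.update(np.round(tr.lons, 7).tobytes())
            for s in self.ground_truth[pid].stays:
                h.update(f"{s.place_id},{s.cls},{s.start},{s.end};".encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# map generation


def generate_map(
    config: MapConfig,
    seed: int | np.random.Generator,
    n_participants: int = 0,
) -> PlaceMap:
    """Generate a deterministic place map.

    Core places are sampled uniformly in a disc of ``core_extent_m`` around
    the town center with a minimum mutual separation; out-of-town places sit
    12-20 km out (beyond the town radius).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_houses = config.n_houses if config.n_houses is not None else n_participants + 12
    counts = [
        ("house", n_houses),
        ("education", config.n_education),
        ("leisure", config.n_leisure),
        ("food", config.n_food),
        ("supermarket", config.n_supermarket),
        ("religious", config.n_religious),
        ("service", config.n_service),
    ]
    if any(c <= 0 for _, c in counts):
        raise ValueError("every in-town category needs at least one place")

    clat, clon = config.town_center
    accepted: list[tuple[float, float]] = []  # local metres east/north
    places: list[Place] = []
    total = sum(c for _, c in counts)
    # grow the campus disc so the separation constraint stays satisfiable
    extent = max(
        config.core_extent_m,
        (config.min_separation_m / 2.0) * float(np.sqrt(total / 0.3)),
    )

    def _sample_core() -> tuple[float, float]:
        for _ in range(500):
            r = extent * np.sqrt(rng.random())
            th = rng.random() * 2 * np.pi
            x, y = r * np.cos(th), r * np.sin(th)
            if all(
                (x - a) ** 2 + (y - b) ** 2 >= config.min_separation_m**2
                for a, b in accepted
            ):
                return x, y
        raise RuntimeError("could not place a point with the required separation")

    for tag, count in counts:
        for i in range(count):
            x, y = _sample_core()
            accepted.append((x, y))
            lat, lon = offset_latlon(clat, clon, x, y)
            places.append(
                Place(f"{tag}-{i:03d}", float(lat), float(lon), _PLACE_RADIUS[tag], tag)
            )
    for i in range(config.n_out_of_town):
        km = rng.uniform(*config.out_of_town_km)
        th = rng.random() * 2 * np.pi
        x, y = km * 1000 * np.cos(th), km * 1000 * np.sin(th)
        lat, lon = offset_latlon(clat, clon, x, y)
        places.append(Place(f"oot-house-{i:03d}", float(lat), float(lon), 60.0, "house"))
    return PlaceMap(places, config.town_center, config.town_radius_m)


def true_class(place_id: str, place_map: PlaceMap, home_place_id: str | None) -> str:
    """Ground-truth semantic class of a place for a given participant."""
    p = place_map[place_id]
    if place_map.is_out_of_town(p.lat, p.lon):
        return "OutOfTown"
    if p.tag == "house":
        return "Home" if place_id == home_place_id else "OtherHouses"
    return {
        "education": "Education",
        "leisure": "Leisure",
        "food": "Food",
        "supermarket": "Supermarket",
        "religious": "Religious",
        "service": "Service",
    }[p.tag]


# ---------------------------------------------------------------------------
# SIAS sampling


def sample_sias(
    n: int,
    seed: int | np.random.Generator | None = None,
    mean: float = SIAS_MEAN,
    sd: float = SIAS_SD,
    lo: int = 11,
    hi: int = 54,
) -> np.ndarray:
    """Integer SIAS totals from a truncated normal on [lo, hi]."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if lo > hi:
        raise ValueError("lo must be <= hi")
    if n == 0:
        return np.array([], dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws), lo, hi).astype(int)


# ---------------------------------------------------------------------------
# behaviour profiles


# day-of-week weights concentrating the SIAS effect on the socially loaded
# evenings (Friday/Saturday); each day-type's weights average to 1 so the
# marginal weekday/weekend effect keeps its configured size
_LEISURE_DOW_W = (0.5, 0.5, 0.5, 0.5, 3.0, 1.8, 0.2)
_OTHERHOUSES_DOW_W = (1.0, 1.0, 1.0, 1.0, 1.0, 1.8, 0.2)


@dataclass
class BehaviorProfile:
    """Per-participant routine parameters (expected dwell minutes etc.)."""

    participant_id: str
    sias_total: int
    z: float
    home_place_id: str
    routine: dict[str, list[str]]  # tag/category -> routine place ids
    expected: dict[tuple[str, str], float]  # (category, "wd"|"we") -> minutes
    oot_prob_we: float
    friday_leisure_mult: float
    wake_h_mean: float
    lunch_minutes: float
    # (base + intercept, slope*z) splits for the day-of-week-weighted effects
    leisure_parts: dict[str, tuple[float, float]] = field(default_factory=dict)
    otherhouses_parts: dict[str, tuple[float, float]] = field(default_factory=dict)
    # day-to-day routine variability: sigma of a mean-one lognormal factor
    # applied to each day's activity budget (rigid routines at high SIAS)
    day_sigma: float = 0.45
    # habitual weekly routine: dow -> {"day": [...], "evening": [...]} where
    # each item is (category, place_id, mean_duration_s); drawn once per
    # participant so that days repeat weekly up to duration noise
    template: dict[int, dict[str, list[tuple[str, str, float]]]] = field(
        default_factory=dict
    )
    lunch_dows: frozenset[int] = frozenset()

    def evening_activity_minutes(
        self, day_type: str, dow: int | None = None, friday: bool = False
    ) -> dict[str, float]:
        """Expected minutes per activity category in the 4 pm-12 am window.

        ``dow`` applies the day-of-week effect weights; None uses the
        day-type marginal (weight 1).
        """
        e = self.expected

        def _weighted(parts, weights, fallback):
            if not parts:
                return fallback
            base, slopez = parts[day_type]
            w = 1.0 if dow is None else weights[dow]
            return max(0.0, base + w * slopez)

        leisure = _weighted(self.leisure_parts, _LEISURE_DOW_W,
                            e[("leisure", day_type)])
        leisure *= 0.6 if day_type == "we" else 1.0
        if friday:
            leisure *= self.friday_leisure_mult
        otherh = _weighted(self.otherhouses_parts, _OTHERHOUSES_DOW_W,
                           e[("otherhouses", day_type)])
        food = e[("food", day_type)] * (0.4 if day_type == "wd" else 0.6)
        out = {
            "leisure": leisure,
            "food": food,
            "supermarket": e[("supermarket", day_type)],
            "religious": e[("religious", day_type)] if day_type == "wd" else 0.0,
            "service": e[("service", day_type)],
            "otherhouses": otherh,
        }
        return out

    def expected_evening_home_minutes(self, day_type: str) -> float:
        """Expected 4 pm-12 am home minutes implied by the routine model."""
        acts = self.evening_activity_minutes(day_type)
        travel_budget = 12.0 * sum(1 for v in acts.values() if v > 1)
        return max(0.0, 480.0 - sum(acts.values()) - travel_budget)


def _clamp(minutes: float, label: str, clamped: list[str]) -> float:
    if minutes < 0:
        clamped.append(label)
        return 0.0
    return minutes


def build_profile(
    sias_total: int,
    place_map: PlaceMap,
    effects: EffectConfig,
    seed: int | np.random.Generator,
    participant_id: str = "p000",
    home_place_id: str | None = None,
    friend_home_ids: list[str] | None = None,
    intercept_scale: float = 1.0,
) -> BehaviorProfile:
    """Build a routine profile whose expectations shift linearly with SIAS.

    ``intercept_scale`` scales the per-participant random intercepts (0
    makes two profiles with the same seed differ only through SIAS).
    Negative expected dwell after applying slopes is clamped at 0 (logged).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = (sias_total - SIAS_MEAN) / SIAS_SD

    in_town_houses = [
        p for p in place_map.with_tag("house")
        if not place_map.is_out_of_town(p.lat, p.lon)
    ]
    if home_place_id is None:
        home_place_id = in_town_houses[int(rng.integers(len(in_town_houses)))].place_id
    if friend_home_ids is None:
        pool = [p.place_id for p in in_town_houses if p.place_id != home_place_id]
        k = min(3, len(pool))
        friend_home_ids = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    def ic(sd: float) -> float:
        return float(rng.normal(0.0, sd * intercept_scale))

    clamped: list[str] = []
    e: dict[tuple[str, str], float] = {}
    e[("education", "wd")] = max(0.0, 345.0 + ic(25.0))
    e[("education", "we")] = _clamp(105.0 + effects.education_we * z + ic(30.0),
                                    "education/we", clamped)
    leisure_parts = {
        "wd": (35.0 + ic(10.0), effects.leisure_evening_wd * z),
        "we": (70.0 + ic(15.0), effects.leisure_we * z),
    }
    e[("leisure", "wd")] = _clamp(sum(leisure_parts["wd"]), "leisure/wd", clamped)
    e[("leisure", "we")] = _clamp(sum(leisure_parts["we"]), "leisure/we", clamped)
    e[("leisure_morning", "we")] = _clamp(
        6.0 + effects.leisure_morning_we * z + ic(3.0), "leisure_morning/we", clamped
    )
    e[("food", "wd")] = _clamp(30.0 + effects.food_wd * z + ic(6.0), "food/wd", clamped)
    e[("food", "we")] = _clamp(24.0 + effects.food_we * z + ic(6.0), "food/we", clamped)
    e[("supermarket", "wd")] = _clamp(4.0 + effects.supermarket_wd * z + ic(2.0),
                                      "supermarket/wd", clamped)
    e[("supermarket", "we")] = _clamp(13.0 + effects.supermarket_we * z + ic(3.0),
                                      "supermarket/we", clamped)
    e[("religious", "wd")] = _clamp(3.0 + 0.4 * effects.religious * z + ic(1.5),
                                    "religious/wd", clamped)
    e[("religious", "we")] = _clamp(6.0 + effects.religious * z + ic(2.0),
                                    "religious/we", clamped)
    e[("service", "wd")] = _clamp(4.0 + effects.service * z + ic(2.0), "service/wd", clamped)
    e[("service", "we")] = _clamp(6.0 + effects.service * z + ic(2.0), "service/we", clamped)
    otherhouses_parts = {
        "wd": (21.0 + ic(8.0), effects.otherhouses_wd * z),
        "we": (40.0 + ic(12.0), effects.otherhouses_we * z),
    }
    e[("otherhouses", "wd")] = _clamp(sum(otherhouses_parts["wd"]),
                                      "otherhouses/wd", clamped)
    e[("otherhouses", "we")] = _clamp(sum(otherhouses_parts["we"]),
                                      "otherhouses/we", clamped)
    if clamped:
        logger.warning(
            "profile %s: expected dwell clamped at 0 for %s",
            participant_id, ", ".join(clamped),
        )

    def _routine(tag: str, base: float) -> list[str]:
        ids = sorted(p.place_id for p in place_map.with_tag(tag)
                     if not place_map.is_out_of_town(p.lat, p.lon))
        k = len(ids)
        size = int(np.clip(np.floor(base - effects.entropy_narrowing * z), 1, k))
        pick = rng.choice(k, size=size, replace=False)
        return [ids[i] for i in sorted(pick)]

    routine = {
        "education": _routine("education", 2.5),
        "leisure": _routine("leisure", 4.5),
        "food": _routine("food", 4.5),
        "supermarket": _routine("supermarket", 1.5),
        "religious": _routine("religious", 1.2),
        "service": _routine("service", 1.8),
        "otherhouses": list(friend_home_ids),
        "outoftown": sorted(
            p.place_id for p in place_map.places
            if place_map.is_out_of_town(p.lat, p.lon)
        ),
    }

    oot_prob = float(np.clip(0.18 + effects.outoftown_prob_we * z + ic(0.04), 0.02, 0.85))
    mult = 1.0 + max(0.0, effects.friday_leisure_base - effects.friday_leisure_slope * z)
    profile = BehaviorProfile(
        participant_id=participant_id,
        sias_total=int(sias_total),
        z=z,
        home_place_id=home_place_id,
        routine=routine,
        expected=e,
        oot_prob_we=oot_prob,
        friday_leisure_mult=mult,
        wake_h_mean=7.3,
        lunch_minutes=max(0.0, 0.6 * e[("food", "wd")]),
        leisure_parts=leisure_parts,
        otherhouses_parts=otherhouses_parts,
        day_sigma=float(np.clip(0.5 - effects.day_variability * z, 0.12, 1.0)),
    )
    _draw_weekly_template(profile, rng)
    return profile


# ---------------------------------------------------------------------------
# day simulation


def _place_xy(place_map: PlaceMap, pid: str) -> tuple[float, float]:
    p = place_map[pid]
    return p.lat, p.lon


def _travel_s(place_map: PlaceMap, a: str, b: str) -> float:
    if a == b:
        return 0.0
    d = haversine_m(_place_xy(place_map, a), _place_xy(place_map, b))
    if d < 1200:
        return d / _WALK_MS
    if d < 2500:
        return d / _BIKE_MS
    return d / _DRIVE_MS


class _DayBuilder:
    """Assembles a day's stay/travel schedule (seconds from midnight)."""

    def __init__(self, place_map: PlaceMap, home: str):
        self.pmap = place_map
        self.home = home
        self.cur = home
        self.t = 0.0
        self.stays: list[tuple[str, float, float]] = []
        self.travels: list[tuple[float, float, str, str]] = []
        self.latest = 23.8 * 3600

    def stay(self, pid: str, dur: float) -> bool:
        tt = _travel_s(self.pmap, self.cur, pid)
        tt_home = _travel_s(self.pmap, pid, self.home)
        avail = self.latest - self.t - tt - tt_home
        dur = min(dur, avail)
        if dur < 600.0:
            return False
        if tt > 0:
            self.travels.append((self.t, self.t + tt, self.cur, pid))
            self.t += tt
        start = self.t
        self.t += dur
        if self.stays and self.stays[-1][0] == pid and self.stays[-1][2] >= start:
            p0, s0, _ = self.stays.pop()
            self.stays.append((p0, s0, self.t))
        else:
            self.stays.append((pid, start, self.t))
        self.cur = pid
        return True

    def stay_until(self, pid: str, end_s: float) -> bool:
        return self.stay(pid, end_s - self.t - _travel_s(self.pmap, self.cur, pid))

    def finish(self) -> None:
        if self.cur != self.home:
            tt = _travel_s(self.pmap, self.cur, self.home)
            self.travels.append((self.t, self.t + tt, self.cur, self.home))
            self.t += tt
            self.cur = self.home
        if self.t < DAY_S:
            if self.stays and self.stays[-1][0] == self.home and self.stays[-1][2] >= self.t:
                p0, s0, _ = self.stays.pop()
                self.stays.append((p0, s0, float(DAY_S)))
            else:
                self.stays.append((self.home, self.t, float(DAY_S)))
        self.t = float(DAY_S)


def _pick(rng: np.random.Generator, ids: list[str]) -> str:
    return ids[int(rng.integers(len(ids)))]


def _draw_weekly_template(profile: BehaviorProfile, rng: np.random.Generator) -> None:
    """Draw the participant's habitual weekly routine, once.

    Which activities happen on which day of the week (and at which habitual
    places) is fixed for the whole study; only durations and occasional
    deviations vary day to day.  Occurrence probabilities are chosen so
    that expected dwell minutes match the profile's routine model.
    """
    template: dict[int, dict[str, list[tuple[str, str, float]]]] = {}
    lunch_dows: set[int] = set()
    exp = profile.expected
    routine = profile.routine
    for dow in range(7):
        we = dow >= 5
        dt = "we" if we else "wd"
        day_items: list[tuple[str, str, float]] = []
        if not we:
            if profile.lunch_minutes >= 10 and rng.random() < min(
                0.95, profile.lunch_minutes / 40.0
            ):
                lunch_dows.add(dow)
        else:
            if dow == 6 and exp[("religious", "we")] > 1:
                p = min(0.95, exp[("religious", "we")] / _TYPICAL_MIN["religious"])
                if rng.random() < p:
                    day_items.append(
                        ("religious", _pick(rng, routine["religious"]),
                         exp[("religious", "we")] / p * 60.0)
                    )
            lm = exp.get(("leisure_morning", "we"), 0.0)
            if lm > 1:
                p = min(0.9, lm / 40.0)
                if rng.random() < p:
                    day_items.append(
                        ("leisure", _pick(rng, routine["leisure"]), lm / p * 60.0)
                    )
            school_min = exp[("education", "we")]
            edu_p = min(0.9, school_min / 150.0)
            if school_min > 15 and rng.random() < edu_p:
                day_items.append(
                    ("education", _pick(rng, routine["education"]),
                     float(np.clip(school_min * 60.0 / edu_p, 1800.0, 5.0 * 3600)))
                )
            if rng.random() < profile.oot_prob_we:
                day_items.append(
                    ("outoftown", _pick(rng, routine["outoftown"]), 150 * 60.0)
                )
            lunch_p = min(0.9, exp[("food", "we")] * 0.4 / _TYPICAL_MIN["food"])
            if rng.random() < lunch_p:
                day_items.append(
                    ("food", _pick(rng, routine["food"]),
                     exp[("food", "we")] * 0.4 / lunch_p * 60.0)
                )

        acts = profile.evening_activity_minutes(dt, dow=dow, friday=dow in (4, 5))
        evening_items: list[tuple[str, str, float]] = []
        m = acts["supermarket"]
        if m > 1:
            p = min(0.95, m / _TYPICAL_MIN["supermarket"])
            if rng.random() < p:
                evening_items.append(
                    ("supermarket", _pick(rng, routine["supermarket"]), m / p * 60.0)
                )
        m = acts["leisure"]
        if m > 1:
            n_vis = min(int(rng.poisson(m / _TYPICAL_MIN["leisure"])), 3)
            for _ in range(n_vis):
                evening_items.append(
                    ("leisure", _pick(rng, routine["leisure"]),
                     _TYPICAL_MIN["leisure"] * 60.0)
                )
        others: list[tuple[str, str, float]] = []
        for cat in ("food", "otherhouses", "religious", "service"):
            m = acts[cat]
            if m <= 1:
                continue
            p = min(0.9, m / _TYPICAL_MIN[cat])
            if rng.random() < p:
                others.append((cat, _pick(rng, routine[cat]), m / p * 60.0))
        if others:
            order = rng.permutation(len(others))
            others = [others[i] for i in order]
        template[dow] = {"day": day_items, "evening": evening_items + others}
    profile.template = template
    profile.lunch_dows = frozenset(lunch_dows)


def _schedule_day(profile: BehaviorProfile, place_map: PlaceMap, dow: int,
                  rng: np.random.Generator):
    """Build one day's stay/travel schedule from the weekly routine template.

    Durations get gamma noise times a mean-one lognormal day factor (wider
    for low-SIAS/erratic routines); items are occasionally skipped, and
    erratic participants sometimes add an unplanned evening outing.
    """
    we = dow >= 5
    dt = "we" if we else "wd"
    b = _DayBuilder(place_map, profile.home_place_id)
    exp = profile.expected
    tmpl = profile.template.get(dow, {"day": [], "evening": []})
    v = profile.day_sigma
    day_factor = float(rng.lognormal(-0.5 * v * v, v))
    p_skip = 0.08

    def _dur(mean_s: float, lo: float = 600.0, hi: float = 3.5 * 3600) -> float:
        return float(np.clip(rng.gamma(6.0, mean_s / 6.0) * day_factor, lo, hi))

    # -- daytime block
    wake = float(np.clip(rng.normal(profile.wake_h_mean + (1.5 if we else 0.0), 0.4),
                         6.2, 11.0)) * 3600
    leave = wake + rng.uniform(900, 2400)
    school_min = exp[("education", "wd")]
    if not we and school_min > 15:
        b.stay(profile.home_place_id, leave)
        edu = profile.routine["education"]
        lunch_t = float(rng.normal(12.1, 0.3)) * 3600
        school_end = float(np.clip(rng.normal(15.7, 0.5), 14.5, 16.5)) * 3600
        if dow in profile.lunch_dows:
            b.stay_until(edu[0], lunch_t)
            b.stay(profile.routine["food"][0],
                   max(600.0, rng.gamma(6.0, profile.lunch_minutes * 60 / 6.0)))
            b.stay_until(edu[-1], school_end)
        else:
            b.stay_until(edu[0], school_end)
    else:
        b.stay(profile.home_place_id, leave)
        for cat, pid, mean in tmpl["day"]:
            if rng.random() < p_skip:
                continue
            lo, hi = (3600.0, 6.0 * 3600) if cat == "outoftown" else (600.0, 5.0 * 3600)
            b.stay(pid, _dur(mean, lo, hi))
            if rng.random() < 0.4:  # home pause between daytime outings
                b.stay(profile.home_place_id, rng.uniform(1800, 4800))

    # -- evening block (4 pm-12 am)
    items = [it for it in tmpl["evening"] if rng.random() >= p_skip]
    # unplanned extra outing: more likely the more erratic the routine
    p_extra = min(0.6, max(0.0, 0.9 * (v - 0.15)))
    if rng.random() < p_extra:
        cat = ("leisure", "food")[int(rng.integers(2))]
        items.append(
            (cat, _pick(rng, profile.routine[cat]), _TYPICAL_MIN[cat] * 60.0)
        )
    if items:
        pause_end = float(np.clip(rng.normal(17.6, 0.8), 16.2, 19.5)) * 3600
        if b.t < pause_end - 900:
            b.stay(profile.home_place_id, pause_end - b.t - 300)
        for cat, pid, mean in items:
            if not b.stay(pid, _dur(mean)):
                break
    b.finish()
    return b.stays, b.travels


def simulate_day(
    profile: BehaviorProfile,
    place_map: PlaceMap,
    date: _date,
    seed: int | np.random.Generator,
    jitter_sigma_m: float = 10.0,
    interval_s: int = NOMINAL_INTERVAL_S,
):
    """Simulate one day: (times, lats, lons, gt_stays, gt_transitions).

    GPS points lie on the nominal sampling grid; stay points are jittered
    around the place centroid, transition points around the straight-line
    interpolant.  Ground truth mirrors the emitted schedule exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    day_epoch = int(datetime(date.year, date.month, date.day, tzinfo=timezone.utc).timestamp())
    stays, travels = _schedule_day(profile, place_map, date.weekday(), rng)
    if any(e > DAY_S + 1 for _, _, e in stays):
        raise RuntimeError("schedule exceeds 24 h")

    grid = np.arange(0, DAY_S, interval_s, dtype=np.int64)
    times_l, lats_l, lons_l = [], [], []
    segs = [("stay", s, e, pid, pid) for pid, s, e in stays] + [
        ("travel", s, e, a, bb) for s, e, a, bb in travels
    ]
    segs.sort(key=lambda x: x[1])
    for kind, s, e, a, bb in segs:
        lo = int(np.searchsorted(grid, s, side="left"))
        hi = int(np.searchsorted(grid, e, side="left"))
        if hi <= lo:
            continue
        g = grid[lo:hi]
        if kind == "stay":
            lat0, lon0 = _place_xy(place_map, a)
            lat = np.full(len(g), lat0)
            lon = np.full(len(g), lon0)
        else:
            lat0, lon0 = _place_xy(place_map, a)
            lat1, lon1 = _place_xy(place_map, bb)
            frac = (g - s) / max(1.0, (e - s))
            lat = lat0 + (lat1 - lat0) * frac
            lon = lon0 + (lon1 - lon0) * frac
        if jitter_sigma_m > 0:
            east = rng.normal(0.0, jitter_sigma_m, len(g))
            north = rng.normal(0.0, jitter_sigma_m, len(g))
            lat = lat + np.degrees(north / 6_371_000.0)
            lon = lon + np.degrees(
                east / (6_371_000.0 * np.cos(np.radians(lat0)))
            )
        times_l.append(g + day_epoch)
        lats_l.append(lat)
        lons_l.append(lon)

    times = np.concatenate(times_l) if times_l else np.array([], dtype=np.int64)
    lats = np.concatenate(lats_l) if lats_l else np.array([])
    lons = np.concatenate(lons_l) if lons_l else np.array([])
    order = np.argsort(times, kind="stable")
    times, lats, lons = times[order], lats[order], lons[order]

    gt_stays = [
        GroundTruthStay(
            place_id=pid,
            cls=true_class(pid, place_map, profile.home_place_id),
            start=int(round(s)) + day_epoch,
            end=int(round(e)) + day_epoch,
        )
        for pid, s, e in stays
    ]
    gt_trans = [(int(round(s)) + day_epoch, int(round(e)) + day_epoch) for s, e, _, _ in travels]
    return times, lats, lons, gt_stays, gt_trans


def inject_gaps(
    trace: ParticipantTrace,
    gap_config: GapConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[ParticipantTrace, list[tuple[int, int]]]:
    """Remove points inside sampled (or forced) gap windows."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals: list[tuple[int, int]] = [tuple(map(int, g)) for g in gap_config.forced]
    active = gap_config.rate_per_day > 0 or gap_config.patchy_day_prob > 0
    if active and len(trace) > 1:
        first_day = int(trace.times[0] // DAY_S)
        last_day = int(trace.times[-1] // DAY_S)
        for day in range(first_day, last_day + 1):
            ds, de = day * DAY_S, (day + 1) * DAY_S
            patchy = rng.random() < gap_config.patchy_day_prob
            rate = gap_config.patchy_rate_per_day if patchy else gap_config.rate_per_day
            probs = np.asarray(
                gap_config.patchy_regime_probs if patchy else gap_config.regime_probs,
                dtype=float,
            )
            probs = probs / probs.sum()
            for _ in range(int(rng.poisson(rate))):
                start = int(rng.integers(ds, de))
                regime = rng.choice(3, p=probs)
                if regime == 0:
                    dur = rng.uniform(120, 300)
                elif regime == 1:
                    dur = rng.uniform(360, 1680)
                else:
                    dur = rng.uniform(1920, 4800)
                intervals.append((start, start + int(dur)))
    if not intervals:
        return trace, []
    keep = np.ones(len(trace), dtype=bool)
    for s, e in intervals:
        keep &= ~((trace.times >= s) & (trace.times < e))
    out = ParticipantTrace(
        trace.participant_id,
        trace.times[keep],
        trace.lats[keep],
        trace.lons[keep],
        trace.nominal_interval,
    )
    return out, sorted(intervals)


def generate_cohort(config: CohortConfig, seed: int) -> CohortBundle:
    """Generate a full cohort bundle, deterministic in (config, seed)."""
    if config.n_participants <= 0:
        raise ValueError("n_participants must be positive")
    ss = np.random.SeedSequence(seed)
    map_ss, sias_ss, assign_ss, part_ss = ss.spawn(4)
    place_map = generate_map(config.map, np.random.default_rng(map_ss),
                             n_participants=config.n_participants)
    sias_vals = sample_sias(
        config.n_participants, np.random.default_rng(sias_ss),
        config.sias_mean, config.sias_sd, config.sias_min, config.sias_max,
    )
    in_town_houses = sorted(
        p.place_id for p in place_map.with_tag("house")
        if not place_map.is_out_of_town(p.lat, p.lon)
    )
    arng = np.random.default_rng(assign_ss)
    home_order = arng.permutation(len(in_town_houses))

    sias: dict[str, int] = {}
    traces: dict[str, ParticipantTrace] = {}
    gts: dict[str, ParticipantGroundTruth] = {}
    child_seeds = part_ss.spawn(config.n_participants)
    for i in range(config.n_participants):
        pid = f"p{i:03d}"
        prng = np.random.default_rng(child_seeds[i])
        home = in_town_houses[int(home_order[i % len(in_town_houses)])]
        others = [h for h in in_town_houses if h != home]
        fr_idx = prng.choice(len(others), size=min(3, len(others)), replace=False)
        friends = [others[j] for j in sorted(fr_idx)]
        profile = build_profile(
            int(sias_vals[i]), place_map, config.effects, prng,
            participant_id=pid, home_place_id=home, friend_home_ids=friends,
        )
        all_t, all_la, all_lo = [], [], []
        gt = ParticipantGroundTruth(home_place_id=home)
        for d in range(config.n_days):
            day = config.start_date + timedelta(days=d)
            tms, la, lo, gst, gtr = simulate_day(
                profile, place_map, day, prng,
                jitter_sigma_m=config.noise.jitter_sigma_m,
            )
            all_t.append(tms)
            all_la.append(la)
            all_lo.append(lo)
            gt.stays.extend(gst)
            gt.transitions.extend(gtr)
        trace = ParticipantTrace(
            pid, np.concatenate(all_t), np.concatenate(all_la), np.concatenate(all_lo)
        )
        trace, gap_ivs = inject_gaps(trace, config.noise.gaps, prng)
        gt.gaps = gap_ivs
        sias[pid] = int(sias_vals[i])
        traces[pid] = trace
        gts[pid] = gt
    return CohortBundle(
        config=config, seed=seed, place_map=place_map,
        sias=sias, traces=traces, ground_truth=gts,
    )
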