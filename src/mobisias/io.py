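"""Trace data model, readers/writers, and SIAS scoring.

The on-disk trace dialects are:

* CSV with header ``participant_id,timestamp,lat,lon`` and ISO-8601 UTC
  timestamps (second resolution), and
* GeoJSON (RFC 7946) FeatureCollections of Point features carrying a
  ``timestamp`` property.

Both round-trip exactly: timestamps to the second, coordinates to 1e-7
degrees.  SIAS (Social Interaction Anxiety Scale) scoring follows the
instrument definition: 20 items rated 0-4, total 0-80, with the clinical
cutoff of 34 separating high from low social anxiety.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GpsPoint",
    "ParticipantTrace",
    "SiasResponse",
    "SiasScore",
    "TraceValidationError",
    "SIAS_CUTOFF",
    "read_trace",
    "write_trace",
    "score_sias",
    "classify_sias",
    "read_manifest",
    "write_manifest",
]

SIAS_CUTOFF = 34
NOMINAL_INTERVAL_S = 150


class TraceValidationError(ValueError):
    """Raised for malformed or out-of-contract trace/SIAS inputs."""


@dataclass(frozen=True)
class GpsPoint:
    """One timestamped GPS fix (UTC, second resolution)."""

    timestamp: datetime
    lat: float
    lon: float

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0):
            raise TraceValidationError(f"latitude {self.lat} out of [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise TraceValidationError(f"longitude {self.lon} out of [-180, 180]")


def _to_epoch(ts: datetime) -> int:
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return int(ts.timestamp())


def _from_epoch(t: int) -> datetime:
    return datetime.fromtimestamp(int(t), tz=timezone.utc)


class ParticipantTrace:
    """A time-ordered GPS trace for one participant.

    Stored internally as numpy arrays (epoch seconds, lat, lon) for speed;
    the ``points`` property materialises :class:`GpsPoint` objects.
    Timestamps must be strictly increasing; duplicates are rejected.
    """

    __slots__ = ("participant_id", "times", "lats", "lons", "nominal_interval")

    def __init__(
        self,
        participant_id: str,
        times: Iterable[int] | np.ndarray,
        lats: Iterable[float] | np.ndarray,
        lons: Iterable[float] | np.ndarray,
        nominal_interval: int = NOMINAL_INTERVAL_S,
    ):
        self.participant_id = str(participant_id)
        self.times = np.asarray(times, dtype=np.int64)
        self.lats = np.asarray(lats, dtype=np.float64)
        self.lons = np.asarray(lons, dtype=np.float64)
        self.nominal_interval = int(nominal_interval)
        if not (len(self.times) == len(self.lats) == len(self.lons)):
            raise TraceValidationError("times/lats/lons length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise TraceValidationError(
                    f"timestamps not strictly increasing at index {i + 1}"
                )
        if len(self.lats) and (
            self.lats.min() < -90 or self.lats.max() > 90
            or self.lons.min() < -180 or self.lons.max() > 180
        ):
            raise TraceValidationError("coordinate out of bounds")

    @classmethod
    def from_points(
        cls,
        participant_id: str,
        points: Sequence[GpsPoint],
        nominal_interval: int = NOMINAL_INTERVAL_S,
    ) -> "ParticipantTrace":
        return cls(
            participant_id,
            [_to_epoch(p.timestamp) for p in points],
            [p.lat for p in points],
            [p.lon for p in points],
            nominal_interval,
        )

    @property
    def points(self) -> list[GpsPoint]:
        return [
            GpsPoint(_from_epoch(t), float(la), float(lo))
            for t, la, lo in zip(self.times, self.lats, self.lons)
        ]

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParticipantTrace):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and np.array_equal(self.times, other.times)
            and np.allclose(self.lats, other.lats, atol=1e-7, rtol=0)
            and np.allclose(self.lons, other.lons, atol=1e-7, rtol=0)
        )


@dataclass(frozen=True)
class SiasResponse:
    """A complete SIAS questionnaire response: 20 items each rated 0-4."""

    items: tuple[int, ...]

    def __post_init__(self):
        if len(self.items) != 20:
            raise TraceValidationError(f"SIAS requires 20 items, got {len(self.items)}")
        for i, v in enumerate(self.items):
            if v not in (0, 1, 2, 3, 4):
                raise TraceValidationError(f"item {i} rating {v} outside {{0..4}}")


@dataclass(frozen=True)
class SiasScore:
    total: int
    group: str  # "high" | "low"
    cutoff: int = SIAS_CUTOFF


def score_sias(resp: SiasResponse) -> int:
    """Total SIAS score: the sum of the 20 item ratings (0-80)."""
    return int(sum(resp.items))


def classify_sias(total: int, cutoff: int = SIAS_CUTOFF) -> str:
    """Classify a total SIAS score as ``"high"`` (>= cutoff) or ``"low"``."""
    if not (0 <= total <= 80):
        raise TraceValidationError(f"SIAS total {total} outside [0, 80]")
    return "high" if total >= cutoff else "low"


def sias_score(total: int, cutoff: int = SIAS_CUTOFF) -> SiasScore:
    return SiasScore(total=int(total), group=classify_sias(total, cutoff), cutoff=cutoff)


# ---------------------------------------------------------------------------
# trace readers / writers

_CSV_COLUMNS = ["participant_id", "timestamp", "lat", "lon"]


def _format_times(times: np.ndarray) -> list[str]:
    return [
        datetime.fromtimestamp(int(t), tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")
        for t in times
    ]


def read_trace(path: str | Path, format: str | None = None) -> ParticipantTrace:
    """Read a validated trace from CSV or GeoJSON.

    The format is inferred from the suffix when not given.  Malformed rows
    raise :class:`TraceValidationError` naming the offending line/feature.
    """
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    if fmt == "csv":
        return _read_trace_csv(path)
    if fmt == "geojson":
        return _read_trace_geojson(path)
    raise ValueError(f"unknown trace format {fmt!r}")


def _read_trace_csv(path: Path) -> ParticipantTrace:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraceValidationError(f"{path}: missing columns {missing}")
    if df.empty:
        return ParticipantTrace("", [], [], [])
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as e:
        raise TraceValidationError(f"{path}: unparseable timestamp ({e})") from e
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = lat.isna() | lon.isna() | ts.isna()
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 1-based
        raise TraceValidationError(f"{path}: malformed row at line {line}")
    pids = df["participant_id"].unique()
    if len(pids) > 1:
        raise TraceValidationError(f"{path}: multiple participant_ids {list(pids)}")
    return ParticipantTrace(
        pids[0],
        (ts.astype("int64") // 10**9).to_numpy(),
        lat.to_numpy(),
        lon.to_numpy(),
    )


def _read_trace_geojson(path: Path) -> ParticipantTrace:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise TraceValidationError(f"{path}: not a FeatureCollection")
    pid = str(data.get("participant_id", ""))
    times, lats, lons = [], [], []
    for i, feat in enumerate(data.get("features", [])):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        if geom.get("type") != "Point" or "timestamp" not in props:
            raise TraceValidationError(f"{path}: feature {i} is not a timestamped Point")
        lon, lat = geom["coordinates"][:2]
        ts = pd.Timestamp(props["timestamp"])
        if ts.tzinfo is None:
            ts = ts.tz_localize("UTC")
        times.append(int(ts.timestamp()))
        lats.append(float(lat))
        lons.append(float(lon))
    return ParticipantTrace(pid, times, lats, lons)


def write_trace(trace: ParticipantTrace, path: str | Path, format: str | None = None) -> Path:
    """Write a trace to CSV or GeoJSON so that ``read_trace`` round-trips it."""
    path = Path(path)
    fmt = format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")
    if fmt == "csv":
        df = pd.DataFrame(
            {
                "participant_id": trace.participant_id,
                "timestamp": _format_times(trace.times),
                "lat": np.round(trace.lats, 7),
                "lon": np.round(trace.lons, 7),
            },
            columns=_CSV_COLUMNS,
        )
        df.to_csv(path, index=False)
    elif fmt == "geojson":
        feats = [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [round(float(lo), 7), round(float(la), 7)],
                },
                "properties": {"timestamp": ts},
            }
            for ts, la, lo in zip(_format_times(trace.times), trace.lats, trace.lons)
        ]
        obj = {
            "type": "FeatureCollection",
            "participant_id": trace.participant_id,
            "features": feats,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    return path


def write_manifest(scores: dict[str, int], path: str | Path) -> Path:
    """Write the cohort manifest CSV (``participant_id,sias_total``)."""
    df = pd.DataFrame(
        {"participant_id": list(scores), "sias_total": [scores[p] for p in scores]}
    )
    df.to_csv(path, index=False)
    return Path(path)


def read_manifest(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    return dict(zip(df["participant_id"], df["sias_total"].astype(int)))
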