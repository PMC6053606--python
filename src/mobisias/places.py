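"""Place map: the geodatabase stand-in used for semantic labeling.

A :class:`PlaceMap` holds places with circular footprints and raw category
tags (the closed tag vocabulary below), plus a town center and radius used
to decide whether a stay is out of town.  It serializes to GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geo import haversine_m, haversine_vec_m

__all__ = ["Place", "PlaceMap", "TAG_VOCABULARY", "UnknownTagError"]

#: Closed vocabulary of raw place tags.
TAG_VOCABULARY = frozenset(
    {"house", "education", "leisure", "food", "supermarket", "religious", "service"}
)


class UnknownTagError(ValueError):
    """A place carries a tag outside the declared vocabulary."""


@dataclass(frozen=True)
class Place:
    place_id: str
    lat: float
    lon: float
    radius_m: float
    tag: str

    def __post_init__(self):
        if self.radius_m <= 0:
            raise ValueError(f"place {self.place_id}: radius must be > 0")
        if self.tag not in TAG_VOCABULARY:
            raise UnknownTagError(f"place {self.place_id}: unknown tag {self.tag!r}")


class PlaceMap:
    """A set of places plus the town geometry."""

    def __init__(self, places: list[Place], town_center: tuple[float, float],
                 town_radius_m: float):
        if town_radius_m <= 0:
            raise ValueError("town_radius_m must be > 0")
        self.places = sorted(places, key=lambda p: p.place_id)
        self.town_center = (float(town_center[0]), float(town_center[1]))
        self.town_radius_m = float(town_radius_m)
        self._by_id = {p.place_id: p for p in self.places}
        if len(self._by_id) != len(self.places):
            raise ValueError("duplicate place_id in map")
        self._lats = np.array([p.lat for p in self.places])
        self._lons = np.array([p.lon for p in self.places])
        self._radii = np.array([p.radius_m for p in self.places])

    def __len__(self) -> int:
        return len(self.places)

    def __getitem__(self, place_id: str) -> Place:
        return self._by_id[place_id]

    def __contains__(self, place_id: str) -> bool:
        return place_id in self._by_id

    def distances_m(self, lat: float, lon: float) -> np.ndarray:
        """Distance from (lat, lon) to every place centroid, in map order."""
        return haversine_vec_m(lat, lon, self._lats, self._lons)

    def footprint_radii(self) -> np.ndarray:
        return self._radii

    def is_out_of_town(self, lat: float, lon: float) -> bool:
        return haversine_m((lat, lon), self.town_center) > self.town_radius_m

    def with_tag(self, tag: str) -> list[Place]:
        return [p for p in self.places if p.tag == tag]

    # -- GeoJSON serialization ------------------------------------------------

    def to_geojson(self, path: str | Path) -> Path:
        obj = {
            "type": "FeatureCollection",
            "town_center": list(self.town_center),
            "town_radius_m": self.town_radius_m,
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                    "properties": {
                        "place_id": p.place_id,
                        "tag": p.tag,
                        "radius": p.radius_m,
                    },
                }
                for p in self.places
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)
        return Path(path)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PlaceMap":
        with open(path) as fh:
            obj = json.load(fh)
        places = [
            Place(
                place_id=f["properties"]["place_id"],
                lat=f["geometry"]["coordinates"][1],
                lon=f["geometry"]["coordinates"][0],
                radius_m=f["properties"]["radius"],
                tag=f["properties"]["tag"],
            )
            for f in obj["features"]
        ]
        return cls(places, tuple(obj["town_center"]), obj["town_radius_m"])
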