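"""Great-circle migration distances.

Migration distance is the haversine (spherical great-circle) distance between
a fixed origin — the breeding-season sampling region, by default the centroid
of the Jutland peninsula — and each species' non-breeding distribution
centroid, expressed in thousands of kilometres.  Sedentary species have
distance 0 by definition.

The sphere radius defaults to the Earth's mean radius, 6371 km, and is
configurable (the choice matters at the ~0.3% level relative to an
ellipsoidal geodesic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "JUTLAND_CENTROID",
    "GeoPoint",
    "MigrationRecord",
    "haversine_km",
    "migration_distance",
    "read_centroids_csv",
]

EARTH_RADIUS_KM = 6371.0

#: Approximate centroid of the Jutland peninsula, Denmark — the default
#: origin.  A configuration value, not a physical constant: pass your own
#: origin to :func:`migration_distance` to override it.
JUTLAND_CENTROID: "GeoPoint"


class GeoPoint(NamedTuple):
    """Geographic point in decimal degrees; latitude in [-90, 90],
    longitude in (-180, 180]."""

    lat: float
    lon: float

    def validate(self) -> "GeoPoint":
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 < self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside (-180, 180]")
        return self


JUTLAND_CENTROID = GeoPoint(56.0, 9.3)


@dataclass
class MigrationRecord:
    """Migratory status and non-breeding centroid of one species."""

    species: str
    status: str  # "sedentary" or "migratory"
    centroid: Optional[GeoPoint] = None

    def __post_init__(self) -> None:
        if self.status not in ("sedentary", "migratory"):
            raise ValueError(
                f"{self.species}: status must be 'sedentary' or 'migratory', "
                f"got {self.status!r}"
            )
        if self.status == "migratory" and self.centroid is None:
            raise ValueError(
                f"{self.species}: migratory species requires a non-breeding centroid"
            )
        if self.centroid is not None:
            self.centroid.validate()


def haversine_km(a: GeoPoint, b: GeoPoint, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points on a sphere, in km.

    Standard haversine form: symmetric, non-negative, bounded by pi*R.
    """
    a = GeoPoint(*a).validate()
    b = GeoPoint(*b).validate()
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon) - math.radians(a.lon)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    # clamp for rounding at antipodes
    return 2.0 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def migration_distance(
    records: Iterable[MigrationRecord],
    origin: GeoPoint = JUTLAND_CENTROID,
    radius_km: float = EARTH_RADIUS_KM,
) -> pd.Series:
    """Per-species migration distance in thousands of km.

    Sedentary species map to exactly 0; migratory species to the haversine
    distance from ``origin`` to their non-breeding centroid divided by 1000.
    """
    origin = GeoPoint(*origin).validate()
    out = {}
    for rec in records:
        if rec.status == "sedentary":
            out[rec.species] = 0.0
        else:
            out[rec.species] = haversine_km(origin, rec.centroid, radius_km) / 1000.0
    return pd.Series(out, name="migration_distance_Mm").rename_axis("species")


def read_centroids_csv(path: str | Path) -> list[MigrationRecord]:
    """Read records from CSV with columns species, status, lat, lon
    (lat/lon blank for sedentary species)."""
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        centroid = None
        if not (pd.isna(row.lat) or pd.isna(row.lon)):
            centroid = GeoPoint(float(row.lat), float(row.lon))
        records.append(MigrationRecord(str(row.species), str(row.status), centroid))
    return records
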