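"""Demand/supply layers and planar geometry primitives.

Coordinates are planar, in meters, in a projected CRS. All distance math is
Euclidean: at sub-district scale (a few km) straight-line distance is the
study design, so no geodetic computation happens anywhere in the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

__all__ = [
    "DemandUnit",
    "Facility",
    "Region",
    "community_centroid",
    "distance_matrix",
    "within_radius",
]


def community_centroid(polygon: Polygon, unit_id: str | None = None) -> Point:
    """Area-weighted geometric center of a community polygon.

    The geometric center stands in for the (unknown) center of the elderly
    population, so a degenerate polygon is a data error, not a silent NaN.

    Parameters
    ----------
    polygon : shapely Polygon
        Simple polygon with positive area, planar coordinates in meters.
    unit_id : str, optional
        Included in the error message when the polygon is degenerate.

    Returns
    -------
    shapely Point
    """
    if not isinstance(polygon, Polygon):
        raise TypeError(f"expected a Polygon, got {type(polygon).__name__}")
    if polygon.area <= 0.0:
        label = f" for demand unit {unit_id!r}" if unit_id is not None else ""
        raise ValueError(f"degenerate (zero-area) polygon{label}: cannot derive a demand point")
    return polygon.centroid


@dataclass(frozen=True)
class DemandUnit:
    """A community: id, geometry (polygon or point) and elderly population.

    ``population`` is the head count of the target group (here: residents
    over 70). Zero is legal — campus or park communities have few elderly
    residents but still receive an accessibility score.
    """

    id: str
    geometry: BaseGeometry
    population: int

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"demand unit {self.id!r}: population must be >= 0, got {self.population}")
        if not isinstance(self.geometry, (Point, Polygon)):
            raise TypeError(f"demand unit {self.id!r}: geometry must be a Point or Polygon")
        if isinstance(self.geometry, Polygon) and self.geometry.area <= 0.0:
            raise ValueError(f"demand unit {self.id!r}: polygon is degenerate (zero area)")

    @property
    def point(self) -> Point:
        """Demand point: the polygon centroid, or the point itself."""
        if isinstance(self.geometry, Polygon):
            return community_centroid(self.geometry, self.id)
        return self.geometry


@dataclass(frozen=True)
class Facility:
    """A community care facility: id, location and bed count (the supply)."""

    id: str
    location: Point
    beds: int

    def __post_init__(self) -> None:
        if self.beds < 0:
            raise ValueError(f"facility {self.id!r}: beds must be >= 0, got {self.beds}")
        if not isinstance(self.location, Point):
            raise TypeError(f"facility {self.id!r}: location must be a Point")


def distance_matrix(demand_points: np.ndarray, facility_points: np.ndarray) -> np.ndarray:
    """Euclidean distances between demand points (rows) and facilities (columns).

    Both arguments are (n, 2) arrays of planar coordinates in meters.
    Coincident points give exact zeros.
    """
    demand_points = np.asarray(demand_points, dtype=float)
    facility_points = np.asarray(facility_points, dtype=float)
    if not (np.isfinite(demand_points).all() and np.isfinite(facility_points).all()):
        raise ValueError("non-finite coordinates in distance_matrix input")
    return cdist(demand_points.reshape(-1, 2), facility_points.reshape(-1, 2))


def within_radius(distances: np.ndarray, d0: float) -> np.ndarray:
    """Boolean catchment incidence: entry (i, j) is True iff d_ij <= d0.

    The boundary is inclusive — a facility exactly at the threshold distance
    is inside the catchment.
    """
    if not d0 > 0:
        raise ValueError(f"search radius d0 must be > 0, got {d0}")
    return np.asarray(distances, dtype=float) <= d0


@dataclass
class Region:
    """Paired demand and supply layers plus the cached distance matrix.

    ``distances[i, j]`` is the Euclidean distance in meters between the
    demand point of unit i and facility j; it is computed on construction
    and validated against the coordinates if supplied explicitly.
    """

    demand_units: Sequence[DemandUnit]
    facilities: Sequence[Facility]
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]
    crs: str | None = None  # provenance only; never used in math

    def __post_init__(self) -> None:
        self.demand_units = list(self.demand_units)
        self.facilities = list(self.facilities)
        ids = [u.id for u in self.demand_units]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate demand unit id(s): {dup}")
        fids = [f.id for f in self.facilities]
        if len(set(fids)) != len(fids):
            dup = sorted({i for i in fids if fids.count(i) > 1})
            raise ValueError(f"duplicate facility id(s): {dup}")
        computed = distance_matrix(self.demand_points, self.facility_points)
        if self.distances is None:
            self.distances = computed
        else:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != computed.shape:
                raise ValueError(
                    f"distance matrix shape {self.distances.shape} does not match "
                    f"({len(self.demand_units)}, {len(self.facilities)})"
                )
            if not np.allclose(self.distances, computed, atol=1e-6):
                raise ValueError("cached distance matrix disagrees with coordinates (tol 1e-6 m)")

    @property
    def n_demand(self) -> int:
        return len(self.demand_units)

    @property
    def n_facilities(self) -> int:
        return len(self.facilities)

    @property
    def demand_ids(self) -> list[str]:
        return [u.id for u in self.demand_units]

    @property
    def facility_ids(self) -> list[str]:
        return [f.id for f in self.facilities]

    @property
    def demand_points(self) -> np.ndarray:
        return np.array([[u.point.x, u.point.y] for u in self.demand_units], dtype=float).reshape(-1, 2)

    @property
    def facility_points(self) -> np.ndarray:
        return np.array([[f.location.x, f.location.y] for f in self.facilities], dtype=float).reshape(-1, 2)

    @property
    def populations(self) -> np.ndarray:
        """Per-demand-unit elderly population D_k (persons)."""
        return np.array([u.population for u in self.demand_units], dtype=float)

    @property
    def beds(self) -> np.ndarray:
        """Per-facility bed count S_j."""
        return np.array([f.beds for f in self.facilities], dtype=float)
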