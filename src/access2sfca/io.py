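"""Reading and writing the demand/supply layers and result tables.

Two input dialects carry identical content:

* GeoJSON FeatureCollections — demand features with Polygon or Point
  geometry and properties ``id``/``population``; supply features with Point
  geometry and ``id``/``beds``;
* attribute CSV — ``id,x,y,population`` and ``id,x,y,beds``.

Coordinates must already be planar meters (projected CRS); an optional
``crs`` string is carried through for provenance only. Output files embed
the run configuration (as a ``metadata`` member in JSON/GeoJSON, as a
leading ``#`` comment line in CSV) so every result is traceable to its
settings.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape

from .region import DemandUnit, Facility, Region
from .report import RunSummary

__all__ = [
    "read_layers",
    "read_demand_layer",
    "read_supply_layer",
    "write_region",
    "write_scores",
    "read_scores",
    "write_summary",
    "write_geojson_scores",
]


def _is_geojson(path: Path) -> bool:
    return path.suffix.lower() in (".geojson", ".json")


def _check_value(value: Any, field: str, uid: Any) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise ValueError(f"feature {uid!r}: missing {field}")
    v = int(value)
    if v < 0:
        raise ValueError(f"feature {uid!r}: {field} must be >= 0, got {value}")
    return v


def _read_features(path: Path) -> list[dict]:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def read_demand_layer(path: str | Path) -> list[DemandUnit]:
    """Read the community layer (GeoJSON or ``id,x,y,population`` CSV)."""
    path = Path(path)
    units: list[DemandUnit] = []
    if _is_geojson(path):
        for feat in _read_features(path):
            props = feat.get("properties") or {}
            if "id" not in props:
                raise ValueError(f"{path}: demand feature without an 'id' property")
            uid = str(props["id"])
            if "population" not in props:
                raise ValueError(f"{path}: demand feature {uid!r} missing 'population' property")
            geom = shape(feat["geometry"])
            units.append(DemandUnit(id=uid, geometry=geom,
                                    population=_check_value(props["population"], "population", uid)))
    else:
        df = pd.read_csv(path, comment="#")
        missing = {"id", "x", "y", "population"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: demand CSV missing column(s) {sorted(missing)}")
        for row in df.itertuples(index=False):
            units.append(DemandUnit(id=str(row.id), geometry=Point(float(row.x), float(row.y)),
                                    population=_check_value(row.population, "population", row.id)))
    return units


def read_supply_layer(path: str | Path) -> list[Facility]:
    """Read the facility layer (GeoJSON points or ``id,x,y,beds`` CSV)."""
    path = Path(path)
    facilities: list[Facility] = []
    if _is_geojson(path):
        for feat in _read_features(path):
            props = feat.get("properties") or {}
            if "id" not in props:
                raise ValueError(f"{path}: supply feature without an 'id' property")
            uid = str(props["id"])
            if "beds" not in props:
                raise ValueError(f"{path}: supply feature {uid!r} missing 'beds' property")
            geom = shape(feat["geometry"])
            if not isinstance(geom, Point):
                raise ValueError(f"{path}: supply feature {uid!r} must have Point geometry")
            facilities.append(Facility(id=uid, location=geom, beds=_check_value(props["beds"], "beds", uid)))
    else:
        df = pd.read_csv(path, comment="#")
        missing = {"id", "x", "y", "beds"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: supply CSV missing column(s) {sorted(missing)}")
        for row in df.itertuples(index=False):
            facilities.append(Facility(id=str(row.id), location=Point(float(row.x), float(row.y)),
                                       beds=_check_value(row.beds, "beds", row.id)))
    return facilities


def read_layers(demand_path: str | Path, supply_path: str | Path, crs: str | None = None) -> Region:
    """Assemble a validated Region from a demand file and a supply file."""
    return Region(
        demand_units=read_demand_layer(demand_path),
        facilities=read_supply_layer(supply_path),
        crs=crs,
    )


def _dump_geojson(features: list[dict], path: Path, metadata: Mapping[str, Any] | None) -> None:
    doc: dict[str, Any] = {"type": "FeatureCollection", "features": features}
    if metadata:
        doc["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_region(
    region: Region,
    demand_path: str | Path,
    supply_path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> None:
    """Write both layers; dialect chosen per path extension."""
    demand_path, supply_path = Path(demand_path), Path(supply_path)
    if _is_geojson(demand_path):
        feats = [
            {"type": "Feature", "geometry": mapping(u.geometry),
             "properties": {"id": u.id, "population": u.population}}
            for u in region.demand_units
        ]
        _dump_geojson(feats, demand_path, metadata)
    else:
        df = pd.DataFrame({
            "id": region.demand_ids,
            "x": region.demand_points[:, 0],
            "y": region.demand_points[:, 1],
            "population": region.populations.astype(int),
        })
        _write_csv(df, demand_path, metadata)
    if _is_geojson(supply_path):
        feats = [
            {"type": "Feature", "geometry": mapping(f.location),
             "properties": {"id": f.id, "beds": f.beds}}
            for f in region.facilities
        ]
        _dump_geojson(feats, supply_path, metadata)
    else:
        df = pd.DataFrame({
            "id": region.facility_ids,
            "x": region.facility_points[:, 0],
            "y": region.facility_points[:, 1],
            "beds": region.beds.astype(int),
        })
        _write_csv(df, supply_path, metadata)


def _write_csv(df: pd.DataFrame, path: Path, metadata: Mapping[str, Any] | None) -> None:
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(dict(metadata), sort_keys=True) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def write_scores(
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> None:
    """Write a per-unit score table (columns at least ``id`` and ``score``)."""
    _write_csv(frame, Path(path), metadata)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores`."""
    df = pd.read_csv(Path(path), comment="#")
    if "id" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: score table needs 'id' and 'score' columns")
    df["id"] = df["id"].astype(str)
    return df


def write_geojson_scores(
    region: Region,
    frame: pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> None:
    """Write demand geometries with the score table's columns as properties."""
    by_id = frame.set_index(frame["id"].astype(str))
    feats = []
    for u in region.demand_units:
        props: dict[str, Any] = {"id": u.id, "population": u.population}
        if u.id in by_id.index:
            row = by_id.loc[u.id]
            for col in frame.columns:
                if col == "id":
                    continue
                val = row[col]
                props[col] = val.item() if hasattr(val, "item") else val
        feats.append({"type": "Feature", "geometry": mapping(u.geometry), "properties": props})
    _dump_geojson(feats, Path(path), metadata)


def write_summary(summary: RunSummary, path: str | Path, metadata: Mapping[str, Any] | None = None) -> None:
    """Write a run summary as JSON (raw and rounded fields both retained)."""
    doc = summary.to_dict()
    if metadata:
        doc["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True, default=float)
        fh.write("\n")
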