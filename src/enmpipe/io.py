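"""Reading and writing the pipeline's vector and tabular formats.

Ranges and ecoregions travel as GeoJSON FeatureCollections; occurrence
records and reconciliation outcomes as CSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .geometry import Ecoregion, EcoregionSet, equal_area_km2

OCCURRENCE_COLUMNS = ["id", "genus", "species", "subspecies", "lon", "lat", "source"]


def read_ranges_geojson(path: str | Path) -> dict[str, BaseGeometry]:
    """Species range polygons keyed by the feature property ``species``."""
    with open(path) as fh:
        fc = json.load(fh)
    out: dict[str, BaseGeometry] = {}
    for feat in fc.get("features", []):
        name = feat.get("properties", {}).get("species")
        if name is None:
            raise ValueError("range feature missing 'species' property")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = geom.buffer(0)
        out[name] = out[name].union(geom) if name in out else geom
    return out


def write_ranges_geojson(ranges: dict[str, BaseGeometry], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"species": name}, "geometry": mapping(geom)}
        for name, geom in sorted(ranges.items())
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ecoregions_geojson(path: str | Path) -> EcoregionSet:
    with open(path) as fh:
        fc = json.load(fh)
    regions = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        rid = props.get("region_id")
        if rid is None:
            raise ValueError("ecoregion feature missing 'region_id' property")
        geom = shape(feat["geometry"])
        area = props.get("area_km2", equal_area_km2(geom))
        regions.append(Ecoregion(str(rid), geom, float(area)))
    return EcoregionSet(regions)


def write_ecoregions_geojson(ecoregions: EcoregionSet, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"region_id": r.region_id, "area_km2": r.area_km2},
            "geometry": mapping(r.polygon),
        }
        for r in ecoregions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_occurrences_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "genus": str, "species": str,
                                  "subspecies": str, "source": str})
    missing = set(OCCURRENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate record id {dup!r}")
    bad = df[(df["lon"].abs() > 180) | (df["lat"].abs() > 90)]
    if len(bad):
        raise ValueError(f"coordinates out of range for ids {bad['id'].tolist()[:5]}")
    return df


def write_occurrences_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
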