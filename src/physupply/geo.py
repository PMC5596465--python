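"""Loosely coupled GIS half: join indicators to geometries, emit GeoJSON.

The simulation and the geographic side exchange data through files: the
indicator table (CSV) is joined to region polygons and written as an
RFC 7946 FeatureCollection (WGS84 lon-lat) whose per-feature properties
are flattened as ``<indicator>_<year>`` — directly usable as a
choropleth source in any GIS tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .indicators import PREFECTURE, SHORTAGE, SUFFICIENT

#: graded sufficiency bins for richer maps (edges inclusive on the left)
GRADED_BINS = ((0.8, "<0.8"), (1.0, "0.8-1.0"), (1.2, "1.0-1.2"))
GRADED_TOP = ">=1.2"


class GeoJoinError(ValueError):
    """Region ids on the two sides of a join do not match."""


@dataclass
class RegionFeatureSet:
    """One GeoJSON feature per region with per-year indicator attributes."""

    features: list[dict]

    @property
    def region_ids(self) -> list[str]:
        return [f["properties"]["region_id"] for f in self.features]

    def to_geojson(self) -> dict:
        return {"type": "FeatureCollection", "features": self.features}


def choropleth_classes(sufficiency_values, bins: str = "binary") -> list[str]:
    """Map-ready class labels for sufficiency values.

    ``binary`` reproduces the red/green shortage map (threshold 1.0,
    boundary counted as sufficient/green); ``graded`` adds intermediate
    bins (<0.8, 0.8-1.0, 1.0-1.2, >=1.2).
    """
    labels = []
    for v in sufficiency_values:
        v = float(v)
        if v < 0:
            raise ValueError(f"sufficiency must be >= 0 (got {v})")
        if bins == "binary":
            labels.append(SUFFICIENT if v >= 1.0 else SHORTAGE)
        elif bins == "graded":
            for edge, label in GRADED_BINS:
                if v < edge:
                    labels.append(label)
                    break
            else:
                labels.append(GRADED_TOP)
        else:
            raise ValueError(f"unknown bins mode: {bins!r}")
    return labels


def join_indicators(
    geometries: dict[str, BaseGeometry],
    indicator_table: pd.DataFrame,
    bins: str = "binary",
) -> RegionFeatureSet:
    """Join per-region indicators onto geometries (a strict bijection).

    Prefecture rows in the indicator table are ignored (they have no
    geometry).  Any region present on one side only aborts the join
    with the offending ids listed.
    """
    regional = indicator_table[indicator_table["region_id"] != PREFECTURE]
    indicator_ids = set(regional["region_id"])
    geometry_ids = set(geometries)
    if indicator_ids != geometry_ids:
        missing_geom = sorted(indicator_ids - geometry_ids)
        missing_ind = sorted(geometry_ids - indicator_ids)
        raise GeoJoinError(
            "region ids do not match: "
            f"indicators without geometry: {missing_geom}; "
            f"geometries without indicators: {missing_ind}"
        )
    features = []
    for rid in sorted(geometry_ids):
        rows = regional[regional["region_id"] == rid].set_index("year")
        props: dict = {"region_id": rid}
        for year, row in rows.sort_index().iterrows():
            props[f"sufficiency_{year}"] = float(row["sufficiency"])
            props[f"density_{year}"] = float(row["density"])
            props[f"status_{year}"] = str(row["status"])
            props[f"class_{year}"] = choropleth_classes(
                [row["sufficiency"]], bins=bins
            )[0]
        features.append({
            "type": "Feature",
            "geometry": mapping(geometries[rid]),
            "properties": props,
        })
    return RegionFeatureSet(features=features)


def write_features(
    feature_set: RegionFeatureSet, path: str | Path, per_year: bool = False
) -> list[Path]:
    """Write a FeatureCollection; optionally one file per report year.

    In per-year mode each ``<stem>_<year>.geojson`` carries only that
    year's attributes (un-suffixed keys) next to ``region_id``.
    """
    path = Path(path)
    if not feature_set.features:
        raise ValueError("refusing to write an empty FeatureCollection")
    if not per_year:
        path.write_text(
            json.dumps(feature_set.to_geojson()), encoding="utf-8"
        )
        return [path]
    years = sorted({
        int(k.rsplit("_", 1)[1])
        for f in feature_set.features
        for k in f["properties"]
        if k.startswith("sufficiency_")
    })
    written = []
    for year in years:
        features = []
        for f in feature_set.features:
            props = {"region_id": f["properties"]["region_id"]}
            for key, value in f["properties"].items():
                if key.endswith(f"_{year}"):
                    props[key.rsplit("_", 1)[0]] = value
            features.append({
                "type": "Feature",
                "geometry": f["geometry"],
                "properties": props,
            })
        out = path.with_name(f"{path.stem}_{year}{path.suffix}")
        out.write_text(
            json.dumps({"type": "FeatureCollection", "features": features}),
            encoding="utf-8",
        )
        written.append(out)
    return written


def read_geometries(path: str | Path) -> dict[str, BaseGeometry]:
    """Read region polygons from a GeoJSON FeatureCollection.

    Every feature must carry a ``region_id`` property; all geometries
    must share one type, and the collection must be non-empty.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed GeoJSON in {path} at line {exc.lineno}, "
            f"column {exc.colno}: {exc.msg}"
        ) from exc
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    features = doc.get("features", [])
    if not features:
        raise ValueError(f"{path} contains no features (no regions)")
    geom_types = {f["geometry"]["type"] for f in features}
    if len(geom_types) > 1:
        raise ValueError(
            f"mixed geometry types in {path}: {sorted(geom_types)}"
        )
    geometries: dict[str, BaseGeometry] = {}
    for f in features:
        props = f.get("properties") or {}
        rid = props.get("region_id")
        if rid is None:
            raise ValueError(f"feature without region_id property in {path}")
        geom = shape(f["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for region {rid} in {path}")
        geometries[str(rid)] = geom
    return geometries
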