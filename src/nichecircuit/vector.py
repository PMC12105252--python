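"""Minimal GeoJSON persistence for shapely geometries.

Streams, roads, urban patches and range polygons travel as plain
GeoJSON FeatureCollections; properties are arbitrary JSON-serializable
mappings (e.g. a stream segment's Strahler order).
"""

from __future__ import annotations

import json
from typing import Iterable, Mapping

import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = ["write_geojson", "read_geojson"]


def write_geojson(features: Iterable, path) -> None:
    """Write geometries (or ``(geometry, properties)`` pairs) as a
    GeoJSON FeatureCollection."""
    feats = []
    for item in features:
        if isinstance(item, tuple):
            geom, props = item
        else:
            geom, props = item, {}
        feats.append(
            {
                "type": "Feature",
                "geometry": geom_mapping(geom),
                "properties": dict(props),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_geojson(path) -> list[tuple[shapely.Geometry, Mapping]]:
    """Read a FeatureCollection back as ``(geometry, properties)`` pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    return [
        (geom_shape(f["geometry"]), f.get("properties") or {})
        for f in doc["features"]
    ]
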