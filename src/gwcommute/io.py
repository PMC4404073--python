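"""GeoJSON and tabular I/O helpers.

Point sets round-trip through GeoJSON ``Point`` features or CSV columns
``x_m``/``y_m``; zone layers come in as GeoJSON ``Polygon``/``MultiPolygon``
features with attribute properties. Everything is planar meters — see
:func:`gwcommute.kernels.looks_like_degrees` for the degree guard.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = [
    "points_to_geojson",
    "points_from_geojson",
    "features_from_geojson",
    "write_geojson",
    "read_geojson",
]


def points_to_geojson(points, properties=None) -> dict:
    """Build a FeatureCollection of Point features; ``properties`` is an
    optional list of per-point property dicts (or a DataFrame)."""
    pts = np.asarray(points, float)
    if properties is not None and hasattr(properties, "to_dict"):
        properties = properties.to_dict("records")
    feats = []
    for i, (x, y) in enumerate(pts):
        props = dict(properties[i]) if properties is not None else {}
        props = {k: (v.item() if isinstance(v, np.generic) else v)
                 for k, v in props.items()}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": feats}


def points_from_geojson(obj) -> np.ndarray:
    """Extract an (n, 2) coordinate array from a FeatureCollection of
    Point features (or a bare geometry list)."""
    feats = obj["features"] if obj.get("type") == "FeatureCollection" else obj
    coords = []
    for f in feats:
        geom = f.get("geometry", f)
        if geom["type"] != "Point":
            raise ValueError(f"expected Point features, got {geom['type']}")
        coords.append(geom["coordinates"][:2])
    return np.asarray(coords, float)


def features_from_geojson(obj):
    """Return a list of (shapely geometry, properties) pairs."""
    from shapely.geometry import shape

    feats = obj["features"] if obj.get("type") == "FeatureCollection" else obj
    return [(shape(f["geometry"]), dict(f.get("properties") or {})) for f in feats]


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True)


def read_geojson(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
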