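"""Plain-text interchange formats: pose CSV, ESRI ASCII grids, GeoJSON, YAML.

Coordinates are metric easting/northing (UTM-style, metres); GeoJSON
files carry a ``crs_note`` property rather than a formal CRS object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import FootprintSet
from .synthetic import BathymetryGrid
from .terrain import ContourSet

__all__ = [
    "write_pose_csv",
    "read_pose_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "footprints_to_geojson",
    "observations_to_geojson",
    "contours_to_geojson",
    "write_yaml",
    "read_yaml",
]

POSE_COLUMNS = [
    "timestamp",
    "easting",
    "northing",
    "depth",
    "altitude",
    "pitch",
    "roll",
    "heading",
]

CRS_NOTE = "local metric easting/northing (metres); no geodetic datum"


def write_pose_csv(poses: pd.DataFrame, path) -> None:
    cols = POSE_COLUMNS + [c for c in poses.columns if c not in POSE_COLUMNS]
    poses[cols].to_csv(path, index=False)


def read_pose_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose CSV missing columns: {missing}")
    return df


def write_ascii_grid(bathy: BathymetryGrid, path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; rows written north-to-south as the format requires."""
    nr, nc = bathy.depth.shape
    half = bathy.cell_size / 2.0
    header = (
        f"ncols {nc}\n"
        f"nrows {nr}\n"
        f"xllcorner {bathy.origin_easting - half}\n"
        f"yllcorner {bathy.origin_northing - half}\n"
        f"cellsize {bathy.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, bathy.depth[::-1], fmt="%.3f")


def read_ascii_grid(path) -> BathymetryGrid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        depth = np.loadtxt(fh)
    cell = hdr["cellsize"]
    return BathymetryGrid(
        origin_easting=hdr["xllcorner"] + cell / 2.0,
        origin_northing=hdr["yllcorner"] + cell / 2.0,
        cell_size=cell,
        depth=np.atleast_2d(depth)[::-1],
    )


def _feature_collection(features: list[dict]) -> dict:
    return {
        "type": "FeatureCollection",
        "properties": {"crs_note": CRS_NOTE},
        "features": features,
    }


def footprints_to_geojson(fps: FootprintSet, path) -> None:
    feats = []
    for i in range(len(fps)):
        ring = fps.corners[i].tolist() + [fps.corners[i][0].tolist()]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "image_id": int(fps.image_id[i]),
                    "camera": fps.camera,
                    "area_m2": float(fps.area[i]),
                    "altitude_m": float(fps.altitude[i]),
                    "valid": bool(fps.valid[i]),
                },
            }
        )
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def observations_to_geojson(obs: pd.DataFrame, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(r.easting), float(r.northing)],
            },
            "properties": {"image_id": int(r.image_id), "taxon": str(r.taxon)},
        }
        for r in obs.itertuples()
    ]
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def contours_to_geojson(contours: ContourSet, path) -> None:
    feats = []
    for level in contours.levels:
        for seg in contours.lines[level]:
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": seg.tolist(),
                    },
                    "properties": {"level_m": float(level)},
                }
            )
    Path(path).write_text(json.dumps(_feature_collection(feats)))


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
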