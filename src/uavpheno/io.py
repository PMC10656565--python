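"""File formats: GeoTIFF rasters (via tifffile with GeoTIFF tags), GeoJSON
rectangles/points, CSV tables and YAML manifests.

Reflectance rasters are stored integer-scaled (uint16, value * scale) so the
on-disk representation round-trips losslessly; height rasters are float32.
The geotransform is carried in the standard ModelPixelScale/ModelTiepoint
GeoTIFF tags and layer names plus the scale factor in the image description.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import tifffile
import yaml

from .geo import BoundingBox, GeoTransform
from .plant_geolocation import GridPoint

MODEL_PIXEL_SCALE_TAG = 33550
MODEL_TIEPOINT_TAG = 33922


def write_geotiff(
    path,
    array: np.ndarray,
    gt: GeoTransform,
    layer_names: Sequence[str],
    scale: Optional[float] = None,
) -> None:
    """Write a (bands, rows, cols) or (rows, cols) raster as GeoTIFF.

    With ``scale`` the data are stored as uint16 ``round(value * scale)``;
    otherwise as float32.
    """
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[None]
    if scale is not None:
        data = np.clip(np.rint(arr * scale), 0, np.iinfo(np.uint16).max).astype(
            np.uint16
        )
    else:
        data = arr.astype(np.float32)
    desc = json.dumps({"layers": list(layer_names), "scale": scale})
    extratags = [
        (MODEL_PIXEL_SCALE_TAG, "d", 3, (gt.gsd_x, gt.gsd_y, 0.0)),
        (MODEL_TIEPOINT_TAG, "d", 6, (0.0, 0.0, 0.0, gt.origin_x, gt.origin_y, 0.0)),
    ]
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        description=desc,
        extratags=extratags,
    )


def read_geotiff(path) -> Tuple[np.ndarray, GeoTransform, List[str]]:
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns (bands, rows, cols) float array (scale applied), the
    geotransform, and the layer names.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        page = tif.pages[0]
        scale_tag = page.tags[MODEL_PIXEL_SCALE_TAG].value
        tiepoint = page.tags[MODEL_TIEPOINT_TAG].value
        desc = json.loads(page.tags["ImageDescription"].value)
    gt = GeoTransform(
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        gsd_x=float(scale_tag[0]),
        gsd_y=float(scale_tag[1]),
    )
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if desc.get("scale"):
        arr = arr / float(desc["scale"])
    return arr, gt, list(desc["layers"])


def _box_polygon(box: BoundingBox) -> List[List[List[float]]]:
    return [[
        [box.xmin, box.ymin],
        [box.xmax, box.ymin],
        [box.xmax, box.ymax],
        [box.xmin, box.ymax],
        [box.xmin, box.ymin],
    ]]


def boxes_to_geojson(boxes_by_tp: Mapping[int, Sequence[BoundingBox]]) -> dict:
    features = []
    for tp in sorted(boxes_by_tp):
        for box in boxes_by_tp[tp]:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon",
                                 "coordinates": _box_polygon(box)},
                    "properties": {"tp": int(tp)},
                }
            )
    return {"type": "FeatureCollection", "features": features}


def geojson_to_boxes(gj: dict) -> Dict[int, List[BoundingBox]]:
    out: Dict[int, List[BoundingBox]] = {}
    for feat in gj["features"]:
        coords = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        tp = feat["properties"].get("tp")
        box = BoundingBox(
            xmin=float(coords[:, 0].min()),
            ymin=float(coords[:, 1].min()),
            xmax=float(coords[:, 0].max()),
            ymax=float(coords[:, 1].max()),
            source_tp=tp,
        )
        out.setdefault(int(tp) if tp is not None else -1, []).append(box)
    return out


def grid_to_geojson(points: Sequence[GridPoint]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
                "properties": {"plant_id": int(p.plant_id)},
            }
            for p in points
        ],
    }


def geojson_to_grid(gj: dict) -> List[GridPoint]:
    return [
        GridPoint(
            plant_id=int(f["properties"]["plant_id"]),
            x=float(f["geometry"]["coordinates"][0]),
            y=float(f["geometry"]["coordinates"][1]),
        )
        for f in gj["features"]
    ]


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1))


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_yaml(path, obj: dict) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
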