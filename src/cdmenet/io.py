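"""Readers and writers: point annotations, density caches, configuration.

Point annotations come from Labelme-style JSON (shape_type "point", or
degenerate single-vertex polygons) or from two-column CSV with an ``x,y``
header.  Prepared density maps are cached as HDF5 (one 2-D float dataset per
image id); configuration round-trips through YAML.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import yaml

from .density import PointSet

__all__ = [
    "read_points",
    "write_points_csv",
    "write_points_labelme",
    "save_density_cache",
    "load_density_cache",
    "load_config",
    "save_config",
]


def read_points(
    path: str | Path, width: int | None = None, height: int | None = None
) -> PointSet:
    """Parse a Labelme JSON or CSV annotation file into a PointSet.

    Image dimensions are taken from the JSON when present; CSV files require
    ``width``/``height`` from the caller.  Out-of-bounds coordinates raise
    with the offending points listed.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_labelme(path, width, height)
    if path.suffix.lower() == ".csv":
        return _read_csv(path, width, height)
    raise ValueError(f"unsupported annotation format: {path.suffix}")


def _read_labelme(path: Path, width, height) -> PointSet:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed JSON ({e})") from e
    w = doc.get("imageWidth", width)
    h = doc.get("imageHeight", height)
    if w is None or h is None:
        raise ValueError(f"{path}: no image dimensions in file or arguments")
    pts = []
    for i, shape in enumerate(doc.get("shapes", [])):
        vertices = shape.get("points", [])
        kind = shape.get("shape_type", "point")
        if kind == "point" or len(vertices) == 1:
            if len(vertices) != 1:
                raise ValueError(f"{path}: shape {i} is a point with "
                                 f"{len(vertices)} vertices")
            pts.append(vertices[0])
        else:
            raise ValueError(
                f"{path}: shape {i} has shape_type {kind!r} with "
                f"{len(vertices)} vertices; only point annotations are supported"
            )
    return PointSet(path.stem, int(w), int(h), np.array(pts, dtype=float).reshape(-1, 2))


def _read_csv(path: Path, width, height) -> PointSet:
    if width is None or height is None:
        raise ValueError(f"{path}: CSV annotations need explicit width/height")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty CSV") from None
        if [c.strip().lower() for c in header[:2]] != ["x", "y"]:
            raise ValueError(f"{path}: expected an 'x,y' header, got {header!r}")
        pts = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                pts.append((float(row[0]), float(row[1])))
            except (ValueError, IndexError):
                raise ValueError(f"{path}: line {lineno}: cannot parse {row!r}") from None
    return PointSet(path.stem, int(width), int(height),
                    np.array(pts, dtype=float).reshape(-1, 2))


def write_points_csv(path: str | Path, points: PointSet) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        writer.writerows([[f"{x:.6g}", f"{y:.6g}"] for x, y in points.points])


def write_points_labelme(path: str | Path, points: PointSet) -> None:
    doc = {
        "version": "5.0.0",
        "imageWidth": points.width,
        "imageHeight": points.height,
        "imagePath": f"{points.image_id}.png",
        "shapes": [
            {"label": "berry", "shape_type": "point", "points": [[float(x), float(y)]]}
            for x, y in points.points
        ],
    }
    Path(path).write_text(json.dumps(doc))


def save_density_cache(path: str | Path, maps: dict[str, np.ndarray],
                       resolution_divisor: int = 8) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["resolution_divisor"] = resolution_divisor
        for image_id, values in maps.items():
            f.create_dataset(image_id, data=np.asarray(values, dtype=np.float64))


def load_density_cache(path: str | Path) -> tuple[dict[str, np.ndarray], int]:
    with h5py.File(path, "r") as f:
        divisor = int(f.attrs.get("resolution_divisor", 1))
        return {k: f[k][...] for k in f.keys()}, divisor


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path: str | Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
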