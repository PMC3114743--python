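"""Readers and writers: images, masks, mesh JSON, CSV tables.

Images are single-channel 8- or 16-bit PNG or TIFF; raw integer sample
values are preserved (no rescaling).  The mesh persists as JSON with
explicit corner coordinates, types, properties and adjacency, round-trip
lossless at full float precision (missing values become null).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .analyze import ProfilePoint
from .digitize import BinaryMask, IntensityImage
from .mesh import PolygonalMesh, Subcompartment
from .simulate import Trajectory

__all__ = [
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_mesh",
    "read_mesh",
    "write_profile_csv",
    "write_stats_csv",
    "write_trajectory_csv",
]

log = logging.getLogger(__name__)

_ALLOWED_PIL_MODES = {"L", "I", "I;16", "P", "1"}


def _read_grid(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        grid = tifffile.imread(path)
        if grid.ndim != 2:
            raise ValueError(
                f"{path}: expected a single-channel image, got shape {grid.shape}"
            )
        if grid.dtype not in (np.uint8, np.uint16, np.bool_):
            raise ValueError(f"{path}: unsupported sample type {grid.dtype}")
        return np.asarray(grid)
    with Image.open(path) as im:
        if im.mode not in _ALLOWED_PIL_MODES:
            raise ValueError(
                f"{path}: mode {im.mode!r} is not a single-channel 8/16-bit image"
            )
        return np.asarray(im)


def read_image(path, species: str | None = None) -> IntensityImage:
    """Load a single-channel intensity image; species defaults to the stem."""
    path = Path(path)
    grid = _read_grid(path).astype(float)
    return IntensityImage(grid, species or path.stem)


def read_mask(path, label: str | None = None) -> BinaryMask:
    """Load a binary mask: any nonzero sample is inside."""
    path = Path(path)
    return BinaryMask(_read_grid(path) != 0, label or path.stem)


def write_image(image: IntensityImage | np.ndarray, path) -> None:
    grid = np.asarray(getattr(image, "grid", image))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if grid.max(initial=0) <= 255:
        arr = grid.astype(np.uint8)
    else:
        arr = grid.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_mask(mask: BinaryMask, path) -> None:
    write_image(mask.grid.astype(np.uint8) * 255, path)


# ---------------------------------------------------------------------------
# mesh JSON
# ---------------------------------------------------------------------------

def _props_out(props: dict[str, float]) -> dict[str, float | None]:
    return {k: (None if (isinstance(v, float) and math.isnan(v)) else v) for k, v in props.items()}


def write_mesh(mesh: PolygonalMesh, path) -> None:
    doc = {
        "bbox": list(mesh.bbox),
        "subcompartments": [
            {
                "id": s.id,
                "corners": s.corners.tolist(),
                "type": s.type,
                "properties": _props_out(s.properties),
            }
            for s in mesh.subcompartments
        ],
        "adjacency": [[i, n, length] for (i, n), length in sorted(mesh.adjacency.items())],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc))


def read_mesh(path) -> PolygonalMesh:
    """Load a mesh JSON; schema errors name the offending JSON path.

    A mesh whose polygon areas do not sum to the bbox area is loaded with a
    warning (manual edits may legitimately leave gaps); adjacency entries
    referencing unknown ids are rejected.
    """
    doc = json.loads(Path(path).read_text())
    try:
        bbox = tuple(float(v) for v in doc["bbox"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid or missing $.bbox") from exc
    subs = []
    for k, entry in enumerate(doc.get("subcompartments", [])):
        try:
            props = {
                name: (math.nan if v is None else float(v))
                for name, v in entry.get("properties", {}).items()
            }
            subs.append(
                Subcompartment(
                    id=int(entry["id"]),
                    corners=np.asarray(entry["corners"], dtype=float),
                    type=str(entry.get("type", "untyped")),
                    properties=props,
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid $.subcompartments[{k}]: {exc}") from exc
    adjacency: dict[tuple[int, int], float] = {}
    known = {s.id for s in subs}
    for k, entry in enumerate(doc.get("adjacency", [])):
        try:
            i, n, length = int(entry[0]), int(entry[1]), float(entry[2])
        except (TypeError, ValueError, IndexError) as exc:
            raise ValueError(f"{path}: invalid $.adjacency[{k}]") from exc
        if i not in known or n not in known:
            raise ValueError(f"{path}: $.adjacency[{k}] references unknown id ({i}, {n})")
        adjacency[(min(i, n), max(i, n))] = length
    mesh = PolygonalMesh(subs, bbox, adjacency)
    if subs and not mesh.tiles_bbox(rtol=1e-9):
        log.warning(
            "%s: polygon areas sum to %.6g but bbox area is %.6g; loading anyway",
            path,
            mesh.total_area(),
            mesh.bbox_area(),
        )
    return mesh


# ---------------------------------------------------------------------------
# CSV outputs
# ---------------------------------------------------------------------------

def write_profile_csv(points: list[ProfilePoint], mesh: PolygonalMesh, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subcompartment_id", "coordinate_or_phi", "value", "type", "area"])
        for p in points:
            sub = mesh[p.subcompartment_id]
            writer.writerow([p.subcompartment_id, repr(p.coordinate), repr(p.value), sub.type, repr(sub.area)])


def write_stats_csv(rows: list[tuple], path) -> None:
    """Rows of (metric, types, species, value)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "types", "species", "value"])
        for metric, types, species, value in rows:
            writer.writerow([metric, types, species, repr(value)])


def write_trajectory_csv(traj: Trajectory, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "subcompartment_id", "value"])
        for t, state in zip(traj.times, traj.states):
            for sid, v in zip(traj.ids, state):
                writer.writerow([repr(float(t)), sid, repr(float(v))])
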