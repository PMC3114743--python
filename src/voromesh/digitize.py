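"""Typing and signal acquisition: from pixel images onto the mesh.

Two pixel-grid inputs drive digitization: ordered *binary masks* (one per
cellular compartment — cytoplasm, nucleus, membranes, shmoo tip) which
assign a compartment type to every subcompartment, and single-channel
*intensity images* whose raw sample values (a.u.) are averaged per
subcompartment into its property map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .mesh import PolygonalMesh

__all__ = [
    "BinaryMask",
    "IntensityImage",
    "label_grid",
    "pixel_membership",
    "assign_types",
    "set_type",
    "set_type_at_point",
    "acquire_signal",
    "MISSING",
]

log = logging.getLogger(__name__)

#: marker for a subcompartment that owns no pixels
MISSING = float("nan")


@dataclass
class BinaryMask:
    """Boolean pixel grid marking one compartment (nonzero = inside)."""

    grid: np.ndarray  # (H, W) bool
    label: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class IntensityImage:
    """Single-channel luminosity image; raw integer samples stored as floats."""

    grid: np.ndarray  # (H, W) float, values >= 0
    species: str

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("image grid must be 2D")
        if np.any(self.grid < 0):
            raise ValueError("intensity values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _image_shape(mesh: PolygonalMesh) -> tuple[int, int]:
    xmin, ymin, xmax, ymax = mesh.bbox
    w, h = xmax - xmin, ymax - ymin
    wi, hi = int(round(w)), int(round(h))
    if not (math.isclose(w, wi) and math.isclose(h, hi)) or wi <= 0 or hi <= 0:
        raise ValueError(f"mesh bbox {mesh.bbox} is not an integral pixel grid")
    return hi, wi


def _check_dims(mesh: PolygonalMesh, shape: tuple[int, int], what: str) -> None:
    expect = _image_shape(mesh)
    if tuple(shape) != expect:
        raise ValueError(
            f"{what} dimensions {tuple(shape)} do not match mesh bbox grid {expect}"
        )


def label_grid(mesh: PolygonalMesh) -> np.ndarray:
    """Assign every pixel center to exactly one subcompartment.

    Returns an (H, W) integer grid of subcompartment ids.  Subcompartments
    are tested in ascending id order and the first polygon covering a pixel
    center (boundary inclusive) claims it, so pixels on shared edges — the
    equidistant ties of a Voronoi mesh — deterministically go to the lower
    id.  Pixels covered by no polygon (possible only through floating-point
    slack in hand-edited meshes) fall back to the nearest centroid.
    """
    h, w = _image_shape(mesh)
    xmin, ymin = mesh.bbox[0], mesh.bbox[1]
    labels = np.full((h, w), -1, dtype=np.int64)
    xs = xmin + np.arange(w) + 0.5
    ys = ymin + np.arange(h) + 0.5
    for sub in sorted(mesh.subcompartments, key=lambda s: s.id):
        minx, miny, maxx, maxy = sub.polygon.bounds
        c0 = max(0, int(math.floor(minx - xmin - 0.5)))
        c1 = min(w - 1, int(math.ceil(maxx - xmin - 0.5)))
        r0 = max(0, int(math.floor(miny - ymin - 0.5)))
        r1 = min(h - 1, int(math.ceil(maxy - ymin - 0.5)))
        if c1 < c0 or r1 < r0:
            continue
        block = labels[r0 : r1 + 1, c0 : c1 + 1]
        free = block == -1
        if not free.any():
            continue
        rr, cc = np.nonzero(free)
        hit = shapely.intersects_xy(sub.polygon, xs[c0 + cc], ys[r0 + rr])
        block[rr[hit], cc[hit]] = sub.id
    orphan = labels == -1
    if orphan.any():
        n = int(orphan.sum())
        log.warning("label_grid: %d pixels covered by no polygon; using nearest centroid", n)
        tree = cKDTree(mesh.centroids())
        rr, cc = np.nonzero(orphan)
        _, idx = tree.query(np.column_stack([xs[cc], ys[rr]]))
        ids = np.array(mesh.ids)
        labels[rr, cc] = ids[idx]
    return labels


def pixel_membership(mesh: PolygonalMesh) -> dict[int, np.ndarray]:
    """Map subcompartment id -> (k, 2) array of owned pixel (row, col).

    Every pixel belongs to exactly one subcompartment; the union over all
    ids is the full pixel grid.
    """
    labels = label_grid(mesh)
    out: dict[int, np.ndarray] = {}
    order = np.argsort(labels, axis=None, kind="stable")
    flat = labels.ravel()[order]
    rows, cols = np.unravel_index(order, labels.shape)
    bounds = np.searchsorted(flat, np.array(sorted(mesh.ids) + [flat[-1] + 1]))
    sorted_ids = sorted(mesh.ids)
    for k, sid in enumerate(sorted_ids):
        sel = slice(bounds[k], bounds[k + 1])
        out[sid] = np.column_stack([rows[sel], cols[sel]])
    return out


def assign_types(
    mesh: PolygonalMesh,
    ordered_masks: list[BinaryMask],
    default_label: str = "outside",
    labels: np.ndarray | None = None,
) -> PolygonalMesh:
    """Type each subcompartment by majority vote against ordered masks.

    A subcompartment takes a mask's label when at least half of its pixel
    centers lie inside that mask; masks are applied in the given order, a
    later mask overwriting earlier assignments.  Subcompartments matched by
    no mask (including zero-pixel ones) get ``default_label``.  Modifies
    the mesh in place and returns it.
    """
    for m in ordered_masks:
        _check_dims(mesh, m.shape, f"mask '{m.label}'")
    if labels is None:
        labels = label_grid(mesh)
    max_id = max(mesh.ids)
    flat = labels.ravel()
    totals = np.bincount(flat, minlength=max_id + 1)
    for sub in mesh:
        sub.type = default_label
    for m in ordered_masks:
        inside = np.bincount(flat[m.grid.ravel()], minlength=max_id + 1)
        for sub in mesh:
            t = totals[sub.id]
            if t > 0 and inside[sub.id] * 2 >= t:
                sub.type = m.label
    return mesh


def set_type(mesh: PolygonalMesh, sid: int, label: str) -> PolygonalMesh:
    """Manually set one subcompartment's type; all others untouched."""
    mesh[sid].type = str(label)
    return mesh


def set_type_at_point(
    mesh: PolygonalMesh,
    point: tuple[float, float],
    label: str,
    labels: np.ndarray | None = None,
) -> int:
    """Set the type of the subcompartment owning the pixel at ``(x, y)``.

    Point-based manual typing: a single marked pixel suffices to tag e.g.
    the shmoo tip, which a majority vote over masks cannot see.  Returns the
    id that was retyped.
    """
    if labels is None:
        labels = label_grid(mesh)
    h, w = labels.shape
    c = min(w - 1, max(0, int(math.floor(point[0] - mesh.bbox[0]))))
    r = min(h - 1, max(0, int(math.floor(point[1] - mesh.bbox[1]))))
    sid = int(labels[r, c])
    set_type(mesh, sid, label)
    return sid


def apply_point_masks(
    mesh: PolygonalMesh,
    ordered_masks: list[BinaryMask],
    labels: np.ndarray,
) -> list[int]:
    """Point-assign labels of masks too small to ever win a majority vote.

    A marker mask (e.g. the single shmoo-tip pixel) can never cover half of
    any subcompartment, so :func:`assign_types` leaves it unmatched.  For
    each such mask — nonempty, unmatched, and smaller than half of every
    subcompartment it touches — the subcompartments owning its pixels are
    retyped directly, mirroring manual type setting.  Returns the retyped
    ids.  Larger unmatched masks (e.g. a thin membrane ring on a coarse
    mesh) are left alone: spreading their label to every touched
    subcompartment would grossly inflate the compartment.
    """
    flat = labels.ravel()
    totals = np.bincount(flat, minlength=max(mesh.ids) + 1)
    typed = {s.type for s in mesh}
    retyped: list[int] = []
    for m in ordered_masks:
        n_mask = int(m.grid.sum())
        if m.label in typed or n_mask == 0:
            continue
        touched = np.unique(labels[m.grid])
        if n_mask * 2 > int(totals[touched].min()):
            continue
        for sid in touched:
            set_type(mesh, int(sid), m.label)
            retyped.append(int(sid))
            log.info("apply_point_masks: type %r set on subcompartment %d", m.label, sid)
    return retyped


def acquire_signal(
    mesh: PolygonalMesh,
    image: IntensityImage,
    labels: np.ndarray | None = None,
) -> PolygonalMesh:
    """Store each subcompartment's mean pixel intensity as a property.

    ``properties[image.species]`` becomes the arithmetic mean of the raw
    sample values of the pixels the subcompartment owns.  Subcompartments
    owning zero pixels get NaN (missing) and are logged; downstream
    statistics exclude them.  Modifies the mesh in place and returns it.
    """
    _check_dims(mesh, image.shape, f"image '{image.species}'")
    if labels is None:
        labels = label_grid(mesh)
    max_id = max(mesh.ids)
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=max_id + 1)
    sums = np.bincount(flat, weights=image.grid.ravel(), minlength=max_id + 1)
    n_empty = 0
    for sub in mesh:
        if counts[sub.id] == 0:
            sub.properties[image.species] = MISSING
            n_empty += 1
        else:
            sub.properties[image.species] = float(sums[sub.id] / counts[sub.id])
    if n_empty:
        log.warning(
            "acquire_signal('%s'): %d subcompartments own no pixels; marked missing",
            image.species,
            n_empty,
        )
    return mesh
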