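"""Voronoi polygonal meshes on a pixel bounding box.

The mesh is the central digitized representation of a 2D microscopy image:
a set of convex (or, when loaded from edited JSON, possibly non-convex)
polygonal *subcompartments* that tile the image rectangle without overlap.
Each subcompartment carries an id, explicit corner coordinates, a
compartment-type label and a map of named scalar properties (per-species
signal levels or simulated concentrations).

Coordinate convention
---------------------
0-based pixel grid in image orientation: x grows rightward, y grows
downward.  Pixel ``(row r, col c)`` has center ``(c + 0.5, r + 0.5)``.
The bounding box of an ``H x W`` image is ``(0, 0, W, H)``.
Polygon corners are stored counter-clockwise (positive signed area).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient

__all__ = [
    "SeedSet",
    "Subcompartment",
    "PolygonalMesh",
    "generate_hex_seeds",
    "generate_region_seeds",
    "build_voronoi_mesh",
    "compute_adjacency",
    "DEDUP_TOL",
    "CONTACT_TOL",
]

log = logging.getLogger(__name__)

#: seeds closer than this are considered duplicates (px)
DEDUP_TOL = 1e-9
#: shared boundaries shorter than this are point contacts, not edges (px)
CONTACT_TOL = 1e-9


@dataclass
class SeedSet:
    """Voronoi seed points inside a bounding box.

    Seeds correspond to subcompartment centers; one Voronoi cell (clipped
    to ``bbox``) is generated per seed.
    """

    points: np.ndarray  # (n, 2) float, pixel units
    bbox: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("seed points must be (n, 2)")
        self.bbox = tuple(float(v) for v in self.bbox)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Subcompartment:
    """One polygonal mesh element.

    ``area`` is the finite-volume cell volume V_i (px^2 in 2D) and
    ``properties`` holds per-species scalar values (e.g. mean Fus3PP signal
    in arbitrary units, or a simulated concentration).  A value of NaN marks
    a missing measurement (subcompartment owned no pixels).
    """

    id: int
    corners: np.ndarray  # (k, 2) float, CCW, closed ring implied
    type: str = "untyped"
    properties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.id = int(self.id)
        if self.id < 0:
            raise ValueError("subcompartment id must be >= 0")
        self.corners = np.atleast_2d(np.asarray(self.corners, dtype=float))
        if self.corners.shape[0] < 3 or self.corners.shape[1] != 2:
            raise ValueError(f"subcompartment {self.id}: need >= 3 corners")
        self._polygon: Polygon | None = None

    @property
    def polygon(self) -> Polygon:
        if self._polygon is None:
            poly = Polygon(self.corners)
            if not poly.is_valid:
                raise ValueError(f"subcompartment {self.id}: polygon is not simple")
            self._polygon = poly
        return self._polygon

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


class PolygonalMesh:
    """A tiling of the bounding box by subcompartments, plus adjacency.

    ``adjacency`` maps unordered id pairs (stored as sorted tuples) to the
    shared-boundary ("contact surface") length S_{i->n} in px.  It is empty
    until :func:`compute_adjacency` has been applied.
    """

    def __init__(
        self,
        subcompartments: list[Subcompartment],
        bbox: tuple[float, float, float, float],
        adjacency: dict[tuple[int, int], float] | None = None,
    ) -> None:
        self.subcompartments = list(subcompartments)
        self.bbox = tuple(float(v) for v in bbox)
        self.adjacency: dict[tuple[int, int], float] = dict(adjacency or {})
        self._by_id = {s.id: s for s in self.subcompartments}
        if len(self._by_id) != len(self.subcompartments):
            raise ValueError("duplicate subcompartment ids")
        for (i, n) in self.adjacency:
            if i not in self._by_id or n not in self._by_id:
                raise ValueError(f"adjacency references unknown id in pair ({i}, {n})")

    # -- accessors -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.subcompartments)

    def __iter__(self):
        return iter(self.subcompartments)

    def __getitem__(self, sid: int) -> Subcompartment:
        try:
            return self._by_id[sid]
        except KeyError:
            raise KeyError(f"no subcompartment with id {sid}") from None

    def __contains__(self, sid: int) -> bool:
        return sid in self._by_id

    @property
    def ids(self) -> list[int]:
        return [s.id for s in self.subcompartments]

    def areas(self) -> np.ndarray:
        return np.array([s.area for s in self.subcompartments])

    def centroids(self) -> np.ndarray:
        return np.array([s.centroid for s in self.subcompartments])

    def contact_length(self, i: int, n: int) -> float:
        return self.adjacency[(min(i, n), max(i, n))]

    def neighbours(self, sid: int) -> list[int]:
        """Ids sharing a boundary edge with ``sid`` (N_i of the model)."""
        out = []
        for (i, n) in self.adjacency:
            if i == sid:
                out.append(n)
            elif n == sid:
                out.append(i)
        return sorted(out)

    def neighbour_map(self) -> dict[int, list[int]]:
        nbrs: dict[int, list[int]] = {s.id: [] for s in self.subcompartments}
        for (i, n) in self.adjacency:
            nbrs[i].append(n)
            nbrs[n].append(i)
        return {k: sorted(v) for k, v in nbrs.items()}

    # -- invariants ----------------------------------------------------
    def total_area(self) -> float:
        return float(sum(s.area for s in self.subcompartments))

    def bbox_area(self) -> float:
        xmin, ymin, xmax, ymax = self.bbox
        return (xmax - xmin) * (ymax - ymin)

    def tiles_bbox(self, rtol: float = 1e-9) -> bool:
        return math.isclose(self.total_area(), self.bbox_area(), rel_tol=rtol)


# ---------------------------------------------------------------------------
# seed generation
# ---------------------------------------------------------------------------

def _check_bbox(bbox) -> tuple[float, float, float, float]:
    xmin, ymin, xmax, ymax = (float(v) for v in bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bbox {bbox}")
    return xmin, ymin, xmax, ymax


def generate_hex_seeds(bbox, spacing: float) -> SeedSet:
    """Triangular-lattice seeds whose Voronoi cells are equilateral hexagons.

    Rows lie at ``y = ymin + (j + 0.5) * spacing * sqrt(3)/2``; columns at
    ``x = xmin + (k + 0.5) * spacing``, with odd rows offset by half a
    spacing.  Every nearest-neighbour seed pair is exactly ``spacing`` apart,
    so interior Voronoi cells are regular hexagons of area
    ``(sqrt(3)/2) * spacing**2``.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    xmin, ymin, xmax, ymax = _check_bbox(bbox)
    dy = spacing * math.sqrt(3.0) / 2.0
    pts: list[tuple[float, float]] = []
    j = 0
    while True:
        y = ymin + (j + 0.5) * dy
        if y >= ymax:
            break
        xoff = spacing / 2.0 if j % 2 else 0.0
        k = 0
        while True:
            x = xmin + (k + 0.5) * spacing + xoff
            if x >= xmax:
                break
            pts.append((x, y))
            k += 1
        j += 1
    return SeedSet(np.array(pts, dtype=float).reshape(-1, 2), (xmin, ymin, xmax, ymax))


def _mask_grid(mask) -> np.ndarray:
    grid = getattr(mask, "grid", mask)
    return np.asarray(grid, dtype=bool)


def generate_region_seeds(bbox, default_spacing: float, region_rules) -> SeedSet:
    """Hex seeds with per-region densities.

    ``region_rules`` is an ordered list of ``(mask, spacing)``: inside each
    rule's mask the default lattice is replaced by one at the rule's spacing;
    where masks overlap, later rules override earlier ones.  Masks are
    pixel-grid booleans matching the bbox dimensions, so a seed at ``(x, y)``
    falls in pixel ``(row floor(y), col floor(x))``.
    """
    xmin, ymin, xmax, ymax = _check_bbox(bbox)
    rules = [( _mask_grid(m), float(sp)) for m, sp in region_rules]
    w, h = int(round(xmax - xmin)), int(round(ymax - ymin))
    for grid, _ in rules:
        if grid.shape != (h, w):
            raise ValueError(
                f"mask dimensions {grid.shape} do not match bbox {h}x{w} (HxW)"
            )

    def owner(pts: np.ndarray) -> np.ndarray:
        """Index of the last rule whose mask contains each point; -1 if none."""
        if not rules:
            return np.full(len(pts), -1)
        cols = np.clip(np.floor(pts[:, 0] - xmin).astype(int), 0, w - 1)
        rows = np.clip(np.floor(pts[:, 1] - ymin).astype(int), 0, h - 1)
        own = np.full(len(pts), -1)
        for idx, (grid, _) in enumerate(rules):
            inside = grid[rows, cols]
            own[inside] = idx
        return own

    parts = []
    default = generate_hex_seeds(bbox, default_spacing).points
    parts.append(default[owner(default) == -1])
    for idx, (_, sp) in enumerate(rules):
        pts = generate_hex_seeds(bbox, sp).points
        parts.append(pts[owner(pts) == idx])
    allpts = np.vstack([p for p in parts if len(p)])
    allpts, ndup = _dedup(allpts)
    if ndup:
        log.warning("generate_region_seeds: removed %d duplicate seeds", ndup)
    return SeedSet(allpts, (xmin, ymin, xmax, ymax))


def _dedup(points: np.ndarray, tol: float = DEDUP_TOL) -> tuple[np.ndarray, int]:
    if len(points) < 2:
        return points, 0
    pairs = cKDTree(points).query_pairs(tol)
    if not pairs:
        return points, 0
    drop = {max(i, j) for i, j in pairs}
    keep = np.array([i for i in range(len(points)) if i not in drop])
    return points[keep], len(points) - len(keep)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def build_voronoi_mesh(seeds: SeedSet) -> PolygonalMesh:
    """Voronoi tessellation of the seeds, clipped to the bounding box.

    Seeds are mirrored across the four bbox edges before tessellating, so
    the cell of every original seed is finite and bounded by the bbox (the
    bisector between a seed and its mirror image is exactly the bbox edge).
    One subcompartment is produced per seed, ids following seed order;
    adjacency is left empty (see :func:`compute_adjacency`).
    """
    pts = np.asarray(seeds.points, dtype=float)
    if len(pts) == 0:
        raise ValueError("cannot build a mesh from zero seeds")
    pts, ndup = _dedup(pts)
    if ndup:
        log.warning("build_voronoi_mesh: removed %d duplicate seeds", ndup)
    xmin, ymin, xmax, ymax = _check_bbox(seeds.bbox)

    mirrors = np.vstack([
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ])
    vor = Voronoi(np.vstack([pts, mirrors]))
    clip_box = box(xmin, ymin, xmax, ymax)

    subs = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError(f"unbounded Voronoi cell for seed {i}")
        poly = Polygon(vor.vertices[region])
        poly = poly.intersection(clip_box)
        if poly.is_empty or poly.geom_type != "Polygon":
            raise RuntimeError(f"degenerate clipped cell for seed {i}")
        poly = orient(poly, sign=1.0)
        corners = np.asarray(poly.exterior.coords[:-1], dtype=float)
        subs.append(Subcompartment(id=i, corners=corners))
    mesh = PolygonalMesh(subs, (xmin, ymin, xmax, ymax))
    mesh.seed_points = pts  # kept for provenance; not part of the JSON schema
    return mesh


def compute_adjacency(mesh: PolygonalMesh) -> PolygonalMesh:
    """Populate ``mesh.adjacency`` with shared-boundary lengths (in place).

    Two subcompartments are neighbours iff their polygons share a boundary
    segment longer than ``CONTACT_TOL``; single shared vertices (point
    contacts) carry no flux and are excluded.  Works for any polygon tiling,
    Voronoi-generated or hand-edited.  Returns the mesh for chaining.
    """
    subs = mesh.subcompartments
    geoms = [s.polygon for s in subs]
    tree = shapely.STRtree(geoms)
    adjacency: dict[tuple[int, int], float] = {}
    for pos, g in enumerate(geoms):
        for other in tree.query(g):
            other = int(other)
            if other <= pos:
                continue
            length = g.intersection(geoms[other]).length
            if length > CONTACT_TOL:
                i, n = subs[pos].id, subs[other].id
                adjacency[(min(i, n), max(i, n))] = float(length)
    mesh.adjacency = adjacency
    return mesh
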