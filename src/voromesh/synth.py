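"""Synthetic mating-yeast scenes: masks and signal images for testing.

Generates the geometry of a pheromone-stimulated (shmooing) yeast cell —
an ellipse with a protrusion toward the mating projection, a nuclear disk,
thin membrane rings — plus a fluorescence-like signal image: an
exponential gradient of the active kinase decaying with distance from the
shmoo tip through the cytoplasm, a uniform level in the nucleus, zero
outside the cell.  Five binary masks (cytoplasm, nucleus, cell membrane,
nuclear membrane, single-pixel shmoo tip) mirror the segmentation inputs
the digitizer expects.

Everything is deterministic for a fixed seed; the seed only randomizes the
protrusion direction so different scenes exercise different geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .digitize import BinaryMask, IntensityImage

__all__ = ["CellScene", "make_scene", "make_masks", "make_signal_image", "MASK_ORDER"]

#: canonical order of mask application for the digitizer
MASK_ORDER = ("cytoplasm", "nucleus", "cell_membrane", "nuclear_membrane", "shmoo_tip")


@dataclass
class CellScene:
    """Parameters fully determining one synthetic cell image.

    Intensities are in arbitrary units on the chosen bit depth's scale;
    ``decay_length`` is the exponential gradient's length constant (px).
    """

    shape: tuple[int, int]  # (H, W)
    cell_center: tuple[float, float]  # (x, y)
    cell_axes: tuple[float, float]  # ellipse semi-axes (a, b), px
    bump_radius: float  # protrusion disk radius, px
    tip_angle: float  # direction of the protrusion, rad
    nucleus_center: tuple[float, float]
    nucleus_radius: float
    membrane_thickness: int  # px
    decay_length: float  # lambda, px
    peak_intensity: float  # I_max at the tip, a.u.
    nucleus_intensity: float  # I_nuc, uniform, a.u.
    tip_pixel: tuple[int, int]  # (row, col) on the cell membrane
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if self.membrane_thickness < 1:
            raise ValueError("membrane_thickness must be >= 1")
        if not _nucleus_inside_cell(self):
            raise ValueError("nucleus disk is not strictly inside the cell")


def _pixel_centers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return xs + 0.5, ys + 0.5


def _inside_cell(scene: CellScene) -> np.ndarray:
    """Boolean grid of the full cell body: ellipse plus protrusion disk."""
    xs, ys = _pixel_centers(scene.shape)
    cx, cy = scene.cell_center
    a, b = scene.cell_axes
    ellipse = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
    bx = cx + a * math.cos(scene.tip_angle)
    by = cy + b * math.sin(scene.tip_angle)
    bump = (xs - bx) ** 2 + (ys - by) ** 2 <= scene.bump_radius**2
    return ellipse | bump


def _nucleus_disk(scene: CellScene) -> np.ndarray:
    xs, ys = _pixel_centers(scene.shape)
    nx, ny = scene.nucleus_center
    return (xs - nx) ** 2 + (ys - ny) ** 2 <= scene.nucleus_radius**2


def _nucleus_inside_cell(scene: CellScene) -> bool:
    cx, cy = scene.cell_center
    a, b = scene.cell_axes
    nx, ny = scene.nucleus_center
    # sample the nucleus rim; every rim point must be inside the ellipse
    th = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    px = nx + scene.nucleus_radius * np.cos(th)
    py = ny + scene.nucleus_radius * np.sin(th)
    return bool(np.all(((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 < 1.0))


def _erode(grid: np.ndarray, thickness: int) -> np.ndarray:
    return ndimage.binary_erosion(grid, iterations=thickness, border_value=0)


def make_masks(scene: CellScene) -> dict[str, BinaryMask]:
    """The five compartment masks, pairwise disjoint, union = cell body.

    Membranes are rings of ``membrane_thickness`` at the cell / nucleus
    boundaries; the shmoo tip is a single membrane pixel (removed from the
    cell-membrane mask so the masks stay disjoint).
    """
    scene.validate()
    inside = _inside_cell(scene)
    interior = _erode(inside, scene.membrane_thickness)
    cell_membrane = inside & ~interior
    ndisk = _nucleus_disk(scene)
    nucleus = _erode(ndisk, scene.membrane_thickness)
    nuclear_membrane = ndisk & ~nucleus
    cytoplasm = interior & ~ndisk
    r, c = scene.tip_pixel
    if not cell_membrane[r, c]:
        raise ValueError(f"tip pixel {scene.tip_pixel} is not on the cell membrane")
    tip = np.zeros(scene.shape, dtype=bool)
    tip[r, c] = True
    cell_membrane = cell_membrane & ~tip
    return {
        "cytoplasm": BinaryMask(cytoplasm, "cytoplasm"),
        "nucleus": BinaryMask(nucleus, "nucleus"),
        "cell_membrane": BinaryMask(cell_membrane, "cell_membrane"),
        "nuclear_membrane": BinaryMask(nuclear_membrane, "nuclear_membrane"),
        "shmoo_tip": BinaryMask(tip, "shmoo_tip"),
    }


def signal_field(scene: CellScene, masks: dict[str, BinaryMask] | None = None) -> np.ndarray:
    """Unquantized signal: I_max * exp(-dist(p, tip)/lambda) in the cytoplasm
    and on both membranes and the tip, I_nuc in the nucleus, 0 outside."""
    if masks is None:
        masks = make_masks(scene)
    xs, ys = _pixel_centers(scene.shape)
    r, c = scene.tip_pixel
    dist = np.hypot(xs - (c + 0.5), ys - (r + 0.5))
    gradient = scene.peak_intensity * np.exp(-dist / scene.decay_length)
    field = np.zeros(scene.shape, dtype=float)
    for name in ("cytoplasm", "cell_membrane", "nuclear_membrane", "shmoo_tip"):
        g = masks[name].grid
        field[g] = gradient[g]
    field[masks["nucleus"].grid] = scene.nucleus_intensity
    return field


def make_signal_image(scene: CellScene, species: str = "Fus3PP") -> IntensityImage:
    """Quantize the signal field to the scene's bit depth."""
    field = signal_field(scene)
    vmax = 2**scene.bit_depth - 1
    return IntensityImage(np.clip(np.round(field), 0, vmax), species)


_PRESETS = {
    # shape, cell center, semi-axes, bump radius, nucleus radius,
    # nucleus offset fraction (toward the side opposite the tip),
    # membrane thickness, decay length
    "paper_like": dict(
        shape=(400, 400),
        center=(190.0, 200.0),
        axes=(150.0, 110.0),
        bump_radius=28.0,
        nucleus_radius=45.0,
        nucleus_offset=0.25,
        thickness=2,
        decay_length=80.0,
    ),
    "minimal": dict(
        shape=(100, 100),
        center=(47.0, 50.0),
        axes=(36.0, 28.0),
        bump_radius=8.0,
        nucleus_radius=12.0,
        nucleus_offset=0.25,
        thickness=2,
        decay_length=24.0,
    ),
}

#: per-pixel cytoplasm-mean / nucleus ratio the presets are calibrated to
TARGET_RATIO = 0.80


def make_scene(preset: str, seed: int = 0) -> CellScene:
    """Deterministic scene for a preset and seed.

    The seed randomizes the protrusion (tip) direction within a cone around
    the +x axis; the nucleus sits offset toward the opposite side.  The
    nucleus intensity is derived from the generated cytoplasm field so the
    per-pixel cytoplasm/nucleus mean ratio equals ``TARGET_RATIO``.
    """
    try:
        p = _PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}") from None
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(-0.35, 0.35))
    cx, cy = p["center"]
    a, b = p["axes"]
    nc = (cx - p["nucleus_offset"] * a * math.cos(angle),
          cy - p["nucleus_offset"] * b * math.sin(angle))
    scene = CellScene(
        shape=p["shape"],
        cell_center=(cx, cy),
        cell_axes=(a, b),
        bump_radius=p["bump_radius"],
        tip_angle=angle,
        nucleus_center=nc,
        nucleus_radius=p["nucleus_radius"],
        membrane_thickness=p["thickness"],
        decay_length=p["decay_length"],
        peak_intensity=255.0,
        nucleus_intensity=1.0,  # placeholder until calibrated below
        tip_pixel=(0, 0),  # placeholder
        bit_depth=8,
        seed=seed,
    )
    # tip = membrane pixel furthest along the protrusion direction
    inside = _inside_cell(scene)
    membrane = inside & ~_erode(inside, scene.membrane_thickness)
    rr, cc = np.nonzero(membrane)
    proj = (cc + 0.5 - cx) * math.cos(angle) + (rr + 0.5 - cy) * math.sin(angle)
    k = int(np.argmax(proj))
    scene.tip_pixel = (int(rr[k]), int(cc[k]))
    # calibrate the nucleus intensity against the unquantized cytoplasm mean
    masks = make_masks(scene)
    field = signal_field(scene, masks)
    cyto_mean = float(field[masks["cytoplasm"].grid].mean())
    scene.nucleus_intensity = cyto_mean / TARGET_RATIO
    scene.validate()
    return scene
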