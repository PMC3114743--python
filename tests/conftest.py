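import numpy as np
import pytest

from voromesh import digitize as dg
from voromesh import mesh as mm
from voromesh import synth


@pytest.fixture()
def two_cell_mesh():
    """Two 0.5x1.0 rectangles splitting the unit square at x = 0.5."""
    seeds = mm.SeedSet([[0.25, 0.5], [0.75, 0.5]], (0, 0, 1, 1))
    return mm.compute_adjacency(mm.build_voronoi_mesh(seeds))


@pytest.fixture()
def quad_mesh():
    """2x2 grid of 0.5x0.5 squares in the unit square."""
    seeds = mm.SeedSet(
        [[0.25, 0.25], [0.75, 0.25], [0.25, 0.75], [0.75, 0.75]], (0, 0, 1, 1)
    )
    return mm.compute_adjacency(mm.build_voronoi_mesh(seeds))


def make_chain(n, width=1.0):
    """1D chain of n unit square cells along +x."""
    seeds = mm.SeedSet([[i + 0.5, width / 2] for i in range(n)], (0, 0, n, width))
    return mm.compute_adjacency(mm.build_voronoi_mesh(seeds))


@pytest.fixture(scope="session")
def minimal_scene():
    return synth.make_scene("minimal", 0)


@pytest.fixture(scope="session")
def minimal_digitized(minimal_scene):
    """Fully digitized minimal scene: typed mesh with acquired signal.

    Returns (scene, masks, image, mesh, labels).
    """
    scene = minimal_scene
    masks = synth.make_masks(scene)
    image = synth.make_signal_image(scene)
    h, w = scene.shape
    seeds = mm.generate_hex_seeds((0, 0, w, h), 4.0)
    mesh = mm.compute_adjacency(mm.build_voronoi_mesh(seeds))
    labels = dg.label_grid(mesh)
    dg.assign_types(mesh, [masks[k] for k in synth.MASK_ORDER], "outside", labels=labels)
    r, c = scene.tip_pixel
    dg.set_type_at_point(mesh, (c + 0.5, r + 0.5), "shmoo_tip", labels=labels)
    dg.acquire_signal(mesh, image, labels=labels)
    return scene, masks, image, mesh, labels


def brute_force_nearest_labels(seeds: np.ndarray, width: int, height: int):
    """Oracle: label every pixel center by its nearest seed (lowest id wins
    ties); returns (labels, tied) where tied marks pixels whose two smallest
    seed distances differ by <= 1e-9."""
    xs, ys = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]
    rows = np.arange(len(pts))
    tied = np.sqrt(d2[rows, second]) - np.sqrt(d2[rows, best]) <= 1e-9
    # lowest id among (near-)exact ties
    labels = best.copy()
    swap = tied & (second < best)
    labels[swap] = second[swap]
    return labels.reshape(height, width), tied.reshape(height, width)
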