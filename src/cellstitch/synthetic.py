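"""Synthetic 3D cell scenes and derived 2D mask stacks for end-to-end testing.

The generator emulates what the stitching pipeline actually consumes:
densely packed convex-ish cells (Voronoi regions of well-separated seed
points, or ellipsoids clipped against their neighbours), per-plane
independently labeled 2D masks as a 2D segmenter would emit them,
over-segmentation and boundary-noise perturbations, and anisotropy via
keep-every-Nth Z-subsampling.  All outputs are pure functions of
``(config, seed)``: a single named NumPy generator is threaded through every
stochastic step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cellstitch.volumes import LabelVolume

_SIX_CONN = ndimage.generate_binary_structure(3, 1)

#: total seed-placement draws before giving up
_MAX_DRAWS = 1000
#: full-scene retries when a realization violates the cell-shape contract
_MAX_SCENE_TRIES = 25


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of a synthetic ground-truth scene.

    shape
        Volume extent ``(Z, Y, X)`` in voxels.
    n_cells
        Number of cells; labels are ``1..n_cells``.
    min_seed_distance
        Minimum pairwise Euclidean distance between cell seed points, in
        voxels; controls packing regularity.
    foreground_margin
        Background shell thickness at the volume border, in voxels.
    cell_model
        ``"voronoi"`` — cells tile the foreground box as Voronoi regions of
        the seeds; ``"ellipsoid"`` — solid ellipsoids around the seeds,
        clipped against neighbours, with background in between.
    radius_range / axis_ratio_range
        Ellipsoid-model only: mean radius drawn uniformly from
        ``radius_range`` (default ``0.35..0.48 * min_seed_distance``) and
        per-axis semi-axes scaled by ratios from ``axis_ratio_range``
        (``(1.0, 1.0)`` gives spheres).
    """

    shape: tuple
    n_cells: int
    seed: int = 0
    min_seed_distance: float = 8.0
    foreground_margin: int = 1
    cell_model: str = "voronoi"
    radius_range: tuple | None = None
    axis_ratio_range: tuple = (1.0, 1.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive integers (Z, Y, X)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.cell_model not in ("voronoi", "ellipsoid"):
            raise ValueError("cell_model must be 'voronoi' or 'ellipsoid'")


@dataclass(frozen=True)
class PerturbConfig:
    """Per-plane corruption emulating an imperfect 2D segmenter.

    split_probability
        Chance that a cell slice is cut in two by a random chord through its
        centroid (planar over-segmentation).
    jitter_radius
        Maximum boundary erosion/dilation per cell slice, in pixels.
    drop_probability
        Chance that a whole plane is blanked to background.
    """

    split_probability: float = 0.0
    jitter_radius: int = 0
    drop_probability: float = 0.0

    def __post_init__(self):
        for name in ("split_probability", "drop_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.jitter_radius < 0:
            raise ValueError("jitter_radius must be non-negative")


def _place_seeds(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    lo = np.full(3, float(config.foreground_margin))
    hi = np.asarray(config.shape, dtype=float) - config.foreground_margin
    if np.any(hi <= lo):
        raise ValueError("foreground_margin leaves no room for seeds")
    seeds: list = []
    for _ in range(_MAX_DRAWS):
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= config.min_seed_distance for q in seeds):
            seeds.append(p)
            if len(seeds) == config.n_cells:
                return np.asarray(seeds)
    raise RuntimeError(
        f"could not place {config.n_cells} seeds at min distance "
        f"{config.min_seed_distance} within {_MAX_DRAWS} draws"
    )


def _foreground_box(shape: tuple, margin: int) -> np.ndarray:
    fg = np.zeros(shape, dtype=bool)
    if margin == 0:
        fg[:] = True
    else:
        fg[margin:-margin or None, margin:-margin or None, margin:-margin or None] = True
    return fg


def _voronoi_labels(config: SceneConfig, seeds: np.ndarray) -> np.ndarray:
    coords = np.argwhere(_foreground_box(config.shape, config.foreground_margin))
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    owner = np.argmin(d2, axis=1) + 1
    vol = np.zeros(config.shape, dtype=np.uint32)
    vol[tuple(coords.T)] = owner
    return vol


def _ellipsoid_labels(config: SceneConfig, seeds: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    if config.radius_range is None:
        rr = (0.35 * config.min_seed_distance, 0.48 * config.min_seed_distance)
    else:
        rr = config.radius_range
    radii = rng.uniform(rr[0], rr[1], size=config.n_cells)
    ratios = rng.uniform(config.axis_ratio_range[0], config.axis_ratio_range[1],
                         size=(config.n_cells, 3))
    semiaxes = radii[:, None] * ratios
    coords = np.argwhere(_foreground_box(config.shape, config.foreground_margin))
    # normalized squared distance to each seed; <= 1 means inside that ellipsoid
    nd2 = (((coords[:, None, :] - seeds[None, :, :]) / semiaxes[None, :, :]) ** 2
           ).sum(axis=2)
    owner = np.argmin(nd2, axis=1)
    inside = nd2[np.arange(coords.shape[0]), owner] <= 1.0
    vol = np.zeros(config.shape, dtype=np.uint32)
    vol[tuple(coords[inside].T)] = owner[inside] + 1
    return vol


def _valid_scene(vol: np.ndarray, n_cells: int) -> bool:
    for lab in range(1, n_cells + 1):
        mask = vol == lab
        if not mask.any():
            return False
        if np.unique(np.nonzero(mask)[0]).size < 2:
            return False
        if ndimage.label(mask, structure=_SIX_CONN)[1] != 1:
            return False
    return True


def generate_scene(config: SceneConfig, return_seeds: bool = False):
    """Deterministic ground-truth volume with labels ``1..n_cells``.

    Every cell is 6-connected and spans at least two Z-layers; realizations
    violating that (e.g. a cell clipped to one layer) are re-drawn from the
    same generator stream, so the result is still a pure function of the
    config.  With ``return_seeds`` the ``(n_cells, 3)`` array of seed points
    (in (Z, Y, X) voxel coordinates) is returned alongside the volume.
    """
    rng = np.random.default_rng(config.seed)
    for _ in range(_MAX_SCENE_TRIES):
        seeds = _place_seeds(config, rng)
        if config.cell_model == "voronoi":
            vol = _voronoi_labels(config, seeds)
        else:
            vol = _ellipsoid_labels(config, seeds, rng)
        if _valid_scene(vol, config.n_cells):
            volume = LabelVolume(vol)
            return (volume, seeds) if return_seeds else volume
    raise RuntimeError("could not generate a valid scene; relax the config")


def split_slice(plane: np.ndarray, label: int, rng: np.random.Generator) -> bool:
    """Cut one cell slice in two by a random chord through its centroid.

    Returns True when the cut produced two non-empty parts (the new part
    gets a fresh label); single-pixel or degenerate cuts leave the plane
    unchanged.
    """
    mask = plane == label
    pts = np.argwhere(mask)
    if pts.shape[0] < 2:
        return False
    cy, cx = pts.mean(axis=0)
    theta = rng.uniform(0.0, np.pi)
    signed = (pts[:, 0] - cy) * -np.sin(theta) + (pts[:, 1] - cx) * np.cos(theta)
    half = signed >= 0
    if half.all() or not half.any():
        return False
    new_label = int(plane.max()) + 1
    sel = pts[half]
    plane[sel[:, 0], sel[:, 1]] = new_label
    return True


def _jitter_slice(plane: np.ndarray, label: int, radius: int,
                  rng: np.random.Generator) -> None:
    """Erode or dilate one cell slice by up to ``radius`` pixels.

    Dilation only claims background pixels; erosion keeps at least one pixel.
    """
    amount = int(rng.integers(0, radius + 1))
    if amount == 0:
        return
    mask = plane == label
    if bool(rng.integers(0, 2)):
        grown = ndimage.binary_dilation(mask, iterations=amount)
        plane[grown & (plane == 0)] = label
    else:
        shrunk = ndimage.binary_erosion(mask, iterations=amount, border_value=0)
        if shrunk.any():
            plane[mask & ~shrunk] = 0


def slice_masks(gt: LabelVolume, axis: str = "z",
                perturb: PerturbConfig | None = None,
                seed: int = 0) -> np.ndarray:
    """Per-plane independently labeled masks, as a 2D segmenter would emit.

    ``axis="z"`` yields the stack of (Y, X) masks; ``axis="x"`` the YZ-plane
    stack ``(X, Z, Y)``; ``axis="y"`` the XZ-plane stack ``(Y, Z, X)``.
    Each plane's labels are renumbered ``1..k`` in a random order
    (background preserved), then optionally perturbed: cell slices split by
    a random chord, boundaries jittered, whole planes blanked.
    """
    axis = axis.lower()
    if axis == "z":
        stack = gt.data.copy()
    elif axis == "x":
        stack = gt.data.transpose(2, 0, 1).copy()
    elif axis == "y":
        stack = gt.data.transpose(1, 0, 2).copy()
    else:
        raise ValueError(f"axis must be 'z', 'x' or 'y', got {axis!r}")

    rng = np.random.default_rng(seed)
    out = np.zeros_like(stack)
    for i in range(stack.shape[0]):
        plane_in = stack[i]
        labels = np.unique(plane_in)
        labels = labels[labels > 0]
        new = rng.permutation(labels.size) + 1
        plane = np.zeros_like(plane_in)
        for old, fresh in zip(labels, new):
            plane[plane_in == old] = fresh
        if perturb is not None:
            if perturb.drop_probability and rng.random() < perturb.drop_probability:
                out[i] = 0
                continue
            for lab in list(np.unique(plane[plane > 0])):
                if perturb.split_probability and rng.random() < perturb.split_probability:
                    split_slice(plane, int(lab), rng)
            if perturb.jitter_radius:
                for lab in list(np.unique(plane[plane > 0])):
                    _jitter_slice(plane, int(lab), perturb.jitter_radius, rng)
        out[i] = plane
    return out


def subsample_z(volume: LabelVolume, factor: int, phase: int = 0) -> LabelVolume:
    """Keep layers with index congruent to ``phase`` modulo ``factor``.

    This is the anisotropy-degradation protocol ("remove every other layer",
    generalized to keep-every-Nth).
    """
    if factor < 2:
        raise ValueError("subsampling factor must be >= 2")
    if volume.depth <= factor:
        raise ValueError("volume depth must exceed the subsampling factor")
    if not 0 <= phase < factor:
        raise ValueError("phase must lie in [0, factor)")
    kept = volume.data[phase::factor]
    if kept.shape[0] == 0:
        raise ValueError("subsampling would leave no layers")
    return LabelVolume(kept.copy())
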