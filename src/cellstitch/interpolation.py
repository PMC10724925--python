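"""Wasserstein interpolation of internal layers between matched cell slices.

Anisotropic stacks sample Z more coarsely than X/Y by a factor N.  Cells are
locally cylindrical, so the missing morphology between two consecutive slices
of the same (stitched) cell can be predicted by morphing one slice into the
other: an exact optimal transport plan is computed between the uniform
distributions on the two slices' boundary pixels under squared-Euclidean
cost, and each internal layer k = 1..N-1 is the rasterized weighted average
``(1 - k/N) * p + (k/N) * q`` over all coupled boundary pairs (p, q),
closed and hole-filled into a solid mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cellstitch._transport import exact_transport
from cellstitch.volumes import LabelVolume

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)
_CLOSE_SE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BoundarySet:
    """Contour pixels of one cell slice: cell pixels with a 4-neighbour
    outside the cell (image borders count as outside)."""

    points: np.ndarray  # (n, 2) int, rows are (Y, X), lexicographically sorted

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class BoundaryCoupling:
    """Exact OT coupling between uniform distributions on two boundaries.

    Rows of ``coupling`` index source points, columns target points; row sums
    are ``1/len(src)`` and column sums ``1/len(tgt)``.  The support of the
    coupling is the partial matching used for interpolation.
    """

    src_points: np.ndarray
    tgt_points: np.ndarray
    coupling: np.ndarray
    objective: float

    def pairs(self, tol: float = 1e-12):
        """(source point, target point, weight) triples with weight > tol."""
        ii, jj = np.nonzero(self.coupling > tol)
        return list(zip(map(tuple, self.src_points[ii]),
                        map(tuple, self.tgt_points[jj]),
                        self.coupling[ii, jj]))


@dataclass(frozen=True)
class InterpolationConfig:
    """Anisotropy factor N (Z spacing / XY spacing); N - 1 internal layers
    are generated per adjacent pair."""

    anisotropy: int = 2
    fill_method: str = "close-and-fill"
    conflict_rule: str = "first-wins"

    def __post_init__(self):
        if self.anisotropy < 2:
            raise ValueError("anisotropy must be an integer >= 2")
        if self.fill_method != "close-and-fill":
            raise ValueError("only 'close-and-fill' filling is supported")
        if self.conflict_rule != "first-wins":
            raise ValueError("only 'first-wins' conflict resolution is supported")


def extract_boundary(layer, label: int) -> BoundarySet:
    """4-connectivity contour of one label's support in a 2D label image."""
    arr = np.asarray(layer)
    mask = arr == label
    if not mask.any():
        raise ValueError(f"label {label} absent from layer")
    interior = ndimage.binary_erosion(mask, structure=_FOUR_CONN, border_value=0)
    pts = np.argwhere(mask & ~interior)
    return BoundarySet(points=pts)  # argwhere is already lexicographic


def boundary_coupling(src: BoundarySet, tgt: BoundarySet) -> BoundaryCoupling:
    """Exact 2-Wasserstein coupling between two boundary point sets.

    Marginals are uniform on each set; the cost is squared Euclidean
    distance between pixel coordinates.
    """
    if len(src) == 0 or len(tgt) == 0:
        raise ValueError("boundaries must be non-empty")
    p = src.points.astype(float)
    q = tgt.points.astype(float)
    cost = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
    a = np.full(len(src), 1.0 / len(src))
    b = np.full(len(tgt), 1.0 / len(tgt))
    coupling, objective = exact_transport(a, b, cost)
    return BoundaryCoupling(src_points=src.points, tgt_points=tgt.points,
                            coupling=coupling, objective=objective)


def _round_half_away(v: np.ndarray) -> np.ndarray:
    """Round half away from zero, independently per coordinate."""
    return np.copysign(np.floor(np.abs(v) + 0.5), v)


def _fill(points: np.ndarray, shape: tuple) -> np.ndarray:
    """Rasterize boundary points and close + fill them into a solid mask."""
    mask = np.zeros(shape, dtype=bool)
    mask[points[:, 0], points[:, 1]] = True
    closed = ndimage.binary_closing(mask, structure=_CLOSE_SE)
    # closing can drop isolated pixels; the rasterized points always belong
    closed |= mask
    return ndimage.binary_fill_holes(closed, structure=_FOUR_CONN)


def interpolate_pair(src_slice, tgt_slice,
                     config: InterpolationConfig) -> list:
    """Morph one cell slice into another, producing N - 1 internal masks.

    ``src_slice`` and ``tgt_slice`` are ``(layer, label)`` pairs of equal
    shape.  For k = 1..N-1 the interpolated boundary is the rounded weighted
    average of every coupled boundary pair at weight alpha = k/N, filled into
    a binary support.
    """
    src_layer, src_label = src_slice
    tgt_layer, tgt_label = tgt_slice
    src_layer = np.asarray(src_layer)
    tgt_layer = np.asarray(tgt_layer)
    if src_layer.shape != tgt_layer.shape:
        raise ValueError("slice shapes differ")
    bs = extract_boundary(src_layer, src_label)
    bt = extract_boundary(tgt_layer, tgt_label)
    cpl = boundary_coupling(bs, bt)
    ii, jj = np.nonzero(cpl.coupling > 1e-12)
    p = bs.points[ii].astype(float)
    q = bt.points[jj].astype(float)

    n = config.anisotropy
    alphas = np.arange(1, n) / n
    # all internal layers from the single coupling, vectorized over k
    pts = (1.0 - alphas)[:, None, None] * p[None] + alphas[:, None, None] * q[None]
    pts = _round_half_away(pts).astype(int)
    return [_fill(pts[k], src_layer.shape) for k in range(n - 1)]


def interpolate_volume(stitched: LabelVolume,
                       config: InterpolationConfig) -> LabelVolume:
    """Insert N - 1 interpolated layers between every adjacent layer pair.

    Output depth is ``(depth - 1) * N + 1``; original layers sit unchanged at
    ``z * N``.  Each label present in both layers z and z+1 contributes its
    interpolated masks to the internal layers; a label present on one side
    only stops at its last original layer.  Voxels claimed by several cells'
    interpolants go to the lowest label (first-wins).
    """
    n = config.anisotropy
    data = stitched.data
    depth = data.shape[0]
    out = np.zeros(((depth - 1) * n + 1,) + data.shape[1:], dtype=data.dtype)
    out[::n] = data
    for z in range(depth - 1):
        shared = np.intersect1d(np.unique(data[z]), np.unique(data[z + 1]))
        for lab in shared[shared > 0]:
            masks = interpolate_pair((data[z], lab), (data[z + 1], lab), config)
            for k, m in enumerate(masks, start=1):
                layer = out[z * n + k]
                layer[m & (layer == 0)] = lab
    return LabelVolume(out)
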