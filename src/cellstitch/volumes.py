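"""Label images, label volumes, orthogonal mask stacks, and their file formats.

Conventions used throughout the package:

* a 2D label image is an integer array indexed ``(Y, X)``; label 0 is
  background, foreground labels are positive and need not be contiguous;
* a label volume is a stack of such images with axis order ``(Z, Y, X)``;
* orthogonal mask stacks hold one independently labeled 2D mask per
  cross-section: YZ-planes indexed by X (each ``(Z, Y)``) and XZ-planes
  indexed by Y (each ``(Z, X)``).

Volumes are stored either as multi-page TIFF (one page per Z-layer, via
:mod:`tifffile`) or as a NumPy ``.npz`` archive holding a single 3D integer
array named ``"labels"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

#: in-memory label dtype; stitched volumes can exceed 65535 labels
LABEL_DTYPE = np.uint32

_MAX_LABEL = np.iinfo(LABEL_DTYPE).max


class LabelVolume:
    """A Z-stack of 2D integer label images with axis order ``(Z, Y, X)``.

    After stitching, equal nonzero labels across layers denote the same cell.
    """

    def __init__(self, data: np.ndarray) -> None:
        arr = np.asarray(data)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be 3D (Z, Y, X), got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"label volume must be non-empty, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise TypeError(f"label volume requires integer pixels, got {arr.dtype}")
        if arr.size and int(arr.min()) < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if arr.size and int(arr.max()) > _MAX_LABEL:
            raise OverflowError(f"labels exceed {LABEL_DTYPE.__name__} range")
        self.data = arr.astype(LABEL_DTYPE, copy=True)

    @classmethod
    def from_layers(cls, layers) -> "LabelVolume":
        layers = [np.asarray(l) for l in layers]
        if not layers:
            raise ValueError("cannot build a volume from zero layers")
        shape = layers[0].shape
        if any(l.shape != shape for l in layers):
            raise ValueError("all layers must share the same (height, width)")
        return cls(np.stack(layers, axis=0))

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def depth(self) -> int:
        return self.data.shape[0]

    def layer(self, z: int) -> np.ndarray:
        return self.data[z]

    def labels(self) -> np.ndarray:
        """Sorted array of foreground labels present anywhere in the volume."""
        labs = np.unique(self.data)
        return labs[labs > 0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelVolume):
            return NotImplemented
        return self.data.shape == other.data.shape and bool(
            np.array_equal(self.data, other.data)
        )


@dataclass(frozen=True)
class OrthogonalMasks:
    """Per-plane 2D masks along the two non-stitching directions.

    ``yz`` has shape ``(X, Z, Y)`` — one independently labeled (Z, Y) mask per
    X index.  ``xz`` has shape ``(Y, Z, X)`` — one (Z, X) mask per Y index.
    Labels carry no meaning across planes.
    """

    yz: np.ndarray
    xz: np.ndarray

    def __post_init__(self):
        for name, arr in (("yz", self.yz), ("xz", self.xz)):
            if arr.ndim != 3 or not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(f"{name} mask stack must be a 3D integer array")

    def check_compatible(self, volume_shape: tuple) -> None:
        z, y, x = volume_shape
        if self.yz.shape != (x, z, y):
            raise ValueError(
                f"YZ mask stack shape {self.yz.shape} incompatible with "
                f"volume {volume_shape}; expected {(x, z, y)}"
            )
        if self.xz.shape != (y, z, x):
            raise ValueError(
                f"XZ mask stack shape {self.xz.shape} incompatible with "
                f"volume {volume_shape}; expected {(y, z, x)}"
            )


def reslice(volume: LabelVolume, axis: str) -> np.ndarray:
    """Cross-section a volume along X or Y into an orthogonal plane stack.

    ``axis="x"`` returns the YZ-plane stack ``(X, Z, Y)`` with
    ``out[x][z, y] == volume.data[z, y, x]``; ``axis="y"`` returns the
    XZ-plane stack ``(Y, Z, X)`` with ``out[y][z, x] == volume.data[z, y, x]``.
    Pixel values are copied, never relabeled.
    """
    axis = axis.lower()
    if axis == "x":
        return volume.data.transpose(2, 0, 1).copy()
    if axis == "y":
        return volume.data.transpose(1, 0, 2).copy()
    raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("tiff", "npz"):
            raise ValueError(f"unknown format {fmt!r}; use 'tiff' or 'npz'")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return "tiff"
    if ext == ".npz":
        return "npz"
    raise ValueError(f"cannot infer format from {path!r}; pass format explicitly")


def read_label_volume(path, fmt: str | None = None) -> LabelVolume:
    """Read a label volume from a multi-page TIFF or an ``.npz`` archive.

    Pages/slices are ordered by index and values are preserved exactly.
    Raises ``TypeError`` for non-integer pixel types and ``ValueError`` for
    ragged pages.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tf:
            shapes = {page.shape for page in tf.pages}
            if len(shapes) > 1:
                raise ValueError(
                    f"pages of {path} do not share a single shape: {sorted(shapes)}"
                )
            arr = np.asarray(tf.asarray())
        if arr.ndim == 2:
            arr = arr[None]
    else:
        with np.load(path) as archive:
            if "labels" not in archive:
                raise ValueError(f"{path} does not contain a 'labels' array")
            arr = archive["labels"]
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError(f"{path} holds {arr.dtype} pixels; label volumes are integer")
    return LabelVolume(arr)


def _smallest_dtype(max_label: int):
    for dt in (np.uint8, np.uint16, np.uint32):
        if max_label <= np.iinfo(dt).max:
            return dt
    raise OverflowError(f"label {max_label} exceeds 32-bit container width")


def write_label_volume(volume: LabelVolume, path, fmt: str | None = None, dtype=None) -> None:
    """Write a label volume losslessly; ``read_label_volume`` inverts it.

    ``dtype`` forces the on-disk integer width; by default the smallest of
    uint8/uint16/uint32 that fits the maximum label is used.  A forced width
    that cannot hold the maximum label raises ``OverflowError``.
    """
    fmt = _infer_format(path, fmt)
    max_label = int(volume.data.max()) if volume.data.size else 0
    if dtype is None:
        dtype = _smallest_dtype(max_label)
    else:
        dtype = np.dtype(dtype)
        if not np.issubdtype(dtype, np.integer):
            raise TypeError("on-disk dtype must be an integer type")
        if max_label > np.iinfo(dtype).max:
            raise OverflowError(
                f"max label {max_label} exceeds {dtype} container width"
            )
    out = volume.data.astype(dtype)
    if fmt == "tiff":
        tifffile.imwrite(path, out)
    else:
        np.savez(path, labels=out)
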