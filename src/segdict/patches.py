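"""Overlapping patch extraction and overlap-averaged reassembly.

A patch set is the sample matrix M of patch-based sparse coding: each
column is one vectorized p-by-p patch (row-major pixel order), tagged
with its top-left origin in the source image.  Origins are enumerated in
raster order with a fixed stride; whenever ``dim - p`` is not a multiple
of the stride a final origin is clamped flush against the border, so
every pixel of the source is covered by at least one patch and no
padding values are ever introduced.

Reassembly resolves overlaps by the unweighted mean of all patch values
covering a pixel, which makes extract → assemble an exact round trip
when the patch contents are left unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import as_pixels

__all__ = ["PatchConfig", "PatchSet", "extract_patches", "assemble_patches"]


@dataclass(frozen=True)
class PatchConfig:
    """Square patch geometry: side length ``patch_size`` and origin stride."""

    patch_size: int = 8
    stride: int = 2

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if not 1 <= self.stride <= self.patch_size:
            raise ValueError("stride must satisfy 1 <= stride <= patch_size")


@dataclass
class PatchSet:
    """Vectorized patches (one per column) with their origins.

    Attributes
    ----------
    data : ndarray of shape (patch_size**2, n_patches)
        One row-major vectorized patch per column.
    origins : ndarray of shape (n_patches, 2)
        (row, col) of each patch's top-left pixel.
    patch_size : int
    source_shape : tuple of int
        (height, width) of the image the patches came from.
    """

    data: np.ndarray
    origins: np.ndarray
    patch_size: int
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.origins = np.asarray(self.origins, dtype=int)
        p = self.patch_size
        if self.data.ndim != 2 or self.data.shape[0] != p * p:
            raise ValueError("data must have patch_size**2 rows")
        if self.origins.shape != (self.data.shape[1], 2):
            raise ValueError("origins must be one (row, col) pair per patch")
        h, w = self.source_shape
        if self.data.shape[1] < 1:
            raise ValueError("a PatchSet must contain at least one patch")
        if (
            (self.origins < 0).any()
            or (self.origins[:, 0] > h - p).any()
            or (self.origins[:, 1] > w - p).any()
        ):
            raise ValueError("every origin must place its patch fully inside the source")

    @property
    def n_patches(self) -> int:
        return self.data.shape[1]


def _axis_origins(dim: int, patch_size: int, stride: int) -> np.ndarray:
    """Origins along one axis: regular grid plus a flush-to-border tail."""
    last = dim - patch_size
    offsets = list(range(0, last + 1, stride))
    if offsets[-1] != last:
        offsets.append(last)
    return np.asarray(offsets, dtype=int)


def extract_patches(image, cfg: PatchConfig = PatchConfig()) -> PatchSet:
    """Extract all overlapping patches of ``image`` under ``cfg``.

    Raises
    ------
    ValueError
        If the image is smaller than the patch in either axis.
    """
    pixels = as_pixels(image)
    p, stride = cfg.patch_size, cfg.stride
    h, w = pixels.shape
    if h < p or w < p:
        raise ValueError(f"image {pixels.shape} is smaller than the {p}x{p} patch")
    rows = _axis_origins(h, p, stride)
    cols = _axis_origins(w, p, stride)
    windows = np.lib.stride_tricks.sliding_window_view(pixels, (p, p))
    # windows[r, c] is the patch with origin (r, c); select the origin grid.
    block = windows[np.ix_(rows, cols)]  # (n_rows, n_cols, p, p)
    data = block.reshape(len(rows) * len(cols), p * p).T.copy()
    origins = np.stack(
        np.meshgrid(rows, cols, indexing="ij"), axis=-1
    ).reshape(-1, 2)
    return PatchSet(data=data, origins=origins, patch_size=p, source_shape=(h, w))


def assemble_patches(patches: PatchSet) -> np.ndarray:
    """Reassemble an image, averaging all patch values covering each pixel.

    The inverse of :func:`extract_patches` for unmodified patch contents;
    for modified patches it is the standard overlap-average estimator.
    """
    if patches.n_patches == 0:
        raise ValueError("cannot assemble an empty PatchSet")
    p = patches.patch_size
    h, w = patches.source_shape
    acc = np.zeros((h, w))
    count = np.zeros((h, w))
    blocks = patches.data.T.reshape(-1, p, p)
    for (r, c), block in zip(patches.origins, blocks):
        acc[r : r + p, c : c + p] += block
        count[r : r + p, c : c + p] += 1.0
    if (count == 0).any():
        raise ValueError("patch set does not cover the full source image")
    return acc / count
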