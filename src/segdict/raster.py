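"""2-D grayscale image container and lossless raster / plain-matrix I/O.

Pixel intensities are held as ``float64`` internally regardless of the
source bit depth; quantization back to the source integer range happens
only when a raster file is written.  Supported on-disk formats:

* PNG and TIFF, 8- or 16-bit grayscale (via :mod:`imageio`);
* a plain-matrix text format — first line ``<height> <width> <real|complex>``,
  followed by one whitespace-delimited row per line — which round-trips
  float (and complex) arrays at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Image2D",
    "as_pixels",
    "read_image",
    "write_image",
    "read_matrix",
    "write_matrix",
]

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}
_MATRIX_SUFFIXES = {".txt", ".asc", ".dat"}


@dataclass
class Image2D:
    """A single-channel image with the bit depth of its source.

    Parameters
    ----------
    pixels : ndarray of shape (height, width)
        Real-valued intensities in the units of the source (e.g. digital
        numbers 0..255 for an 8-bit raster).  Always finite.
    bit_depth : int
        Bits per channel of the source file; sets the peak value
        ``2**bit_depth - 1`` used by PSNR.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must all be finite")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(image) -> np.ndarray:
    """Return the 2-D float array behind an :class:`Image2D` or ndarray."""
    if isinstance(image, Image2D):
        return image.pixels
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image intensities must all be finite")
    return arr


def read_image(path) -> Image2D:
    """Read a grayscale raster or plain-matrix file.

    The recorded ``bit_depth`` comes from the raster sample type (8 for
    ``uint8``, 16 for ``uint16``); matrix files default to 8.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _MATRIX_SUFFIXES:
        data = read_matrix(path)
        if np.iscomplexobj(data):
            raise ValueError(f"{path}: complex matrix cannot be read as an image")
        return Image2D(data, bit_depth=8)
    if suffix in _RASTER_SUFFIXES:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:
            if arr.shape[2] == 1:
                arr = arr[:, :, 0]
            else:
                raise ValueError(f"{path}: color images are not supported")
        if arr.dtype == np.uint8:
            depth = 8
        elif arr.dtype == np.uint16:
            depth = 16
        else:
            raise ValueError(f"{path}: unsupported sample type {arr.dtype}")
        return Image2D(arr.astype(float), bit_depth=depth)
    raise ValueError(f"{path}: unsupported image format '{suffix}'")


def write_image(image: Image2D, path) -> None:
    """Write an image; rasters are quantized to the image's bit depth."""
    path = Path(path)
    suffix = path.suffix.lower()
    if isinstance(image, Image2D):
        pixels, depth = image.pixels, image.bit_depth
    else:
        pixels, depth = as_pixels(image), 8
    if suffix in _MATRIX_SUFFIXES:
        write_matrix(pixels, path)
        return
    if suffix in _RASTER_SUFFIXES:
        import imageio.v3 as iio

        peak = 2**depth - 1
        dtype = np.uint8 if depth <= 8 else np.uint16
        quantized = np.clip(np.rint(pixels), 0, peak).astype(dtype)
        iio.imwrite(path, quantized)
        return
    raise ValueError(f"{path}: unsupported image format '{suffix}'")


def write_matrix(array: np.ndarray, path) -> None:
    """Write a 2-D real or complex array in the plain-matrix text format."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    kind = "complex" if np.iscomplexobj(arr) else "real"
    with open(path, "w") as fh:
        fh.write(f"{arr.shape[0]} {arr.shape[1]} {kind}\n")
        np.savetxt(fh, arr.astype(complex if kind == "complex" else float), fmt="%.18e")


def read_matrix(path) -> np.ndarray:
    """Read a plain-matrix text file written by :func:`write_matrix`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) not in (2, 3):
            raise ValueError(f"{path}: malformed matrix header")
        height, width = int(header[0]), int(header[1])
        kind = header[2] if len(header) == 3 else "real"
        dtype = complex if kind == "complex" else float
        data = np.loadtxt(fh, dtype=dtype, ndmin=2)
    if data.shape != (height, width):
        raise ValueError(
            f"{path}: header says {(height, width)} but data has shape {data.shape}"
        )
    return data
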