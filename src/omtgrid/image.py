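"""Core image type and TIFF I/O.

A microarray scan is a single-channel nonnegative integer matrix; rows are
the image y-axis.  All coordinates in the package are 0-based and intervals
are half-open ``[a, b)``; a separating line at coordinate c is the boundary
between pixel rows/columns c-1 and c.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MicroarrayImage", "read_image", "write_image"]

_U16_MAX = 65535


@dataclass(frozen=True)
class MicroarrayImage:
    """Single-channel intensity matrix A = {a_ij} in scanner units."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D single-channel image, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image too small: {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"intensities must be integers, got dtype {px.dtype}")
        if px.min() < 0:
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def crop(self, row_start: int, row_end: int, col_start: int, col_end: int) -> "MicroarrayImage":
        return MicroarrayImage(self.pixels[row_start:row_end, col_start:col_end])


def read_image(path: str | Path) -> MicroarrayImage:
    """Read a grayscale 8/16-bit TIFF, preserving integer bit depth."""
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (FileNotFoundError, OSError):
        raise
    except Exception as exc:  # malformed TIFF
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 3:
        raise ValueError(
            f"{path} has {data.shape[-1]} channels; expected a single-channel image"
        )
    if data.ndim != 2:
        raise ValueError(f"{path}: unsupported TIFF dimensionality {data.ndim}")
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: expected integer pixel data, got {data.dtype}")
    return MicroarrayImage(data)


def write_image(img: MicroarrayImage, path: str | Path) -> None:
    """Write as 8- or 16-bit grayscale TIFF (bit depth follows the data)."""
    px = img.pixels
    if px.max(initial=0) > _U16_MAX:
        raise ValueError("intensities exceed the 16-bit unsigned range")
    if px.dtype not in (np.uint8, np.uint16):
        px = px.astype(np.uint16)
    tifffile.imwrite(Path(path), px, photometric="minisblack")
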