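"""Grayscale image I/O with a fixed intensity contract.

Images live in memory as 2-D float64 grids in [0, 1]. On read, 8-bit values
map by /255 and 16-bit by /65535; multi-channel inputs are collapsed by the
channel mean with a warning. On write, intensities are quantized by
round-half-up back to the integer range: 8-bit PNG or 16-bit TIFF.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "write_mask"]


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a unit-range float64 grid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {suffix!r}")
    if arr.size == 0:
        raise ValueError(f"zero-size image {path}")
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise ValueError(f"unsupported pixel type {arr.dtype}")
    grid = arr.astype(np.float64) / scale
    if grid.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel input collapsed by channel mean")
        grid = grid.mean(axis=2)
    elif grid.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {grid.ndim}")
    return grid


def write_image(grid: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write a unit-range grid as 8-bit PNG or 16-bit TIFF (round-half-up)."""
    arr = np.asarray(grid, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("grid must be a non-empty 2-D array")
    path = Path(path)
    if bit_depth == 8:
        q = np.floor(np.clip(arr, 0, 1) * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(q, mode="L").save(path)
    elif bit_depth == 16:
        q = np.floor(np.clip(arr, 0, 1) * 65535.0 + 0.5).astype(np.uint16)
        tifffile.imwrite(path, q)
    else:
        raise ValueError("bit_depth must be 8 or 16")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with values 0/255."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(m, mode="L").save(Path(path))
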