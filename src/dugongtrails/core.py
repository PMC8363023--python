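"""Shared container types.

Coordinate conventions used throughout the package: rasters are indexed
0-based, row-major, origin at the top-left pixel; all shifts/offsets are
reported as ``(row_shift, col_shift)``. Binary trail masks are boolean
arrays in memory and {0, 255} single-band 8-bit rasters on disk.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Ground sampling distance every analysis raster is unified to (cm/pixel).
UNIFIED_RESOLUTION_CM = 0.47


@dataclass
class Orthophoto:
    """An RGB orthophoto with its ground sampling distance.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array.
    resolution_cm_per_px:
        Ground size of one pixel in centimetres (0.47–1.0 for the imagery
        this tool targets).
    date:
        Optional acquisition date string (ISO format recommended).
    transform:
        Optional 6-tuple world-file affine transform
        ``(a, d, b, e, c, f)``: x-scale, y-skew, x-skew, y-scale, and the
        world coordinates of the centre of the top-left pixel. Passed
        through untouched by every processing stage.
    """

    pixels: np.ndarray
    resolution_cm_per_px: float = UNIFIED_RESOLUTION_CM
    date: str | None = None
    transform: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"orthophoto must be (H, W, 3), got {self.pixels.shape}")
        if self.resolution_cm_per_px <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def as_bool_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce a {0,1}/{0,255}/bool raster to a boolean trail mask."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(f"mask values must be in {{0, 1, 255}}, found {vals[:10]}")
    return mask > 0


def mask_to_uint8(mask: np.ndarray) -> np.ndarray:
    """Boolean mask -> {0, 255} uint8 raster for storage/display."""
    return np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
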