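"""Tiled inference over orthophotos.

An orthophoto is cropped into overlapping square blocks, each block is
scored by the segmentation network, the overlapping per-block predictions
are integrated by unweighted averaging and rescaled to 0–255 luminance,
and the integrated probability map is binarised at a luminance threshold
(default 125). With a 50% stride, interior pixels receive exactly four
predictions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform

from .core import Orthophoto, UNIFIED_RESOLUTION_CM


@dataclass
class BlockGrid:
    """Block tiling: 0-based, row-major, top-left origin. The final row and
    column of blocks are anchored to the raster edge, so overlap increases
    near the borders rather than padding with fabricated content."""

    block_px: int = 256
    stride_px: int = 128

    def __post_init__(self):
        if not 1 <= self.stride_px <= self.block_px:
            raise ValueError("stride must satisfy 1 <= stride <= block")

    def starts(self, size: int) -> list[int]:
        if size < self.block_px:
            raise ValueError(f"raster extent {size} smaller than block "
                             f"{self.block_px}")
        s = list(range(0, size - self.block_px + 1, self.stride_px))
        if s[-1] != size - self.block_px:
            s.append(size - self.block_px)
        return s


#: 75%-overlap grid used to enlarge the training set.
TRAIN_GRID = BlockGrid(block_px=256, stride_px=64)
#: 50%-overlap grid used at inference (4 predictions per interior pixel).
INFERENCE_GRID = BlockGrid(block_px=256, stride_px=128)


@dataclass
class InferenceConfig:
    luminance_threshold: int = 125

    def __post_init__(self):
        if not 0 <= self.luminance_threshold <= 255:
            raise ValueError("threshold must be in [0, 255]")


def crop_blocks(raster: np.ndarray, grid: BlockGrid
                ) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Deterministic row-major crop of (block, (row0, col0)) views."""
    raster = np.asarray(raster)
    h, w = raster.shape[:2]
    b = grid.block_px
    return [(raster[r:r + b, c:c + b], (r, c))
            for r in grid.starts(h) for c in grid.starts(w)]


def integrate_predictions(blocks_with_positions, raster_size: tuple[int, int]
                          ) -> np.ndarray:
    """Average overlapping block predictions into a 0–255 probability map.

    Per-pixel value = mean of the covering predictions x 255, rounded to
    the nearest integer. Raises if any pixel is uncovered.
    """
    h, w = raster_size
    acc = np.zeros((h, w), dtype=np.float64)
    cov = np.zeros((h, w), dtype=np.int32)
    for block, (r, c) in blocks_with_positions:
        block = np.asarray(block, dtype=np.float64)
        bh, bw = block.shape
        acc[r:r + bh, c:c + bw] += block
        cov[r:r + bh, c:c + bw] += 1
    if (cov == 0).any():
        n = int((cov == 0).sum())
        raise ValueError(f"{n} pixels not covered by any block")
    return np.rint(acc / cov * 255.0).astype(np.uint8)


def binarize_map(prob_map: np.ndarray, config: InferenceConfig | None = None
                 ) -> np.ndarray:
    """Pixel is trail iff its 0–255 luminance value >= the threshold."""
    if config is None:
        config = InferenceConfig()
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 255:
        raise ValueError("probability map values must lie in [0, 255]")
    return prob_map >= config.luminance_threshold


def coverage_counts(grid: BlockGrid, raster_size: tuple[int, int]) -> np.ndarray:
    """How many blocks cover each pixel (diagnostic for the grid)."""
    h, w = raster_size
    cov = np.zeros((h, w), dtype=np.int32)
    b = grid.block_px
    for r in grid.starts(h):
        for c in grid.starts(w):
            cov[r:r + b, c:c + b] += 1
    return cov


def unify_resolution(photo: Orthophoto,
                     target_cm_per_px: float = UNIFIED_RESOLUTION_CM) -> Orthophoto:
    """Bilinear resample of the image to the common analysis resolution."""
    if abs(photo.resolution_cm_per_px - target_cm_per_px) < 1e-9:
        return photo
    h, w = photo.shape
    scale = photo.resolution_cm_per_px / target_cm_per_px
    out_shape = (max(int(round(h * scale)), 1), max(int(round(w * scale)), 1))
    resized = transform.resize(photo.pixels, out_shape, order=1,
                               preserve_range=True, anti_aliasing=scale < 1)
    return Orthophoto(np.clip(resized, 0, 255).astype(np.uint8),
                      target_cm_per_px, date=photo.date, transform=photo.transform)


def resample_mask(mask: np.ndarray, from_cm_per_px: float,
                  target_cm_per_px: float = UNIFIED_RESOLUTION_CM) -> np.ndarray:
    """Nearest-neighbour resample of a boolean mask."""
    if abs(from_cm_per_px - target_cm_per_px) < 1e-9:
        return mask
    scale = from_cm_per_px / target_cm_per_px
    out_shape = (max(int(round(mask.shape[0] * scale)), 1),
                 max(int(round(mask.shape[1] * scale)), 1))
    return transform.resize(mask.astype(float), out_shape, order=0,
                            preserve_range=True, anti_aliasing=False) > 0.5


def extract_trails(photo: Orthophoto, model, grid: BlockGrid | None = None,
                   config: InferenceConfig | None = None,
                   batch_size: int = 16) -> np.ndarray:
    """Full extraction: unify resolution, tile, score, integrate, binarise."""
    photo = unify_resolution(photo)
    if grid is None:
        grid = BlockGrid(block_px=model.config.input_size_px,
                         stride_px=model.config.input_size_px // 2)
    img = photo.pixels.astype(np.float32) / 255.0
    blocks = crop_blocks(img, grid)
    tiles = np.stack([b for b, _ in blocks])
    probs = model.predict(tiles, batch_size=batch_size)
    scored = [(probs[i], pos) for i, (_, pos) in enumerate(blocks)]
    prob_map = integrate_predictions(scored, photo.shape)
    return binarize_map(prob_map, config)


def probability_map(photo: Orthophoto, model, grid: BlockGrid | None = None,
                    batch_size: int = 16) -> np.ndarray:
    """The integrated 0–255 map without binarisation (for PR sweeps)."""
    photo = unify_resolution(photo)
    if grid is None:
        grid = BlockGrid(block_px=model.config.input_size_px,
                         stride_px=model.config.input_size_px // 2)
    img = photo.pixels.astype(np.float32) / 255.0
    blocks = crop_blocks(img, grid)
    tiles = np.stack([b for b, _ in blocks])
    probs = model.predict(tiles, batch_size=batch_size)
    scored = [(probs[i], pos) for i, (_, pos) in enumerate(blocks)]
    return integrate_predictions(scored, photo.shape)
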