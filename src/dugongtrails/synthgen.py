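"""Seeded synthetic intertidal-seagrass scenes with dugong feeding trails.

Emulates the visual structure the segmentation pipeline has to cope with:
a seagrass/sediment background built from a low-frequency noise field
blended with speckle patches, winding unvegetated trails 10–25 cm wide
whose colour fades linearly toward the sediment background as they age,
and bright water-pool highlights whose intensity is independent of the
trail geometry. Day pairs add a known rigid integer-pixel offset and a
known set of newly created trails, so registration, change detection and
the new-trail model can all be validated against exact ground truth.

All randomness flows from one explicit integer seed per call; the same
configuration and seed reproduce every raster bit for bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw, transform

from .core import Orthophoto, UNIFIED_RESOLUTION_CM

# days after which a trail has visually merged with the sediment
TRAIL_VISIBLE_DAYS = 8.5

_SEAGRASS_RGB = np.array([62.0, 92.0, 74.0])
_SEDIMENT_RGB = np.array([168.0, 156.0, 128.0])
_FRESH_TRAIL_RGB = np.array([196.0, 184.0, 152.0])


@dataclass
class SceneConfig:
    image_size_px: tuple[int, int] = (512, 512)
    resolution_cm_per_px: float = UNIFIED_RESOLUTION_CM
    n_trails: int = 4
    trail_width_cm_range: tuple[float, float] = (10.0, 25.0)
    trail_age_days_range: tuple[float, float] = (0.0, 6.0)
    highlight_density: float = 0.15
    background_seagrass_cover: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.resolution_cm_per_px <= 0:
            raise ValueError("resolution must be positive")
        if self.trail_width_cm_range[0] <= 0 or \
                self.trail_width_cm_range[1] < self.trail_width_cm_range[0]:
            raise ValueError("trail width range must be positive and ordered")
        if not 0 <= self.highlight_density <= 1:
            raise ValueError("highlight_density must be in [0, 1]")
        if self.n_trails < 0:
            raise ValueError("n_trails must be non-negative")


@dataclass
class DayPairSpec:
    base_scene: SceneConfig = field(default_factory=SceneConfig)
    rigid_offset_px: tuple[int, int] = (0, 0)
    n_new_trails: int = 2
    fade_old_trails: bool = True


def generate_centerline(seed: int, n_steps: int, step_px: float,
                        turn_sd_deg: float, start: tuple[float, float],
                        heading_deg: float) -> np.ndarray:
    """Random winding polyline: a heading random walk.

    Successive heading changes are drawn from a zero-mean normal with
    standard deviation ``turn_sd_deg``. Returns ``(n_steps+1, 2)`` float
    ``(row, col)`` coordinates. Heading 0 points along +col; positive
    angles turn counter-clockwise in map orientation (row axis points down).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if step_px <= 0:
        raise ValueError("step_px must be positive")
    rng = np.random.default_rng(seed)
    turns = rng.normal(0.0, turn_sd_deg, size=n_steps)
    headings = np.deg2rad(heading_deg + np.concatenate([[0.0], np.cumsum(turns)[:-1]]))
    steps = np.stack([-np.sin(headings), np.cos(headings)], axis=1) * step_px
    pts = np.concatenate([[np.asarray(start, float)],
                          np.asarray(start, float) + np.cumsum(steps, axis=0)])
    return pts


def _rasterize_polyline(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    canvas = np.zeros(shape, dtype=bool)
    pts = np.rint(points).astype(int)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw.line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        canvas[rr[keep], cc[keep]] = True
    return canvas


def _trail_footprint(points: np.ndarray, width_px: int,
                     shape: tuple[int, int]) -> np.ndarray:
    center = _rasterize_polyline(points, shape)
    if not center.any():
        return center
    dist = ndimage.distance_transform_edt(~center)
    return dist <= width_px / 2.0


def _background(shape: tuple[int, int], cover: float,
                rng: np.random.Generator) -> np.ndarray:
    """Low-frequency noise field blended between sediment and seagrass colours,
    plus darker speckle patches standing in for dense seagrass clumps."""
    h, w = shape
    coarse = rng.standard_normal((max(h // 32, 2), max(w // 32, 2)))
    low = transform.resize(coarse, shape, order=1, mode="reflect",
                           anti_aliasing=False)
    low = (low - low.min()) / max(float(np.ptp(low)), 1e-9)
    mix = np.clip(cover + 0.35 * (low - 0.5), 0.0, 1.0)[..., None]
    img = (1 - mix) * _SEDIMENT_RGB + mix * _SEAGRASS_RGB
    speckle_field = rng.standard_normal((max(h // 6, 2), max(w // 6, 2)))
    speckle = transform.resize(speckle_field, shape, order=1, mode="reflect",
                               anti_aliasing=False)
    patches = speckle > 1.0
    img[patches] = img[patches] * 0.82
    img += rng.normal(0.0, 3.0, size=img.shape)
    return img


def _paint_trail(img: np.ndarray, footprint: np.ndarray, age_days: float,
                 rng: np.random.Generator) -> None:
    """Trail colour fades linearly toward the local background with age."""
    fade = float(np.clip(age_days / TRAIL_VISIBLE_DAYS, 0.0, 0.92))
    jitter = rng.normal(0.0, 6.0, size=3)
    trail_rgb = _FRESH_TRAIL_RGB + jitter
    img[footprint] = (1 - fade) * trail_rgb + fade * img[footprint]


def _paint_highlights(img: np.ndarray, shape: tuple[int, int], density: float,
                      rng: np.random.Generator) -> None:
    """Sunlight highlights on water pools. All candidate draws are consumed
    regardless of density, so two configs differing only in density produce
    photos that differ only inside the accepted highlight regions."""
    h, w = shape
    n_candidates = max(4, (h * w) // 12000)
    for _ in range(n_candidates):
        r = float(rng.uniform(0, h))
        c = float(rng.uniform(0, w))
        ry = float(rng.uniform(2.0, 7.0))
        rx = float(rng.uniform(2.0, 7.0))
        gain = float(rng.uniform(60.0, 110.0))
        accept = float(rng.uniform()) < density
        if not accept:
            continue
        rr, cc = draw.ellipse(r, c, ry, rx, shape=(h, w))
        img[rr, cc] += gain


def _scene_arrays(config: SceneConfig, rng_streams=None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(photo float RGB, trail mask, background-only photo)."""
    h, w = config.image_size_px
    if rng_streams is None:
        ss = np.random.SeedSequence(config.seed)
        rng_streams = [np.random.default_rng(s) for s in ss.spawn(3)]
    bg_rng, trail_rng, hl_rng = rng_streams
    bg = _background((h, w), config.background_seagrass_cover, bg_rng)
    img = bg.copy()
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(config.n_trails):
        footprint, _, age = _sample_trail(config, (h, w), trail_rng)
        _paint_trail(img, footprint, age, trail_rng)
        mask |= footprint
    _paint_highlights(img, (h, w), config.highlight_density, hl_rng)
    return img, mask, bg


def _sample_trail(config: SceneConfig, shape: tuple[int, int],
                  rng: np.random.Generator,
                  forbidden: np.ndarray | None = None, max_tries: int = 200,
                  ) -> tuple[np.ndarray, int, float]:
    """Draw one trail footprint; optionally resample until it is disjoint
    from (and not touching) ``forbidden`` and forms a single component."""
    h, w = shape
    res = config.resolution_cm_per_px
    for _ in range(max_tries):
        width_cm = float(rng.uniform(*config.trail_width_cm_range))
        width_px = max(int(round(width_cm / res)), 1)
        age = float(rng.uniform(*config.trail_age_days_range))
        length_px = float(rng.uniform(0.35, 0.9)) * min(h, w)
        step = 3.0
        n_steps = max(int(length_px / step), 2)
        start = (float(rng.uniform(0.1 * h, 0.9 * h)),
                 float(rng.uniform(0.1 * w, 0.9 * w)))
        heading = float(rng.uniform(0.0, 360.0))
        seed = int(rng.integers(2 ** 31))
        pts = generate_centerline(seed, n_steps, step, turn_sd_deg=9.0,
                                  start=start, heading_deg=heading)
        footprint = _trail_footprint(pts, width_px, shape)
        if not footprint.any():
            continue
        if forbidden is not None:
            grown = ndimage.binary_dilation(footprint)
            if (grown & forbidden).any():
                continue
            n_comp = ndimage.label(footprint)[1]
            if n_comp != 1:
                continue
        return footprint, width_px, age
    raise RuntimeError("could not place a disjoint trail; scene too crowded")


def render_scene(config: SceneConfig) -> tuple[Orthophoto, np.ndarray]:
    """Render one scene: RGB orthophoto plus its aligned boolean trail mask."""
    img, mask, _ = _scene_arrays(config)
    photo = Orthophoto(np.clip(img, 0, 255).astype(np.uint8),
                       config.resolution_cm_per_px)
    return photo, mask


def make_day_pair(spec: DayPairSpec) -> tuple[Orthophoto, Orthophoto,
                                              np.ndarray, np.ndarray,
                                              np.ndarray, tuple[int, int]]:
    """Two consecutive-day scenes with a known rigid offset and new trails.

    Day 1 is the day-0 scene rigidly shifted by ``rigid_offset_px`` (so
    ``day1[y, x] = day0[y - dy, x - dx]``) with ``n_new_trails`` fresh
    trails added, each disjoint from (and not touching) the shifted day-0
    trails. Returns ``(photo0, photo1, mask0, mask1, new_trail_mask,
    true_offset)``.
    """
    cfg = spec.base_scene
    h, w = cfg.image_size_px
    dy, dx = spec.rigid_offset_px
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError(f"offset {spec.rigid_offset_px} exceeds image size {(h, w)}")
    m = int(max(abs(dy), abs(dx)))
    big_cfg = replace(cfg, image_size_px=(h + 2 * m, w + 2 * m))
    img_big, mask_big, bg_big = _scene_arrays(big_cfg)

    def crop(a, r0, c0):
        return a[r0:r0 + h, c0:c0 + w]

    img0 = crop(img_big, m, m).copy()
    mask0 = crop(mask_big, m, m).copy()
    img1 = crop(img_big, m - dy, m - dx).copy()
    mask1_old = crop(mask_big, m - dy, m - dx).copy()
    bg1 = crop(bg_big, m - dy, m - dx)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 9173)))
    if spec.fade_old_trails:
        extra = 1.0 / TRAIL_VISIBLE_DAYS
        img1[mask1_old] = ((1 - extra) * img1[mask1_old]
                           + extra * bg1[mask1_old])

    new_mask = np.zeros((h, w), dtype=bool)
    for _ in range(spec.n_new_trails):
        forbidden = mask1_old | new_mask
        footprint, _, _ = _sample_trail(
            replace(cfg, trail_age_days_range=(0.0, 0.0)), (h, w), rng,
            forbidden=forbidden)
        _paint_trail(img1, footprint, 0.0, rng)
        new_mask |= footprint

    photo0 = Orthophoto(np.clip(img0, 0, 255).astype(np.uint8),
                        cfg.resolution_cm_per_px, date="day0")
    photo1 = Orthophoto(np.clip(img1, 0, 255).astype(np.uint8),
                        cfg.resolution_cm_per_px, date="day1")
    return photo0, photo1, mask0, mask1_old | new_mask, new_mask, (dy, dx)


def crop_tiles(photo: Orthophoto, mask: np.ndarray, tile_px: int,
               stride_px: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """(image, mask) training tiles; images scaled to float [0, 1]."""
    img = photo.pixels.astype(np.float32) / 255.0
    h, w = mask.shape
    tiles = []
    for r in range(0, h - tile_px + 1, stride_px):
        for c in range(0, w - tile_px + 1, stride_px):
            tiles.append((img[r:r + tile_px, c:c + tile_px].copy(),
                          mask[r:r + tile_px, c:c + tile_px].copy()))
    return tiles


def write_manifest(path: str | Path, records: list[dict]) -> None:
    """CSV manifest of generated pairs: seeds, offsets, new-trail counts."""
    pd.DataFrame(records).to_csv(path, index=False)
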