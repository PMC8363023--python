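"""Seeded synthetic benchmark experiments at compact (CPU-scale) conditions.

These routines define the study conditions used to validate the pipeline
without field imagery: scenes are rendered at 1.8 cm/pixel so that
10–25 cm trails span 6–14 pixels inside 64-pixel tiles, and the network is
a depth-3, base-8 configuration of the same architecture used at full
scale. Every routine is driven by one integer seed.
"""
from __future__ import annotations

import numpy as np

from .changedet import build_differential
from .evalmetrics import BufferSpec
from .segnet import (AugmentConfig, NetworkConfig, TrailSegmenter, TrainConfig,
                     build_model, split_dataset, train_model)
from .synthgen import (DayPairSpec, SceneConfig, crop_tiles, make_day_pair,
                       render_scene)

TILE = 64
SCENE_RES_CM = 1.8
COMPACT_NET = dict(input_size_px=TILE, depth_levels=3, base_channels=8)

_MOD = 2 ** 31


def training_tiles(seed: int = 0, n_scenes: int = 10
                   ) -> list[tuple[np.ndarray, np.ndarray]]:
    """RGB/mask tiles cropped from seeded synthetic scenes (25 per scene)."""
    tiles = []
    for i in range(n_scenes):
        cfg = SceneConfig(image_size_px=(320, 320),
                          resolution_cm_per_px=SCENE_RES_CM, n_trails=5,
                          seed=(seed * 1009 + 100 + i) % _MOD)
        photo, mask = render_scene(cfg)
        tiles += crop_tiles(photo, mask, TILE, TILE)
    return tiles


def differential_tiles(seed: int = 0, n_pairs: int = 14
                       ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Model_2 tiles: differential one-hot input -> planted-new-trail target.

    A ±1 px registration jitter is injected so the network must learn to
    ignore the thin slivers imperfect registration leaves along old trails.
    """
    rng = np.random.default_rng(seed)
    tiles = []
    for s in range(n_pairs):
        scene = SceneConfig(image_size_px=(256, 256),
                            resolution_cm_per_px=SCENE_RES_CM, n_trails=3,
                            seed=(seed * 1013 + 400 + s) % _MOD)
        spec = DayPairSpec(scene, rigid_offset_px=(0, 0), n_new_trails=2)
        _, _, m0, m1, new, _ = make_day_pair(spec)
        dy, dx = rng.integers(-1, 2, 2)
        prev = np.roll(m0, (dy, dx), axis=(0, 1))
        onehot = build_differential(m1, prev).to_onehot()
        for r in range(0, 256 - TILE + 1, TILE):
            for c in range(0, 256 - TILE + 1, TILE):
                tiles.append((onehot[r:r + TILE, c:c + TILE],
                              new[r:r + TILE, c:c + TILE]))
    return tiles


def train_synthetic_model1(seed: int = 0
                           ) -> tuple[TrailSegmenter, "object", list]:
    """Train the trail-extraction network; returns (model, log, test tiles)."""
    tiles = training_tiles(seed)
    net = NetworkConfig(seed=seed % _MOD, **COMPACT_NET)
    tc = TrainConfig(batch_size=8, max_epochs=12, early_stop_patience=4,
                     seed=seed % _MOD, split_fractions=(0.6, 0.2, 0.2))
    train_set, val_set, test_set = split_dataset(tiles, tc.split_fractions,
                                                 tc.seed)
    model, log = train_model(build_model(net), (train_set, val_set), tc,
                             AugmentConfig(), BufferSpec(7))
    return model, log, test_set


def train_synthetic_model2(seed: int = 1) -> tuple[TrailSegmenter, "object"]:
    """Train the new-trail network on differential tiles."""
    tiles = differential_tiles(seed)
    net = NetworkConfig(seed=seed % _MOD, **COMPACT_NET)
    tc = TrainConfig(batch_size=8, max_epochs=10, early_stop_patience=4,
                     seed=seed % _MOD, split_fractions=(0.7, 0.3, 0.0))
    aug = AugmentConfig(gamma_range=(1.0, 1.0), contrast_range=(1.0, 1.0))
    model, log = train_model(build_model(net), tiles, tc, aug, BufferSpec(7))
    return model, log


def stripe_block(l: int, width: float, angle_deg: float) -> np.ndarray:
    """A straight trail of given width through the block centre."""
    r, x = np.meshgrid(np.arange(l), np.arange(l), indexing="ij")
    theta = np.deg2rad(angle_deg)
    dx = x - (l - 1) / 2
    dr = r - (l - 1) / 2
    dist = np.abs(dx * np.sin(theta) + dr * np.cos(theta))
    return dist <= width / 2
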