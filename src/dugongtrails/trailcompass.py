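"""Line-likelihood estimation of feeding-trail direction.

Each 256x256 block of a trail mask is scored against eight candidate
directions (0°, 22.5°, ..., 157.5°, measured from the +x image axis with
y pointing up, modulo 180°). For a direction, the block is covered by a
family of parallel digital lines; along each line the binary profile of
trail hits is cleaned by deleting every consecutive run shorter than 25%
of that line's length (suppressing noise and trails in other directions),
and the direction's likelihood is the total number of surviving hits. The
direction with the highest likelihood wins (ties: smallest angle). Blocks
whose trail coverage is below 8% of their area are excluded.

For 0°/90° the line families are the rows/columns; for 45°/135° they are
the anti-diagonals/diagonals. For the remaining angles the family is a
digital-line partition: each pixel belongs to exactly one line of offset
``k``, the line being the rounded rasterisation of ``r = r0 - x·tanθ``
(shallow angles) or ``x = x0 - r·cotθ`` (steep angles). Every family
therefore covers each block pixel exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import ceil, cos, radians, sin, tan

import numpy as np
import pandas as pd

from .core import as_bool_mask

DIRECTIONS_DEG: tuple[float, ...] = (0.0, 22.5, 45.0, 67.5, 90.0, 112.5,
                                     135.0, 157.5)

#: Label for blocks with insufficient trail coverage.
EXCLUDED = "EXCLUDED"


@dataclass
class DirectionConfig:
    block_side_l: int = 256
    directions_deg: tuple[float, ...] = DIRECTIONS_DEG
    min_area_fraction: float = 0.08
    min_run_fraction: float = 0.25

    def __post_init__(self):
        if not 0 < self.min_area_fraction < 1:
            raise ValueError("min_area_fraction must be in (0, 1)")


@dataclass
class LineFamily:
    """Parallel digital lines covering an l x l block at one direction."""

    direction_deg: float
    l: int
    lines: list[tuple[np.ndarray, np.ndarray]]  # (rows, cols), ordered along line

    @property
    def line_lengths(self) -> list[int]:
        return [len(r) for r, _ in self.lines]

    def total_cells(self) -> int:
        return sum(self.line_lengths)


@lru_cache(maxsize=64)
def _family_cells(l: int, direction_deg: float
                  ) -> tuple[tuple[np.ndarray, np.ndarray], ...]:
    theta = radians(direction_deg)
    shallow = abs(tan(theta)) <= 1.0 + 1e-9
    rs, xs = np.meshgrid(np.arange(l), np.arange(l), indexing="ij")
    if shallow:
        t = tan(theta)
        key = rs + np.rint(xs * t).astype(int)   # r + round(x·tanθ) = r0
        param = xs
    else:
        ct = cos(theta) / sin(theta)
        key = xs + np.rint(rs * ct).astype(int)  # x + round(r·cotθ) = x0
        param = rs
    flat_key = key.ravel()
    order = np.lexsort((param.ravel(), flat_key))
    sk = flat_key[order]
    srows = rs.ravel()[order]
    scols = xs.ravel()[order]
    cuts = np.flatnonzero(np.diff(sk)) + 1
    rows_split = np.split(srows, cuts)
    cols_split = np.split(scols, cuts)
    return tuple((r.copy(), c.copy()) for r, c in zip(rows_split, cols_split))


def build_line_family(l: int, direction_deg: float) -> LineFamily:
    """The family of parallel lines for one of the eight directions."""
    if l < 2:
        raise ValueError("block side must be >= 2")
    if not any(abs(direction_deg - d) < 1e-9 for d in DIRECTIONS_DEG):
        raise ValueError(f"direction {direction_deg} not in {DIRECTIONS_DEG}")
    cells = _family_cells(l, float(direction_deg))
    return LineFamily(float(direction_deg), l, list(cells))


def filter_profile(v: np.ndarray, line_length: int | None = None,
                   min_run_fraction: float = 0.25) -> np.ndarray:
    """Zero every maximal run of 1s shorter than ceil(fraction x length)."""
    v = np.asarray(v).astype(bool)
    L = len(v) if line_length is None else line_length
    thr = ceil(min_run_fraction * L)
    c = np.zeros_like(v)
    d = np.diff(np.concatenate(([0], v.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s >= thr:
            c[s:e] = True
    return c


def _surviving_hits(v: np.ndarray, thr: int) -> int:
    d = np.diff(np.concatenate(([0], v.astype(np.int8), [0])))
    lens = np.flatnonzero(d == -1) - np.flatnonzero(d == 1)
    return int(lens[lens >= thr].sum())


def direction_likelihood(block_mask: np.ndarray, family: LineFamily,
                         min_run_fraction: float = 0.25) -> int:
    """Sum over the family's lines of the run-filtered hit counts."""
    O = as_bool_mask(block_mask)
    if O.shape != (family.l, family.l):
        raise ValueError(f"block {O.shape} does not match family side {family.l}")
    total = 0
    for rows, cols in family.lines:
        v = O[rows, cols]
        if v.any():
            total += _surviving_hits(v, ceil(min_run_fraction * len(rows)))
    return total


def direction_likelihoods(block_mask: np.ndarray,
                          config: DirectionConfig | None = None) -> np.ndarray:
    """Likelihood per configured direction (same order as the config)."""
    if config is None:
        config = DirectionConfig(block_side_l=np.asarray(block_mask).shape[0])
    O = as_bool_mask(block_mask)
    out = np.empty(len(config.directions_deg))
    for i, d in enumerate(config.directions_deg):
        fam = build_line_family(O.shape[0], d)
        out[i] = direction_likelihood(O, fam, config.min_run_fraction)
    return out


def block_direction(block_mask: np.ndarray,
                    config: DirectionConfig | None = None):
    """Winning direction (degrees) of one block, or ``EXCLUDED``.

    Blocks with trail coverage below ``min_area_fraction`` are excluded;
    otherwise the direction with the highest likelihood wins, with ties
    broken toward the smallest angle.
    """
    O = as_bool_mask(block_mask)
    if config is None:
        config = DirectionConfig(block_side_l=O.shape[0])
    if O.mean() < config.min_area_fraction:
        return EXCLUDED
    lik = direction_likelihoods(O, config)
    return float(config.directions_deg[int(np.argmax(lik))])


@dataclass
class DirectionField:
    """Per-block direction labels plus the aggregate circular histogram."""

    blocks: pd.DataFrame      # block_row, block_col, label, excluded, lik_*
    histogram: pd.DataFrame   # direction_deg, count, fraction
    block_side: int

    def overlay(self, shape: tuple[int, int]) -> np.ndarray:
        """Colour-coded block raster (one colour per direction bin)."""
        import matplotlib

        cmap = matplotlib.colormaps["hsv"]
        img = np.full((*shape, 3), 255, dtype=np.uint8)
        for _, row in self.blocks.iterrows():
            if row["excluded"]:
                continue
            color = (np.array(cmap(row["label"] / 180.0)[:3]) * 255).astype(np.uint8)
            r0 = int(row["block_row"]) * self.block_side
            c0 = int(row["block_col"]) * self.block_side
            img[r0:r0 + self.block_side, c0:c0 + self.block_side] = color
        return img


def direction_field(mask: np.ndarray,
                    config: DirectionConfig | None = None) -> DirectionField:
    """Tile a mask into non-overlapping blocks and estimate each direction.

    Partial blocks at the right/bottom edge (smaller than the block side)
    are not scored. Histogram fractions are over included blocks only.
    """
    mask = as_bool_mask(mask)
    if config is None:
        config = DirectionConfig()
    l = config.block_side_l
    h, w = mask.shape
    if h < l or w < l:
        raise ValueError(f"mask {mask.shape} smaller than block side {l}")
    rows = []
    for br in range(h // l):
        for bc in range(w // l):
            block = mask[br * l:(br + 1) * l, bc * l:(bc + 1) * l]
            if block.mean() < config.min_area_fraction:
                rows.append({"block_row": br, "block_col": bc,
                             "label": np.nan, "excluded": True,
                             **{f"lik_{d:g}": np.nan
                                for d in config.directions_deg}})
                continue
            lik = direction_likelihoods(block, config)
            label = float(config.directions_deg[int(np.argmax(lik))])
            rows.append({"block_row": br, "block_col": bc,
                         "label": label, "excluded": False,
                         **{f"lik_{d:g}": lik[i]
                            for i, d in enumerate(config.directions_deg)}})
    blocks = pd.DataFrame(rows)
    included = blocks[~blocks["excluded"]]
    counts = [int((included["label"] == d).sum()) for d in config.directions_deg]
    n_inc = max(len(included), 1)
    histogram = pd.DataFrame({
        "direction_deg": config.directions_deg,
        "count": counts,
        "fraction": [c / n_inc if len(included) else 0.0 for c in counts],
    })
    return DirectionField(blocks, histogram, l)
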