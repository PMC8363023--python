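"""Daily new-trail change detection.

Consecutive-day trail masks are first registered by two-stage block
template matching (coarse 3200-px blocks, then fine 256-px blocks; each
stage searches integer shifts up to 20% of its block length for the
highest normalised cross-correlation). The registered masks are combined
into a ternary differential image (current-only / previous-only / both),
the differential is scored by the new-trail network (Model_2), the
integrated prediction is binarised, and a morphological opening removes
speckle noise. Areas are accounted in m² from the pixel resolution.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .core import as_bool_mask
from .evalmetrics import dilate_binary, erode_binary
from .mosaic import BlockGrid, InferenceConfig, binarize_map, crop_blocks, \
    integrate_predictions


@dataclass
class RegistrationConfig:
    """Two-stage block registration parameters.

    ``min_score_factor`` generalises the no-signal rule. For a template of
    N pixels the NCC of unrelated content fluctuates at the 1/sqrt(N)
    scale, so a peak below ``min_score_factor / sqrt(N)`` is consistent
    with noise: the block gives no evidence to move and the identity shift
    is retained.
    """

    coarse_block_px: int = 3200
    fine_block_px: int = 256
    max_offset_fraction: float = 0.2
    min_score_factor: float = 8.0

    def __post_init__(self):
        if not 0 < self.max_offset_fraction < 1:
            raise ValueError("max_offset_fraction must be in (0, 1)")
        if self.fine_block_px > self.coarse_block_px:
            raise ValueError("fine block must not exceed coarse block")
        if self.fine_block_px < 8:
            raise ValueError("fine block unreasonably small")

    def max_correctable_offset_m(self, resolution_cm_per_px: float) -> float:
        """Largest correctable shift of the coarse stage, in metres."""
        return self.max_offset_fraction * self.coarse_block_px \
            * resolution_cm_per_px / 100.0


@dataclass
class MatchResult:
    dy: int
    dx: int
    score: float                       # NCC at the chosen shift
    peak_z: float = float("inf")       # NCC peak x sqrt(template pixels):
                                       # its height over the noise floor
    no_signal: bool = False
    at_window_edge: bool = False


@dataclass
class OpeningConfig:
    """Square structuring element for erosion-then-dilation noise removal."""

    element_side: int = 3

    def __post_init__(self):
        if self.element_side < 1:
            raise ValueError("element side must be >= 1")


def ncc_score(template_block: np.ndarray, candidate_block: np.ndarray) -> float:
    """Zero-mean normalised cross-correlation in [-1, 1].

    Returns ``nan`` (the no-signal sentinel) when either block has zero
    variance, where the score is undefined.
    """
    a = np.asarray(template_block, dtype=np.float64)
    b = np.asarray(candidate_block, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"blocks differ in shape: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def match_block_offset(previous_block: np.ndarray, current_block: np.ndarray,
                       max_offset_px: int) -> MatchResult:
    """Best integer shift of ``previous`` onto ``current`` within a window.

    The centre of the current block (inset by the window radius) is used as
    the template and slid exhaustively over the previous block, so every
    candidate placement compares real content only. The returned
    ``(dy, dx)`` satisfies ``current[y, x] ≈ previous[y - dy, x - dx]``.
    Ties are broken by smallest shift magnitude, then row-major order.
    """
    prev = np.asarray(previous_block, dtype=np.float32)
    cur = np.asarray(current_block, dtype=np.float32)
    if prev.shape != cur.shape:
        raise ValueError(f"blocks differ in shape: {prev.shape} vs {cur.shape}")
    m = int(max_offset_px)
    if m < 0:
        raise ValueError("max_offset must be non-negative")
    if m == 0:
        s = ncc_score(cur, prev)
        return MatchResult(0, 0, s, no_signal=np.isnan(s))
    h, w = cur.shape
    if h <= 2 * m + 1 or w <= 2 * m + 1:
        raise ValueError(f"block {cur.shape} too small for offset window {m}")
    template = cur[m:h - m, m:w - m]
    if template.std() == 0 or prev.std() == 0:
        return MatchResult(0, 0, float("nan"), no_signal=True)
    corr = match_template(prev, template)  # (2m+1, 2m+1), exhaustive placements
    corr = np.where(np.isfinite(corr), corr, -np.inf)
    best = corr.max()
    if not np.isfinite(best):
        return MatchResult(0, 0, float("nan"), no_signal=True)
    # peak height relative to the 1/sqrt(N) noise floor of an N-pixel NCC
    peak_z = float(best * np.sqrt(template.size))
    ties = np.argwhere(corr >= best - 1e-6)
    shifts = m - ties  # peak at (m-dy, m-dx)
    order = np.lexsort((shifts[:, 1], shifts[:, 0],
                        (shifts ** 2).sum(axis=1)))
    dy, dx = (int(v) for v in shifts[order[0]])
    at_edge = abs(dy) == m or abs(dx) == m
    return MatchResult(dy, dx, float(best), peak_z=peak_z,
                       at_window_edge=at_edge)


def _chunk_edges(size: int, block: int) -> list[tuple[int, int]]:
    edges = list(range(0, size, block))
    return [(e, min(e + block, size)) for e in edges]


def _translated_window(src: np.ndarray, r0: int, r1: int, c0: int, c1: int,
                       dy: int, dx: int) -> np.ndarray:
    """src content for window [r0:r1, c0:c1] shifted by (dy, dx), zero-filled."""
    out = np.zeros((r1 - r0, c1 - c0), dtype=src.dtype)
    rs, re = r0 - dy, r1 - dy
    cs, ce = c0 - dx, c1 - dx
    rs_c, re_c = max(rs, 0), min(re, src.shape[0])
    cs_c, ce_c = max(cs, 0), min(ce, src.shape[1])
    if rs_c < re_c and cs_c < ce_c:
        out[rs_c - rs:re_c - rs, cs_c - cs:ce_c - cs] = src[rs_c:re_c, cs_c:ce_c]
    return out


def _register_stage(previous: np.ndarray, current: np.ndarray,
                    valid: np.ndarray, block: int, frac: float,
                    min_score_factor: float, stage: str, diagnostics: list
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One matching stage; ``valid`` marks pixels carrying observed previous
    data (shifting moves content out of view, leaving no-data bands). Blocks
    touching no-data are not matched — their content offers no alignment
    evidence — and keep the identity shift."""
    h, w = current.shape
    m = int(round(frac * block))
    corrected = np.zeros_like(previous)
    new_valid = np.zeros_like(valid)
    for r0, r1 in _chunk_edges(h, block):
        for c0, c1 in _chunk_edges(w, block):
            ch, cw = r1 - r0, c1 - c0
            no_data = not valid[r0:r1, c0:c1].all()
            if no_data or ch <= 2 * m + 1 or cw <= 2 * m + 1:
                res = MatchResult(0, 0, float("nan"), no_signal=True)
            else:
                res = match_block_offset(previous[r0:r1, c0:c1].astype(np.float32),
                                         current[r0:r1, c0:c1].astype(np.float32),
                                         m)
            weak = res.no_signal or res.peak_z < min_score_factor
            dy, dx = (0, 0) if weak else (res.dy, res.dx)
            corrected[r0:r1, c0:c1] = _translated_window(previous, r0, r1, c0, c1,
                                                         dy, dx)
            new_valid[r0:r1, c0:c1] = _translated_window(valid, r0, r1, c0, c1,
                                                         dy, dx)
            diagnostics.append({"stage": stage, "row0": r0, "col0": c0,
                                "dy": dy, "dx": dx, "ncc": res.score,
                                "peak_z": res.peak_z,
                                "no_signal": res.no_signal, "no_data": no_data,
                                "at_window_edge": res.at_window_edge})
    return corrected, new_valid


def register_with_validity(previous_mask: np.ndarray, current_mask: np.ndarray,
                           config: RegistrationConfig | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Two-stage registration returning the observed-data validity raster.

    ``valid`` is True where the corrected raster carries real previous-day
    content; shifting leaves no-data bands (False) at the trailing edges,
    and downstream change detection must not claim new trails there.
    """
    if config is None:
        config = RegistrationConfig()
    previous = as_bool_mask(previous_mask).astype(np.float32)
    current = as_bool_mask(current_mask).astype(np.float32)
    if previous.shape != current.shape:
        raise ValueError("masks must share a raster size")
    if min(current.shape) < config.fine_block_px:
        raise ValueError(f"raster {current.shape} smaller than fine block "
                         f"{config.fine_block_px}")
    diagnostics: list[dict] = []
    valid = np.ones_like(previous)
    out, valid = _register_stage(previous, current, valid,
                                 config.coarse_block_px,
                                 config.max_offset_fraction, config.min_score_factor,
                                 "coarse", diagnostics)
    out, valid = _register_stage(out, current, valid, config.fine_block_px,
                                 config.max_offset_fraction, config.min_score_factor,
                                 "fine", diagnostics)
    return out > 0.5, valid > 0.5, pd.DataFrame(diagnostics)


def two_stage_register(previous_mask: np.ndarray, current_mask: np.ndarray,
                       config: RegistrationConfig | None = None,
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Coarse-then-fine per-block registration of the previous-day mask.

    Each stage caps the search at ``max_offset_fraction`` of its block
    length; per-block shifts are applied independently, pulling content
    from the full raster (zero fill beyond the edges). Blocks with no NCC
    signal (e.g. empty sea or sand) or containing no-data keep shift
    (0, 0). Returns the corrected previous mask and a per-block
    diagnostics table.
    """
    corrected, _, diagnostics = register_with_validity(previous_mask,
                                                       current_mask, config)
    return corrected, diagnostics


@dataclass
class DifferentialImage:
    """Ternary classification of two aligned trail masks.

    The three planes are pairwise disjoint and their union equals the
    union of the inputs; everything else is background.
    """

    current_only: np.ndarray
    previous_only: np.ndarray
    both: np.ndarray

    def to_onehot(self) -> np.ndarray:
        """(H, W, 3) float32 one-hot planes — the Model_2 input encoding."""
        return np.stack([self.current_only, self.previous_only, self.both],
                        axis=-1).astype(np.float32)

    def to_rgb(self) -> np.ndarray:
        """Display rendering: current-only black, previous-only grey,
        both mid-grey stripes tone, background white."""
        h, w = self.current_only.shape
        img = np.full((h, w, 3), 255, dtype=np.uint8)
        img[self.both] = 150
        img[self.previous_only] = 200
        img[self.current_only] = 0
        return img


def build_differential(current_mask: np.ndarray,
                       previous_mask_corrected: np.ndarray) -> DifferentialImage:
    """current-only / previous-only / both planes of two aligned masks."""
    cur = as_bool_mask(current_mask)
    prev = as_bool_mask(previous_mask_corrected)
    if cur.shape != prev.shape:
        raise ValueError(f"masks differ in shape: {cur.shape} vs {prev.shape}")
    return DifferentialImage(current_only=cur & ~prev,
                             previous_only=prev & ~cur,
                             both=cur & prev)


def opening_filter(mask: np.ndarray, config: OpeningConfig | None = None
                   ) -> np.ndarray:
    """Morphological opening (erosion then dilation, square element).

    Removes foreground features smaller than the element; the result is
    always a subset of the input and applying it twice changes nothing.
    """
    if config is None:
        config = OpeningConfig()
    mask = as_bool_mask(mask)
    return dilate_binary(erode_binary(mask, config.element_side),
                         config.element_side)


def extract_new_trails(model2, current_mask: np.ndarray,
                       previous_mask: np.ndarray,
                       reg_config: RegistrationConfig | None = None,
                       inference_config: InferenceConfig | None = None,
                       opening_config: OpeningConfig | None = None,
                       grid: BlockGrid | None = None) -> np.ndarray:
    """Full daily-new-trail pipeline on two Model_1 masks.

    register -> differential -> tile (50% overlap) -> Model_2 -> integrate
    -> binarise -> opening. Pass ``reg_config=None`` to skip registration
    when the masks are already aligned.
    """
    current = as_bool_mask(current_mask)
    previous = as_bool_mask(previous_mask)
    valid = np.ones_like(current)
    if reg_config is not None:
        previous, valid, _ = register_with_validity(previous, current,
                                                    reg_config)
    diff = build_differential(current, previous)
    # no previous-day observation -> no evidence for change there
    diff = DifferentialImage(diff.current_only & valid,
                             diff.previous_only & valid, diff.both & valid)
    onehot = diff.to_onehot()
    if grid is None:
        size = model2.config.input_size_px
        grid = BlockGrid(block_px=size, stride_px=size // 2)
    blocks = crop_blocks(onehot, grid)
    tiles = np.stack([b for b, _ in blocks])
    probs = model2.predict(tiles)
    scored = [(probs[i], pos) for i, (_, pos) in enumerate(blocks)]
    prob_map = integrate_predictions(scored, current.shape)
    new_mask = binarize_map(prob_map, inference_config)
    return opening_filter(new_mask, opening_config)


def mask_area(mask: np.ndarray, resolution_cm_per_px: float) -> float:
    """Positive-pixel area in m²: count x (resolution/100)²."""
    if resolution_cm_per_px <= 0:
        raise ValueError("resolution must be positive")
    count = int(as_bool_mask(mask).sum())
    return count * (resolution_cm_per_px / 100.0) ** 2


def daily_area_report(entries: list[dict]) -> pd.DataFrame:
    """Per-day new-trail area table: (date, gap_days, new_area_m2, ...)."""
    return pd.DataFrame(entries, columns=["date", "gap_days", "new_area_m2"])
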