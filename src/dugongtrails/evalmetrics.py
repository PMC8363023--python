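"""Buffer-tolerant evaluation of binary trail masks.

Annotating the exact boundary of a feeding trail on an orthophoto is
uncertain at the centimetre scale, so the confusion counts tolerate
boundary disagreement: the annotation is dilated with a square structuring
element of side ``w + 2`` and the ring between the dilated and the original
annotation (the *buffer*) absorbs predicted positives as true positives.

    TP = |pred ∧ annot| + |pred ∧ buffer|
    FP = |pred ∧ ¬(annot ∨ buffer)|
    FN = |annot ∧ ¬pred|          (FN is counted against the raw annotation)

    precision = TP/(TP+FP),  recall = TP/(TP+FN),  F1 = 2TP/(2TP+FP+FN)

Zero-denominator cases are reported as 0 with an explicit ``degenerate``
flag so threshold/width sweeps stay total.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import as_bool_mask


@dataclass
class BufferSpec:
    """Buffer width ``w`` (px); the dilation element is a square of side w+2."""

    width_w_px: int = 7

    def __post_init__(self):
        if self.width_w_px < 0:
            raise ValueError("buffer width must be non-negative")

    @property
    def element_side(self) -> int:
        return self.width_w_px + 2


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    degenerate: bool = False


@dataclass
class EvalConfig:
    thresholds: Sequence[int] = tuple(range(100, 181, 10))
    buffer_widths: Sequence[int] = tuple(range(0, 11))

    def __post_init__(self):
        if any(t < 0 or t > 255 for t in self.thresholds):
            raise ValueError("thresholds must lie in [0, 255]")


def _element_origin(side: int) -> int:
    # odd side: centre; even side: upper-left of the two central cells
    return (side - 1) // 2


def dilate_binary(mask: np.ndarray, element_side_px: int) -> np.ndarray:
    """Morphological dilation with a square element; background outside the image.

    The element origin is its centre; for an even side it is anchored to the
    upper-left of the central 2x2 cells.
    """
    if element_side_px < 1:
        raise ValueError("element side must be >= 1")
    mask = as_bool_mask(mask)
    s = element_side_px
    o = _element_origin(s)
    padded = np.pad(mask, ((o, s - 1 - o), (o, s - 1 - o)))
    win = sliding_window_view(padded, (s, s))
    return win.any(axis=(-2, -1))


def erode_binary(mask: np.ndarray, element_side_px: int) -> np.ndarray:
    """Morphological erosion (same element/origin conventions as dilation)."""
    if element_side_px < 1:
        raise ValueError("element side must be >= 1")
    mask = as_bool_mask(mask)
    s = element_side_px
    o = _element_origin(s)
    padded = np.pad(mask, ((o, s - 1 - o), (o, s - 1 - o)))
    win = sliding_window_view(padded, (s, s))
    return win.all(axis=(-2, -1))


def make_buffer(annotation: np.ndarray, spec: BufferSpec) -> np.ndarray:
    """The tolerance ring: dilation(annotation, w+2) minus the annotation."""
    annotation = as_bool_mask(annotation)
    return dilate_binary(annotation, spec.element_side) & ~annotation


def buffered_confusion(prediction: np.ndarray, annotation: np.ndarray,
                       spec: BufferSpec) -> EvalReport:
    """Pixel confusion counts with buffer-tolerant true positives."""
    prediction = as_bool_mask(prediction)
    annotation = as_bool_mask(annotation)
    if prediction.shape != annotation.shape:
        raise ValueError(
            f"prediction {prediction.shape} and annotation {annotation.shape} differ")
    buffer = make_buffer(annotation, spec)
    tp = int((prediction & annotation).sum() + (prediction & buffer).sum())
    fp = int((prediction & ~(annotation | buffer)).sum())
    fn = int((annotation & ~prediction).sum())
    return f1_from_counts(tp, fp, fn)


def f1_from_counts(tp: int, fp: int, fn: int) -> EvalReport:
    """Precision/recall/F1 with explicit zero-denominator conventions."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if 2 * tp + fp + fn == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)
    return EvalReport(tp, fp, fn, precision, recall, f1, degenerate)


def buffered_recall(prediction: np.ndarray, annotation: np.ndarray,
                    spec: BufferSpec) -> float:
    """Fraction of annotated pixels lying within the buffer-dilated prediction.

    The mirror image of the buffered TP rule: an annotated pixel counts as
    recovered if the prediction comes within the buffer tolerance of it.
    Returns 0 for an empty annotation.
    """
    prediction = as_bool_mask(prediction)
    annotation = as_bool_mask(annotation)
    if prediction.shape != annotation.shape:
        raise ValueError("prediction and annotation sizes differ")
    n = int(annotation.sum())
    if n == 0:
        return 0.0
    reach = dilate_binary(prediction, spec.element_side) if prediction.any() \
        else prediction
    return int((annotation & reach).sum()) / n


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same scale as the inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def threshold_pr_curve(prob_map: np.ndarray, annotation: np.ndarray,
                       spec: BufferSpec, config: EvalConfig | None = None,
                       ) -> pd.DataFrame:
    """Precision–recall point per binarisation threshold of a probability map."""
    from .mosaic import binarize_map, InferenceConfig

    if config is None:
        config = EvalConfig()
    if len(config.thresholds) == 0:
        raise ValueError("threshold list is empty")
    rows = []
    for t in config.thresholds:
        pred = binarize_map(prob_map, InferenceConfig(luminance_threshold=int(t)))
        rep = buffered_confusion(pred, annotation, spec)
        rows.append({"threshold": int(t), "precision": rep.precision,
                     "recall": rep.recall, "f1": rep.f1})
    return pd.DataFrame(rows)


def buffer_width_sweep(prediction: np.ndarray, annotation: np.ndarray,
                       widths: Sequence[int]) -> pd.DataFrame:
    """Buffered F1 per buffer width w (non-decreasing in w).

    The knee of this curve is left to the analyst; no automatic selection.
    """
    if any(w < 0 for w in widths):
        raise ValueError("buffer widths must be non-negative")
    rows = []
    for w in widths:
        rep = buffered_confusion(prediction, annotation, BufferSpec(int(w)))
        rows.append({"width_px": int(w), "f1": rep.f1,
                     "precision": rep.precision, "recall": rep.recall})
    return pd.DataFrame(rows)


def plot_pr_curve(curve: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["recall"], curve["precision"], "o-")
    for _, row in curve.iterrows():
        ax.annotate(int(row["threshold"]), (row["recall"], row["precision"]),
                    fontsize=7)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_f1_vs_width(sweep: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(sweep["width_px"], sweep["f1"], "o-")
    ax.set_xlabel("buffer width w (px)")
    ax.set_ylabel("buffered F1")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
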