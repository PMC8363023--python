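# Methods

This note documents the models, conventions and numerical choices behind
`dugongtrails`, and what the synthetic experiments do and do not show.

## Problem setting

Dugong feeding trails are unvegetated winding tracks, 10–25 cm wide, left
in intertidal seagrass beds. On centimetre-resolution orthophotos
(0.5–1.0 cm/pixel ground sampling, unified here to 0.47 cm/pixel) they
are hard to extract by rules because they vary in shape (irregular
winding, non-constant width), colour (sediment deposited by tidal
currents makes old trails fade toward the background over roughly 8.5
days) and illuminance (water pools left in the excavated trails reflect
sunlight). The pipeline therefore uses learned segmentation for
extraction and for change detection, plus two deterministic geometric
algorithms (registration, direction scoring).

## Trail-segmentation network (Model_1) and new-trail network (Model_2)

Both networks share one architecture: an encoder–decoder fully
convolutional network with skip connections (U-Net family), with one
more encoder/decoder pair than the classic four-level design at full
scale. Per encoder level: 3×3 convolution → batch normalisation → leaky
ReLU (slope 0.1), followed by 2×2 max-pooling; a stride-2 convolution is
available as a configurable alternative downsampling. Per decoder level:
2×2 stride-2 transposed convolution → batch norm → ReLU, concatenation
with the matching encoder feature map (decoder channels first), then a
3×3 convolution block. A 1×1 convolution and sigmoid produce a per-pixel
score in [0, 1]. Channel widths start at `base_channels` (default 64)
and double per level; the per-level channel counts and convolutions per
level are configurable because reasonable variants exist.

Model_1 consumes RGB tiles scaled to [0, 1]. Model_2 consumes a
three-channel one-hot encoding of the differential image (current-only,
previous-only, both) — the three visual classes of the change problem —
avoiding any arbitrary scalar ordering of the classes.

Training minimises binary cross-entropy on the sigmoid output (computed
from logits for numerical stability) with Adam at an initial learning
rate of 0.01, batch size 8, at most 50 epochs with early stopping
(patience 5) on validation loss; the best-validation weights are kept.
Data augmentation draws, per sample: rotation from {−90°, 0°, 90°,
180°} and a horizontal flip (applied identically to image and mask), and
gamma in [0.6, 1.2] and contrast in [0.8, 1.4] (image only). Datasets
are split 50/25/25 into train/validation/test; training crops use 75%
tile overlap to enlarge the set, inference uses 50% overlap.

The layers, backpropagation and the optimiser are implemented directly
in NumPy (`nn.py`), NHWC float32, with convolution as an im2col matrix
product. Every gradient is covered by finite-difference and adjoint
tests. All randomness flows from explicit integer seeds, so builds and
training runs are bit-reproducible on a fixed BLAS.

## Tiled inference

Rasters are cropped into 256×256 blocks (0-based, row-major, top-left
origin) with 50% stride; the final row/column of blocks anchors to the
raster edge rather than padding, so overlap increases near borders and
no content is fabricated. Per-pixel scores from overlapping blocks are
combined by unweighted arithmetic mean — the natural reading of
"four-fold prediction" at 50% overlap, where each interior pixel receives
exactly four predictions — scaled by 255 and rounded to the nearest
integer. Binarisation marks a pixel as trail iff its luminance value is
**≥ 125** (the boundary value counts as trail; one side had to be chosen
and is tested). The threshold grid for precision–recall sweeps is 100 to
180 in steps of 10; the knee of the curve (and of the buffer-width
sweep) is reported, never auto-selected, because that choice is a visual
judgement.

## Buffer-tolerant evaluation

The buffer is `dilate(annotation, square of side w+2) − annotation`,
default w = 7 px ≈ 25% of the mean observed trail width (13.00 cm) at
0.47 cm/pixel. Predicted pixels in the annotation or buffer are TP;
predicted pixels outside both are FP; annotated pixels not predicted are
FN (the buffer never changes FN). Degenerate zero-denominator cases
report 0 with an explicit flag so sweeps stay total.

Two consequences worth stating plainly: (i) TP + FP = |prediction|
always, and |prediction ∧ annotation| + FN = |annotation| always, but
TP + FN can exceed |annotation| because buffer TPs are extra predicted
pixels outside the annotation; (ii) recall as defined carries no
boundary tolerance, so "fraction of planted pixels recovered" is also
offered as *buffered recall* (`buffered_recall`): an annotated pixel
counts as recovered iff it lies within the (w+2)-dilated prediction —
the mirror image of the buffered-TP rule.

Morphology conventions: dilation/erosion use a square element whose
origin is its centre, anchored to the upper-left central cell for even
sides; out-of-image pixels are background for both operators (so the
erosion/dilation duality holds only away from the border, and opening
matches `scipy.ndimage.binary_opening` defaults, which the tests verify
against brute-force double loops). The opening filter (erosion then
dilation, default 3×3) removes speckle smaller than the element, is
idempotent and anti-extensive.

## Two-stage registration

Orthophotos of consecutive days carry metre-scale georeferencing error,
so the previous day's mask is aligned to the current day's before
differencing: first 3200×3200-px blocks, then 256×256-px blocks, each
searching integer shifts up to 20% of the block length (at 0.47 cm/pixel
the coarse stage corrects up to ≈3 m). The search is exhaustive over the
integer window: the centre of the current block (inset by the window
radius) is the template and is slid over the previous block with
FFT-accelerated normalised cross-correlation, so every candidate
placement compares real content only. Ties break to the smallest shift
magnitude, then row-major order. Per-block shifts are applied
independently, pulling content from the full raster.

A block gives no evidence to move when its match is indistinguishable
from noise. Zero-variance content (empty sea/sand) is flagged no-signal
outright; beyond that, the NCC of unrelated N-pixel patches fluctuates
at the 1/√N scale, so a peak below `min_score_factor/√N` (default factor
8; empirical pure-noise peaks reach ≈4) is rejected and the identity
shift kept. This scale-free rule replaces any fixed NCC threshold, which
either rejects genuine sparse-trail matches (large templates) or passes
noise (small ones).

Rigid shifting moves content out of view, so the registered raster
carries **no-data bands** at its trailing edges. A validity raster is
propagated through both stages: blocks containing no-data are not
matched, and the differential image is restricted to the jointly
observed region — content that slid into view is not reported as new
trails, and no change claims are made where the previous day was never
seen. Area accounting is therefore over the jointly observed region.

Known limitation: a fine block containing only a locally straight, wide
trail stripe is ambiguous along the stripe axis (the aperture problem);
under heavy noise its per-block shift can slide a few pixels along the
trail. The rigid offset itself (the coarse match) is unaffected.

## Direction estimation

Angles are measured from the +x image axis with y up, modulo 180°; the
eight bins are 0°, 22.5°, …, 157.5°. For each direction a block is
covered by a family of parallel digital lines: rows (0°), columns (90°),
diagonals (135°, i.e. top-left→bottom-right), anti-diagonals (45°), and
for the remaining angles the rounded rasterisation of `r = r0 − x·tanθ`
(|tanθ| ≤ 1) or `x = x0 − r·cotθ` (steep). Every pixel belongs to
exactly one line of each family (a partition, which makes the four
axis/diagonal families coincide with their textbook definitions and is
verified by counting). Along each line, maximal runs of trail pixels
shorter than ⌈0.25·L⌉ (L = the line's in-block cell count; for
diagonals L = l−|k|) are zeroed — suppressing noise and crossings of
trails in other directions — and the direction's likelihood is the total
surviving count. Highest likelihood wins; ties break to the smallest
angle (an all-ones block returns 0°). Blocks with trail coverage below
8% are excluded. Likelihoods are unnormalised sums, as the construction
prescribes; line counts differ slightly between families, which the
recovery tests bound in practice.

Geometry of recoverability: a straight trail of width w in a block of
side L is recovered unambiguously when its coverage w/L is at least 0.08
(the exclusion rule) while runs crossing it at the adjacent 22.5° bin
(length ≈ w·cot 22.5° ≈ 2.41 w) stay below the 0.25·L run threshold,
i.e. w/L < 0.104. The recovery fixtures use L = 112, w = 10
(w/L ≈ 0.089), inside this window.

## Synthetic scenes

The generator emulates the features that make extraction hard: a
background blending sediment and seagrass colours through a
low-frequency noise field with darker speckle patches; winding trails
(heading random walk, turn SD 9° per 3-px step) with width drawn in
10–25 cm and rasterised as `round(width_cm / resolution)` pixels; linear
colour fade toward the background with age (fully faded by ≈8.5 days);
and elliptical sunlight highlights whose candidate draws are consumed
independently of the acceptance density, so scenes differing only in
highlight density differ only inside the accepted highlight regions. Day
pairs crop two windows from one padded canvas, giving an exact rigid
integer offset, and plant fresh trails disjoint from (and not touching)
the shifted old trails so the new-trail ground truth has a known
component count.

What it does **not** model: radiometric water optics, species-specific
seagrass texture, non-rigid orthophoto distortion, tidal state. Passing
the synthetic benchmarks shows the machinery is correct and learnable
end to end; it does not certify field-imagery accuracy, which requires
real annotated orthophotos and full-scale training.

## Problem sizes for desk runs

The test suite and the acceptance script run the study at compact sizes
chosen as this package's own benchmark conditions: scenes of 320×320 px
at 1.8 cm/pixel (trails 6–14 px wide), 64-px tiles, a depth-3,
base-8-channel network (max 12 epochs), registration blocks of 320/64 px,
and 250 training tiles per network. At these sizes the full suite trains
both networks and finishes in a few minutes on one CPU; the architecture,
losses, thresholds and all conventions are identical to the full-scale
configuration defaults (256-px tiles, depth 5, base 64, blocks 3200/256).

## Degenerate inputs and tie-breaks (summary)

- Binarisation at exactly the threshold: trail.
- Even-sided structuring elements: origin at the upper-left central cell.
- Zero-denominator precision/recall/F1: 0 with a degenerate flag.
- NCC of zero-variance content: NaN sentinel, shift (0, 0).
- Matching ties: smallest |shift|, then row-major.
- Direction ties: smallest angle.
- Trails that do not fit the image are clipped, never an error; a day
  offset larger than the image is an error.
- Empty threshold lists, mismatched raster sizes, rasters smaller than a
  block, and non-{0,255} mask files raise descriptive errors.
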