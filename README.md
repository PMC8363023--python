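# dugongtrails

Automated observation of **dugong feeding trails** in UAV orthophotos of
intertidal seagrass beds.

Dugongs (*Dugong dugon*) uproot whole seagrass plants while feeding,
leaving winding unvegetated tracks 10–25 cm wide. The area, daily renewal
and direction of these trails are standard indicators of how a seagrass
bed is used as a feeding ground, but mapping them on foot is slow and
restricted to small plots. This package implements a complete desk-side
pipeline for trail observation from centimetre-resolution orthophotos:

1. **Trail extraction** — an encoder–decoder segmentation network
   ("Model_1", U-Net-style with skip connections) scores 256×256-px RGB
   tiles; overlapping tile predictions are averaged, rescaled to 0–255
   luminance and binarised at a threshold of 125.
2. **Buffer-tolerant evaluation** — with TP/FP/FN pixel counts,

       precision = TP/(TP+FP),  recall = TP/(TP+FN),
       F1 = 2·TP / (2·TP + FP + FN),

   where predicted pixels falling inside a *buffer* — the ring
   `dilate(annotation, w+2) − annotation`, default width w = 7 px — count
   as TP, absorbing centimetre-scale annotation uncertainty at trail
   boundaries.
3. **Daily new trails** — consecutive-day masks are registered by
   two-stage normalised-cross-correlation template matching (3200-px
   blocks, then 256-px blocks, shifts capped at 20% of the block length),
   combined into a ternary differential image (current-only /
   previous-only / both), scored by a second network ("Model_2"), and
   cleaned with a morphological opening. Trail areas are reported in m².
4. **Trail direction** — each 256×256 block of a mask is scored against 8
   directions (0°, 22.5°, …, 157.5°) by summing trail pixels that form
   consecutive runs of at least 25% of the line length along parallel
   digital lines at each direction; blocks under 8% coverage are
   excluded; the result is a direction field and circular histogram.

Because no public imagery exists for this problem, the package ships a
seeded synthetic scene generator (`synthgen`) that emulates the relevant
structure — seagrass/sediment background, winding trails of realistic
width whose colour fades with age, water-pool highlights, day pairs with
known rigid offsets and known newly added trails — so every stage is
testable end to end with exact ground truth. The networks and their
training loop (Adam, initial learning rate 0.01, binary cross-entropy)
are implemented in NumPy with explicit backpropagation; see
`docs/methods.md` for the model and all numerical conventions.

## Worked example

```python
import numpy as np
from dugongtrails import (SceneConfig, DayPairSpec, make_day_pair,
                          RegistrationConfig, two_stage_register,
                          BufferSpec, buffered_confusion, mask_area,
                          direction_field)
from dugongtrails.trailcompass import DirectionConfig

# a synthetic day pair: 320x320 px at 1.8 cm/px, 4 winding trails,
# day 1 rigidly shifted by (12, -9) px with 2 fresh trails added
scene = SceneConfig(image_size_px=(320, 320), resolution_cm_per_px=1.8,
                    n_trails=4, seed=21)
spec = DayPairSpec(scene, rigid_offset_px=(12, -9), n_new_trails=2)
photo0, photo1, mask0, mask1, new, true_offset = make_day_pair(spec)
print("true offset:", true_offset, "| new-trail area:",
      round(mask_area(new, 1.8), 2), "m2")

reg = RegistrationConfig(coarse_block_px=320, fine_block_px=64)
corrected, diag = two_stage_register(mask0, mask1, reg)
print("recovered coarse shift:",
      tuple(diag[diag.stage == 'coarse'][['dy', 'dx']].values[0]))

rep = buffered_confusion(corrected, mask1 & ~new, BufferSpec(7))
print(f"old-trail agreement after registration: F1 = {rep.f1:.3f}")

field = direction_field(mask1, DirectionConfig(block_side_l=64))
top = field.histogram.sort_values('fraction', ascending=False).iloc[0]
print(f"dominant trail direction: {top['direction_deg']:g} deg "
      f"({100*top['fraction']:.0f}% of scored blocks)")
```

prints

```
true offset: (12, -9) | new-trail area: 0.7 m2
recovered coarse shift: (12, -9)
old-trail agreement after registration: F1 = 1.000
dominant trail direction: 135 deg (30% of scored blocks)
```

The registration recovers the planted rigid offset exactly, so the
shifted day-0 trails align perfectly with their day-1 positions (buffered
F1 = 1.0), and the per-block direction estimator reports the most common
bearing of the winding trails.

## Command line

`dugongtrails` exposes the stages as subcommands — `synth`, `train`,
`segment`, `evaluate`, `diff`, `newtrails`, `direction`, `area` — all
driven by one YAML config (flags override; unknown keys are rejected):

```bash
dugongtrails synth --seed 1 --out fixtures/ --size 320
dugongtrails evaluate --pred pred_mask.png --annot annot_mask.png --width-sweep
dugongtrails direction --mask trails.png --out-dir directions/ --overlay
```

Rasters are PNG or GeoTIFF with ESRI world files; masks are {0, 255}
single-band images; reports are CSV.

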