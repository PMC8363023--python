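"""Encoder–decoder trail-segmentation network (Model_1 / Model_2).

A U-Net-style fully convolutional network: an encoder of 3x3 conv +
batch-norm + leaky-ReLU blocks each followed by 2x2 max-pooling (or,
optionally, a stride-2 convolution), a mirrored decoder of 2x2 stride-2
transposed convolutions with skip concatenations from the matching encoder
level, and a 1x1 convolution + sigmoid head producing a per-pixel trail
score in [0, 1]. Model_1 consumes RGB tiles; Model_2 consumes the
three-channel one-hot encoding of a differential image (current-only /
previous-only / both) and scores daily-new-trail pixels.

Training uses binary cross-entropy on the sigmoid output and the Adam
optimiser with an initial learning rate of 0.01.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .evalmetrics import BufferSpec, buffered_confusion, f1_from_counts

DOWNSAMPLING_MODES = ("max_pool_2x2", "strided_conv_2")


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``depth_levels`` counts encoder/decoder pairs; the default (5) is one
    more than the classic four-level U-Net. ``base_channels`` doubles at
    each level. A compact configuration (depth 3, base 8, 64-px tiles) is
    used for CPU-scale synthetic experiments.
    """

    input_size_px: int = 256
    input_channels: int = 3
    depth_levels: int = 5
    base_channels: int = 64
    convs_per_level: int = 1
    downsampling_mode: str = "max_pool_2x2"
    leaky_slope: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.downsampling_mode not in DOWNSAMPLING_MODES:
            raise ValueError(f"downsampling_mode must be one of {DOWNSAMPLING_MODES}")
        div = 2 ** self.depth_levels
        if self.input_size_px % div:
            raise ValueError(
                f"input size {self.input_size_px} not divisible by 2^depth_levels={div}")


@dataclass
class TrainConfig:
    initial_learning_rate: float = 0.01
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    batch_size: int = 8
    max_epochs: int = 50
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-6:
            raise ValueError("split fractions must sum to 1")


@dataclass
class AugmentConfig:
    """Random augmentation draws applied per training sample.

    Geometric transforms (rotation, flip) apply identically to image and
    mask; photometric transforms (gamma, contrast) apply to the image only.
    """

    rotations_deg: tuple[int, ...] = (-90, 0, 90, 180)
    flip: bool = True
    gamma_range: tuple[float, float] = (0.6, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.4)


class TrailSegmenter:
    """The network handle: owns layers, forward/backward and (de)serialisation."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        slope = config.leaky_slope
        enc_channels = [c * 2 ** d for d in range(config.depth_levels)]

        def conv_block(c_in, c_out, act):
            return [nn.Conv2D(rng, c_in, c_out, k=3),
                    nn.BatchNorm(c_out),
                    nn.LeakyReLU(slope) if act == "leaky" else nn.ReLU()]

        self.encoder: list[list[nn.Layer]] = []   # per level: conv blocks
        self.downs: list[list[nn.Layer]] = []     # per level: downsampling op
        c_in = config.input_channels
        for c_out in enc_channels:
            blocks: list[nn.Layer] = []
            for i in range(config.convs_per_level):
                blocks += conv_block(c_in if i == 0 else c_out, c_out, "leaky")
            self.encoder.append(blocks)
            if config.downsampling_mode == "max_pool_2x2":
                self.downs.append([nn.MaxPool2()])
            else:
                self.downs.append([nn.Conv2D(rng, c_out, c_out, k=3, stride=2),
                                   nn.BatchNorm(c_out), nn.LeakyReLU(slope)])
            c_in = c_out

        bottom = enc_channels[-1] * 2
        self.bottleneck: list[nn.Layer] = []
        for i in range(config.convs_per_level):
            self.bottleneck += conv_block(c_in if i == 0 else bottom, bottom, "leaky")

        self.ups: list[list[nn.Layer]] = []
        self.decoder: list[list[nn.Layer]] = []
        c_in = bottom
        for c_skip in reversed(enc_channels):
            self.ups.append([nn.ConvTranspose2(rng, c_in, c_skip),
                             nn.BatchNorm(c_skip), nn.ReLU()])
            blocks = []
            for i in range(config.convs_per_level):
                blocks += conv_block(2 * c_skip if i == 0 else c_skip, c_skip, "relu")
            self.decoder.append(blocks)
            c_in = c_skip
        self.head = nn.Conv2D(rng, c_in, 1, k=1, pad=0)

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self) -> list[nn.Layer]:
        layers: list[nn.Layer] = []
        for blocks in self.encoder + self.downs:
            layers += blocks
        layers += self.bottleneck
        for blocks in self.ups + self.decoder:
            layers += blocks
        layers.append(self.head)
        return layers

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._all_layers():
            out += layer.params()
        return out

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        n, h, w, c = x.shape
        div = 2 ** self.config.depth_levels
        if c != self.config.input_channels:
            raise ValueError(f"expected {self.config.input_channels} channels, got {c}")
        for name, dim in (("height", h), ("width", w)):
            if dim % div:
                raise ValueError(f"input {name} {dim} not divisible by 2^depth={div}")
        return x

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        skips = []
        for blocks, down in zip(self.encoder, self.downs):
            for layer in blocks:
                x = layer.forward(x, train)
            skips.append(x)
            for layer in down:
                x = layer.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._skip_channels = []
        for up, blocks, skip in zip(self.ups, self.decoder, reversed(skips)):
            for layer in up:
                x = layer.forward(x, train)
            self._skip_channels.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)  # decoder features first
            for layer in blocks:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward_from_logits(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        skip_grads = []
        for up, blocks, c_dec in zip(reversed(self.ups), reversed(self.decoder),
                                     reversed(self._skip_channels)):
            for layer in reversed(blocks):
                g = layer.backward(g)
            skip_grads.append(g[..., c_dec:])
            g = g[..., :c_dec]
            for layer in reversed(up):
                g = layer.backward(g)
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        # skip_grads[i] belongs to encoder level i; encoder runs deepest-first here
        for down, blocks, g_skip in zip(reversed(self.downs), reversed(self.encoder),
                                        reversed(skip_grads)):
            for layer in reversed(down):
                g = layer.backward(g)
            g = g + g_skip
            for layer in reversed(blocks):
                g = layer.backward(g)

    def predict(self, tiles: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Probability maps in [0, 1] for a tile or a batch of tiles."""
        tiles = np.asarray(tiles, dtype=np.float32)
        single = tiles.ndim == 3
        if single:
            tiles = tiles[None]
        outs = [nn.sigmoid(self.forward_logits(tiles[i:i + batch_size], train=False))
                for i in range(0, len(tiles), batch_size)]
        probs = np.concatenate(outs, axis=0)[..., 0]
        return probs[0] if single else probs

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._all_layers()):
            for j, p in enumerate(layer.params()):
                out[f"layer{i:03d}_param{j}"] = p.value
            for key, arr in layer.state().items():
                out[f"layer{i:03d}_state_{key}"] = arr
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self._all_layers()):
            for j, p in enumerate(layer.params()):
                p.value[...] = arrays[f"layer{i:03d}_param{j}"]
            state = {key: arrays[f"layer{i:03d}_state_{key}"]
                     for key in layer.state()}
            layer.load_state(state)

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the architecture."""
        path = Path(path)
        np.savez(path, **self.state_arrays())
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"network": asdict(self.config)}, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrailSegmenter":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(NetworkConfig(**meta["network"]))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            model.load_state_arrays(dict(data))
        return model


def build_model(config: NetworkConfig) -> TrailSegmenter:
    """Instantiate a segmentation network from its configuration."""
    return TrailSegmenter(config)


def predict_tile(model: TrailSegmenter, tile: np.ndarray) -> np.ndarray:
    """Score one tile; raises if the tile does not match the model input."""
    tile = np.asarray(tile, dtype=np.float32)
    if tile.ndim != 3:
        raise ValueError(f"tile must be (H, W, C), got shape {tile.shape}")
    return model.predict(tile)


def augment_sample(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One random augmentation draw.

    Rotation/flip are applied to both image and mask; gamma and contrast
    perturb the image only. ``image`` is float in [0, 1]; ``mask`` is
    boolean (or binary) and is returned with the same two values.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape[:2]} differ")
    rng = np.random.default_rng(seed)
    rot = int(rng.choice(config.rotations_deg))
    do_flip = bool(rng.integers(0, 2)) if config.flip else False
    gamma = float(rng.uniform(*config.gamma_range))
    contrast = float(rng.uniform(*config.contrast_range))

    k = {0: 0, 90: 1, 180: 2, -90: 3}[rot]
    img = np.rot90(image, k, axes=(0, 1))
    msk = np.rot90(mask, k, axes=(0, 1))
    if do_flip:
        img = np.flip(img, axis=1)
        msk = np.flip(msk, axis=1)
    img = np.clip(img, 0.0, 1.0) ** gamma
    img = np.clip((img - 0.5) * contrast + 0.5, 0.0, 1.0)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def split_dataset(samples: list, fractions: tuple[float, float, float],
                  seed: int) -> tuple[list, list, list]:
    """Disjoint, exhaustive train/validation/test partition (seeded)."""
    if len(samples) == 0:
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-6 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    n = len(samples)
    order = np.random.default_rng(seed).permutation(n)
    counts = [int(np.floor(f * n)) for f in fractions]
    # distribute rounding remainder by largest fractional part (stable)
    rema = [(f * n - c, -i) for i, (f, c) in enumerate(zip(fractions, counts))]
    for _, neg_i in sorted(rema, reverse=True)[: n - sum(counts)]:
        counts[-neg_i] += 1
    parts, start = [], 0
    for c in counts:
        parts.append([samples[i] for i in order[start:start + c]])
        start += c
    return tuple(parts)


def _as_batch(samples, aug: AugmentConfig | None, rng) -> tuple[np.ndarray, np.ndarray]:
    imgs, masks = [], []
    for img, msk in samples:
        if aug is not None:
            img, msk = augment_sample(img, msk, aug, int(rng.integers(2 ** 31)))
        imgs.append(np.asarray(img, dtype=np.float32))
        masks.append(np.asarray(msk, dtype=np.float32))
    return np.stack(imgs), np.stack(masks)[..., None]


def evaluate_tiles(model: TrailSegmenter, samples, buffer_spec: BufferSpec,
                   threshold: int = 125) -> tuple[float, float]:
    """(mean BCE loss, buffered F1) of a model over (image, mask) tiles."""
    losses, tp = 0.0, 0
    fp = fn = 0
    for img, msk in samples:
        logits = model.forward_logits(np.asarray(img, np.float32)[None])
        target = np.asarray(msk, np.float32)[None, ..., None]
        losses += nn.bce_with_logits(logits, target)
        pred = np.rint(nn.sigmoid(logits[0, ..., 0]) * 255) >= threshold
        rep = buffered_confusion(pred, np.asarray(msk, bool), buffer_spec)
        tp += rep.tp
        fp += rep.fp
        fn += rep.fn
    rep = f1_from_counts(tp, fp, fn)
    return losses / max(len(samples), 1), rep.f1


def train_model(model: TrailSegmenter, dataset, train_config: TrainConfig,
                augment_config: AugmentConfig | None = None,
                buffer_spec: BufferSpec | None = None,
                ) -> tuple[TrailSegmenter, pd.DataFrame]:
    """Train with Adam/BCE; returns the best-validation-loss weights.

    ``dataset`` is either a flat list of ``(image, mask)`` tiles — split
    internally with ``train_config.split_fractions`` — or a
    ``(train, validation)`` pair of such lists. The metrics log has one row
    per epoch: training loss, validation loss and buffered validation F1.
    Raises ``RuntimeError`` if the loss goes non-finite.
    """
    if buffer_spec is None:
        buffer_spec = BufferSpec()
    if isinstance(dataset, tuple) and len(dataset) == 2:
        train_set, val_set = dataset
    else:
        train_set, val_set, _ = split_dataset(
            list(dataset), train_config.split_fractions, train_config.seed)
    if not train_set:
        raise ValueError("training split is empty")
    size = train_set[0][0].shape[0]
    if size != model.config.input_size_px:
        raise ValueError(
            f"tiles are {size} px but model expects {model.config.input_size_px}")

    rng = np.random.default_rng(train_config.seed)
    opt = nn.Adam(model.params(), lr=train_config.initial_learning_rate)
    rows = []
    best_val, best_state, patience = np.inf, None, 0
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), train_config.batch_size):
            batch = [train_set[i] for i in order[start:start + train_config.batch_size]]
            x, y = _as_batch(batch, augment_config, rng)
            logits = model.forward_logits(x, train=True)
            loss = nn.bce_with_logits(logits, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {loss}")
            opt.zero_grad()
            model.backward_from_logits(nn.bce_logits_grad(logits, y))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_loss, val_f1 = (evaluate_tiles(model, val_set, buffer_spec)
                            if val_set else (np.nan, np.nan))
        rows.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                     "val_loss": val_loss, "val_buffered_f1": val_f1,
                     "learning_rate": train_config.initial_learning_rate})
        monitor = val_loss if val_set else epoch_loss / n_batches
        if monitor < best_val - 1e-6:
            best_val, patience = monitor, 0
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        else:
            patience += 1
            if patience >= train_config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, pd.DataFrame(rows)
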