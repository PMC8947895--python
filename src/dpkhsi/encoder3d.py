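"""Three-layer 3D convolutional encoder and layer-feature extraction strategies.

The 3D encoder treats a PCA-reduced patch as a single-channel volume
(``27 x 27 x 30`` by default) and stacks three valid 3D convolutions, each
followed by batch normalisation, ReLU and 2x2x2 max pooling:

    27x27x30 --conv 32@4x4x5--> 24x24x26 --pool--> 12x12x13
             --conv 64@5x5x4-->  8x 8x10 --pool-->  4x 4x 5
             --conv 128@3x3x4--> 2x 2x 2 --pool-->  1x 1x 1,

so the flattened encoder output length equals the third layer's kernel
count.  A fully connected head (width 500, ReLU, then softmax over the
class count) completes the supervised network.

The companion 2D encoder used for the layer-feature experiments is a
valid-convolution stack 96@5x5 / 192@3x3 / 384@3x3 on an 11x11 input with
no inter-layer pooling, giving layer activations h1: 96x7x7, h2: 192x5x5,
h3: 384x3x3.  (The stack is reconstructed from its published feature sizes:
channel counts are the pooled sizes and map sides are the un-pooled sizes
divided by the channels; it is asserted only against those sizes.)  A
feature strategy picks a subset of {h1, h2, h3} and either flattens the
maps or global-max-pools each channel before concatenation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .preprocess import PatchSet

__all__ = [
    "Encoder3DSpec",
    "FeatureStrategy",
    "ConvEncoder",
    "TrainEncoderConfig",
    "shape_chain",
    "build_encoder3d",
    "build_encoder2d",
    "forward_features_2d",
    "feature_dims",
    "assemble_features",
    "train_encoder",
]

TABLE_3D_LAYERS = ((32, (4, 4, 5)), (64, (5, 5, 4)), (128, (3, 3, 4)))
ENC2D_CHANNELS = (96, 192, 384)
ENC2D_KERNELS = ((5, 5), (3, 3), (3, 3))
ENC2D_INPUT_SIDE = 11


@dataclass
class Encoder3DSpec:
    """Architecture of the 3D encoder (defaults reproduce the reference net)."""

    layers: tuple = TABLE_3D_LAYERS          # (kernel_count, kernel_size) per layer
    pool: tuple[int, int, int] = (2, 2, 2)
    batch_norm: bool = True
    fc_width: int = 500
    input_shape: tuple[int, int, int] = (27, 27, 30)


@dataclass
class FeatureStrategy:
    """Which encoder layers feed the classifier, and whether they are pooled."""

    layers_used: tuple[str, ...]  # subset of ("h1", "h2", "h3")
    pooled: bool

    def __post_init__(self):
        if not self.layers_used:
            raise ValueError("feature strategy must use at least one layer")
        bad = [h for h in self.layers_used if h not in ("h1", "h2", "h3")]
        if bad:
            raise ValueError(f"unknown layer name(s) {bad}")


def shape_chain(spec: Encoder3DSpec) -> list[dict]:
    """Analytic per-layer shapes: conv output and pooled output volumes."""
    shape = tuple(spec.input_shape)
    chain = []
    for li, (count, kernel) in enumerate(spec.layers, start=1):
        if any(k > s for k, s in zip(kernel, shape)):
            raise ValueError(
                f"layer {li}: kernel {kernel} exceeds its input extent {shape}"
            )
        conv_out = tuple(s - k + 1 for s, k in zip(shape, kernel))
        pool_out = tuple(math.ceil(c / p) for c, p in zip(conv_out, spec.pool))
        chain.append({
            "layer": li, "input": shape, "kernels": count,
            "conv_out": conv_out, "pool_out": pool_out,
        })
        shape = pool_out
    return chain


def flattened_length(spec: Encoder3DSpec) -> int:
    chain = shape_chain(spec)
    last = chain[-1]
    return last["kernels"] * int(np.prod(last["pool_out"]))


class ConvEncoder:
    """A stack of conv blocks whose per-block activations are retrievable.

    Each block is conv (+ batch norm) + ReLU (+ max pool).  The 3D encoder
    pools after every block; the 2D encoder has no inter-block pooling.
    """

    def __init__(self, blocks: list[list[_nn.Layer]], input_channels: int = 1):
        self.blocks = blocks
        self.input_channels = input_channels

    def layers(self) -> list[_nn.Layer]:
        return [l for blk in self.blocks for l in blk]

    def params(self):
        return [p for l in self.layers() for p in l.params()]

    def grads(self):
        return [g for l in self.layers() for g in l.grads()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for blk in self.blocks:
            for l in blk:
                x = l.forward(x, train=train)
        return x

    def forward_blocks(self, x: np.ndarray) -> list[np.ndarray]:
        """Activation at the end of every block (inference mode)."""
        outs = []
        for blk in self.blocks:
            for l in blk:
                x = l.forward(x)
            outs.append(x)
        return outs


def build_encoder3d(spec: Encoder3DSpec | None = None, seed: int = 0) -> ConvEncoder:
    """Build the 3D encoder; raises a shape error naming any infeasible layer."""
    spec = spec or Encoder3DSpec()
    shape_chain(spec)  # validates feasibility, names the offending layer
    rng = np.random.default_rng(seed)
    blocks = []
    in_ch = 1
    for count, kernel in spec.layers:
        blk: list[_nn.Layer] = [_nn.ConvND(in_ch, count, kernel, rng=rng)]
        if spec.batch_norm:
            blk.append(_nn.BatchNorm(count))
        blk.append(_nn.ReLU())
        blk.append(_nn.MaxPoolND(spec.pool))
        blocks.append(blk)
        in_ch = count
    return ConvEncoder(blocks, input_channels=1)


def build_encoder2d(
    in_channels: int,
    channels: tuple[int, ...] = ENC2D_CHANNELS,
    kernels: tuple = ENC2D_KERNELS,
    batch_norm: bool = False,
    seed: int = 0,
) -> ConvEncoder:
    """Build the 2D layer-feature encoder (no inter-layer pooling)."""
    rng = np.random.default_rng(seed)
    blocks = []
    in_ch = in_channels
    for count, kernel in zip(channels, kernels):
        blk: list[_nn.Layer] = [_nn.ConvND(in_ch, count, kernel, rng=rng)]
        if batch_norm:
            blk.append(_nn.BatchNorm(count))
        blk.append(_nn.ReLU())
        blocks.append(blk)
        in_ch = count
    return ConvEncoder(blocks, input_channels=in_channels)


def forward_features_2d(encoder2d: ConvEncoder, patch: np.ndarray) -> dict[str, np.ndarray]:
    """Per-layer activations {h1, h2, h3} for a patch or patch batch."""
    single = patch.ndim == 3
    x = patch[None] if single else patch
    outs = encoder2d.forward_blocks(x)
    maps = {f"h{i + 1}": (o[0] if single else o) for i, o in enumerate(outs)}
    return maps


def feature_dims(
    strategy: FeatureStrategy,
    channels: tuple[int, ...] = ENC2D_CHANNELS,
    sides: tuple[int, ...] = (7, 5, 3),
) -> int:
    """Analytic feature-vector length of a strategy (un-pooled or pooled)."""
    total = 0
    for h in strategy.layers_used:
        i = int(h[1]) - 1
        total += channels[i] if strategy.pooled else channels[i] * sides[i] ** 2
    return total


def assemble_features(maps: dict[str, np.ndarray], strategy: FeatureStrategy) -> np.ndarray:
    """Concatenate the chosen layer activations into one feature vector.

    With ``pooled=True`` every channel is reduced to its global spatial
    maximum first; otherwise maps are flattened.  Works on single samples
    (3-D maps) or batches (4-D maps).
    """
    parts = []
    for h in strategy.layers_used:
        if h not in maps:
            raise KeyError(f"strategy uses {h} but maps only has {sorted(maps)}")
        m = maps[h]
        batched = m.ndim == 4
        if strategy.pooled:
            axes = (1, 2) if batched else (0, 1)
            parts.append(m.max(axis=axes))
        else:
            parts.append(m.reshape(m.shape[0], -1) if batched else m.ravel())
    return np.concatenate(parts, axis=-1)


# --------------------------------------------------------------------------
# training

@dataclass
class TrainEncoderConfig:
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 16
    fc_width: int = 500
    seed: int = 0
    log_every: int = 1


class _Crop(_nn.Layer):
    """Crop spatial axes to a target size (decoder fix-up after upsampling)."""

    trainable = False

    def __init__(self, target_sp):
        self.target_sp = tuple(target_sp)

    def forward(self, x, train=False):
        if train:
            self._in_sp = x.shape[1:-1]
        sl = (slice(None),) + tuple(slice(0, t) for t in self.target_sp) + (slice(None),)
        return x[sl]

    def backward(self, g):
        pads = [(0, 0)] + [
            (0, s - t) for s, t in zip(self._in_sp, self.target_sp)
        ] + [(0, 0)]
        return np.pad(g, pads)


def _mirrored_decoder(encoder: ConvEncoder, input_sp: tuple, seed: int) -> list[_nn.Layer]:
    """Decoder mirroring the encoder: upsample for each pool, transposed conv
    for each conv, ReLU between blocks and a linear last layer."""
    rng = np.random.default_rng(seed)
    # replay encoder shapes to know pre-pool sizes for exact cropping
    shapes = []  # per block: (pre_conv_sp, pre_pool_sp)
    sp = tuple(input_sp)
    specs = []
    for blk in encoder.blocks:
        conv = blk[0]
        pre_conv = sp
        sp = tuple(s - k + 1 for s, k in zip(sp, conv.kernel))
        pre_pool = sp
        pool = next((l for l in blk if isinstance(l, _nn.MaxPoolND)), None)
        if pool is not None:
            sp = tuple(math.ceil(s / p) for s, p in zip(sp, pool.pool))
        in_ch = conv.W.shape[-1]
        out_ch = conv.W.shape[0]
        specs.append((conv.kernel, in_ch, out_ch, pool.pool if pool else None))
        shapes.append((pre_conv, pre_pool))

    layers: list[_nn.Layer] = []
    for bi in reversed(range(len(encoder.blocks))):
        kernel, in_ch, out_ch, pool = specs[bi]
        pre_conv, pre_pool = shapes[bi]
        if pool is not None:
            layers.append(_nn.Upsample(pool))
            layers.append(_Crop(pre_pool))
        layers.append(_nn.ConvTransposeND(out_ch, in_ch, kernel, rng=rng))
        layers.append(_Crop(pre_conv))
        if bi > 0:
            layers.append(_nn.ReLU())
    return layers


def train_encoder(
    encoder: ConvEncoder,
    patches: PatchSet | np.ndarray,
    mode: str = "autoencoder",
    hyper: TrainEncoderConfig | None = None,
    classes: int | None = None,
    labels: np.ndarray | None = None,
) -> dict:
    """Train the encoder; returns the training history.

    ``autoencoder`` minimises reconstruction error through a mirrored
    decoder (discarded afterwards); ``supervised`` trains through the fully
    connected head on labels.  Loss curves are logged per epoch; a NaN loss
    aborts with a diagnostic.
    """
    hyper = hyper or TrainEncoderConfig()
    if isinstance(patches, PatchSet):
        x = patches.patches
        labels = patches.labels if labels is None else labels
    else:
        x = np.asarray(patches)
    # 3D encoders consume single-channel volumes
    if encoder.input_channels == 1 and x.ndim == 4:
        x = x[..., None]
    rng = np.random.default_rng(hyper.seed)

    if mode == "autoencoder":
        decoder = _mirrored_decoder(encoder, x.shape[1:-1], hyper.seed + 1)
        model = _nn.Sequential(encoder.layers() + decoder)
        target = x
        y = None
    elif mode == "supervised":
        if labels is None:
            raise ValueError("supervised mode needs labels")
        y = np.asarray(labels) - 1
        n_classes = classes or int(y.max()) + 1
        probe = encoder.forward(x[:1])
        head = [
            _nn.Flatten(),
            _nn.Dense(int(np.prod(probe.shape[1:])), hyper.fc_width, rng=rng),
            _nn.ReLU(),
            _nn.Dense(hyper.fc_width, n_classes, rng=rng),
        ]
        model = _nn.Sequential(encoder.layers() + head)
        target = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    opt = _nn.Adam(model.params(), model.grads(), lr=hyper.lr)
    n = x.shape[0]
    history = {"loss": [], "mode": mode}
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            out = model.forward(x[idx], train=True)
            if mode == "autoencoder":
                loss, grad = _nn.mse_loss(out, target[idx])
            else:
                loss, grad = _nn.softmax_cross_entropy(out, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (loss={loss}) at epoch {epoch}; "
                    "reduce the learning rate"
                )
            model.backward(grad)
            opt.step()
            epoch_loss += loss * idx.size
        history["loss"].append(epoch_loss / n)
    if mode == "supervised":
        history["head"] = _nn.Sequential(model.layers[len(encoder.layers()):])
    return history
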