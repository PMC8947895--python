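"""SDCNN: spectral-difference super-resolution for hyperspectral spectra.

The model learns the mapping from the first-order band difference of a
spectrally degraded spectrum to the reference band difference.  It is a
small stack of 1-D same-padding convolutions over the difference signal
(three layers by default, kernel sizes 9-5-3, hidden channels 64/32, ReLU
between layers, linear output) trained with mean squared error.  Restored
spectra are obtained by cumulative reintegration of the predicted
differences anchored at the first degraded band.

Training logs average PSNR and SSIM between the predicted and reference
difference arrays at a fixed evaluation interval, which makes the
increase-then-plateau behaviour of the quality curves observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .hsi_io import HyperCube
from .metrics import psnr, ssim

__all__ = [
    "SDCNNSpec",
    "SDCNN",
    "SDCNNTrainConfig",
    "build_sdcnn",
    "train_sdcnn",
    "apply_sdcnn",
    "reintegrate",
]


@dataclass
class SDCNNSpec:
    """Layer plan: one kernel size per layer; hidden channel widths between."""

    kernel_sizes: tuple[int, ...] = (9, 5, 3)
    channels: tuple[int, ...] = (64, 32)
    loss: str = "mse"

    @property
    def n_layers(self) -> int:
        return len(self.kernel_sizes)

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if len(self.channels) != self.n_layers - 1:
            raise ValueError(
                f"{self.n_layers} layers need {self.n_layers - 1} hidden widths, "
                f"got {len(self.channels)}"
            )
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("same padding needs odd kernel sizes (center undefined)")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")

    @property
    def receptive_field(self) -> int:
        return sum(self.kernel_sizes) - (self.n_layers - 1)


@dataclass
class SDCNN:
    spec: SDCNNSpec
    net: _nn.Sequential
    history: dict = field(default_factory=dict)

    def predict_diff(self, input_diff: np.ndarray) -> np.ndarray:
        """Predicted reference differences for (..., bands-1) difference signals."""
        flat = np.asarray(input_diff, dtype=float).reshape(-1, input_diff.shape[-1])
        out = self.net.forward(flat[:, :, None])[:, :, 0]
        return out.reshape(input_diff.shape)


def build_sdcnn(spec: SDCNNSpec | None = None, seed: int = 0) -> SDCNN:
    """Stack of same-padding 1-D convolutions; last layer linear."""
    spec = spec or SDCNNSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    widths = (1,) + tuple(spec.channels) + (1,)
    layers: list[_nn.Layer] = []
    for li, k in enumerate(spec.kernel_sizes):
        layers.append(_nn.ConvND(widths[li], widths[li + 1], (k,), padding="same", rng=rng))
        if li < spec.n_layers - 1:
            layers.append(_nn.ReLU())
    return SDCNN(spec, _nn.Sequential(layers))


@dataclass
class SDCNNTrainConfig:
    lr: float = 1e-3
    iterations: int = 300
    batch_size: int = 64
    eval_every: int = 20
    seed: int = 0


def train_sdcnn(
    model: SDCNN,
    input_diff: np.ndarray,
    reference_diff: np.ndarray,
    hyper: SDCNNTrainConfig | None = None,
) -> SDCNN:
    """Minimise MSE between predicted and reference differences.

    ``input_diff`` and ``reference_diff`` must have equal shapes; the
    leading axes index pixels.  PSNR/SSIM curves against the reference are
    recorded every ``eval_every`` iterations.  A NaN loss aborts.
    """
    hyper = hyper or SDCNNTrainConfig()
    if input_diff.shape != reference_diff.shape:
        raise ValueError("input and reference difference shapes must match")
    x = np.asarray(input_diff, dtype=float).reshape(-1, input_diff.shape[-1])[:, :, None]
    t = np.asarray(reference_diff, dtype=float).reshape(-1, reference_diff.shape[-1])[:, :, None]
    rng = np.random.default_rng(hyper.seed)
    opt = _nn.Adam(model.net.params(), model.net.grads(), lr=hyper.lr)
    n = x.shape[0]
    curves = {"iteration": [], "psnr": [], "ssim": [], "loss": []}
    peak = float(np.abs(t).max()) or 1.0
    for it in range(1, hyper.iterations + 1):
        idx = rng.integers(0, n, size=min(hyper.batch_size, n))
        out = model.net.forward(x[idx], train=True)
        loss, grad = _nn.mse_loss(out, t[idx])
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged (loss={loss}) at iteration {it}")
        model.net.backward(grad)
        opt.step()
        if it % hyper.eval_every == 0 or it == hyper.iterations:
            pred = model.predict_diff(input_diff)
            curves["iteration"].append(it)
            curves["psnr"].append(psnr(pred, reference_diff, peak=peak))
            curves["ssim"].append(ssim(pred.reshape(-1, pred.shape[-1]),
                                       reference_diff.reshape(-1, pred.shape[-1])))
            curves["loss"].append(loss)
    model.history = curves
    return model


def reintegrate(first_band: np.ndarray, diffs: np.ndarray) -> np.ndarray:
    """Cumulative reintegration of band differences anchored at a first band."""
    bands = diffs.shape[-1] + 1
    out = np.empty(diffs.shape[:-1] + (bands,))
    out[..., 0] = first_band
    out[..., 1:] = first_band[..., None] + np.cumsum(diffs, axis=-1)
    return out


def apply_sdcnn(
    model: SDCNN,
    degraded: HyperCube | np.ndarray,
    down_factor: int | None = None,
) -> np.ndarray:
    """Restore spectra: predict differences from the degraded cube's own
    differences, then reintegrate anchored at the first degraded band.

    When ``down_factor`` is given, a data-consistency back-projection is
    applied afterwards: each ``down_factor``-band block of the restored
    spectrum is shifted so its mean matches the degraded spectrum's block
    mean (which block-average degradation preserves from the reference),
    removing the low-frequency drift that reintegration accumulates.
    """
    data = degraded.data if isinstance(degraded, HyperCube) else np.asarray(degraded)
    input_diff = np.diff(data, axis=-1)
    pred = model.predict_diff(input_diff)
    restored = reintegrate(data[..., 0], pred)
    if down_factor is not None and down_factor > 1:
        bands = data.shape[-1]
        if bands % down_factor != 0:
            raise ValueError("bands not divisible by down_factor")
        blocks = bands // down_factor
        deg_means = data.reshape(*data.shape[:-1], blocks, down_factor).mean(axis=-1)
        res_means = restored.reshape(*data.shape[:-1], blocks, down_factor).mean(axis=-1)
        restored = restored + np.repeat(deg_means - res_means, down_factor, axis=-1)
    return restored
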