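"""Pre-learned-kernel CNN: cluster centers become frozen convolution kernels.

Instead of learning convolution weights by back-propagation, the kernels are
taken from the cluster centers that density-peaks clustering finds among
kernel-sized sub-image blocks of the training patches.  The network is the
single-convolutional-layer architecture

    input -> conv(frozen kernel bank) -> ReLU -> max-pool -> flatten
          -> fully connected -> softmax,

and error back-propagation updates only the fully connected part.  The
number of kernels K is decided adaptively by the MCFSFDP threshold sweep (or
fixed by top-k gamma selection, or drawn at random for the random-kernel
ablation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .preprocess import PatchSet, SubPatchSet
from .density_peaks import ClusterResult

__all__ = [
    "KernelBank",
    "PreLearnedCNN",
    "TrainConfig",
    "centers_to_kernels",
    "random_kernels",
    "conv_forward",
    "max_pool",
    "train_classifier",
    "predict",
]


@dataclass
class KernelBank:
    """K frozen convolution kernels with provenance.

    Under ``zero_mean_unit_norm`` each kernel is mean-centred and scaled to
    unit Frobenius norm, so its response acts as a matched filter for the
    block pattern it came from.
    """

    kernels: np.ndarray  # K x n x n x d
    provenance: str = "mcfsfdp"
    normalisation: str = "zero_mean_unit_norm"

    def __post_init__(self):
        if self.kernels.ndim != 4 or self.kernels.shape[0] < 1:
            raise ValueError("kernel bank must be K x n x n x d with K >= 1")

    @property
    def K(self) -> int:
        return self.kernels.shape[0]

    @property
    def n(self) -> int:
        return self.kernels.shape[1]

    @property
    def d(self) -> int:
        return self.kernels.shape[3]

    def checksum(self) -> str:
        return hashlib.sha256(np.ascontiguousarray(self.kernels).tobytes()).hexdigest()


def _normalise_kernels(kernels: np.ndarray) -> np.ndarray:
    out = kernels - kernels.mean(axis=(1, 2, 3), keepdims=True)
    norms = np.sqrt((out**2).sum(axis=(1, 2, 3), keepdims=True))
    if np.any(norms < 1e-12):
        bad = np.flatnonzero(norms.ravel() < 1e-12)
        raise ValueError(
            f"kernel(s) {bad.tolist()} are constant blocks: zero after mean-centering"
        )
    return out / norms


def centers_to_kernels(
    sub: SubPatchSet,
    result: ClusterResult,
    normalisation: str = "zero_mean_unit_norm",
    provenance: str = "mcfsfdp",
) -> KernelBank:
    """Turn the cluster-center sub-image blocks into a kernel bank."""
    centers = np.asarray(result.centers, dtype=int)
    if centers.size == 0:
        raise ValueError("cluster result has no centers")
    if centers.max() >= len(sub):
        raise ValueError("center index out of range of the sub-patch set")
    kernels = sub.blocks[centers].astype(float)
    if normalisation == "zero_mean_unit_norm":
        kernels = _normalise_kernels(kernels)
    elif normalisation != "none":
        raise ValueError(f"unknown normalisation {normalisation!r}")
    return KernelBank(kernels, provenance=provenance, normalisation=normalisation)


def random_kernels(K: int, n: int, d: int, seed: int = 0) -> KernelBank:
    """Random-kernel ablation bank (unit-norm Gaussian kernels)."""
    rng = np.random.default_rng(seed)
    kernels = rng.standard_normal((K, n, n, d))
    return KernelBank(_normalise_kernels(kernels), provenance="random")


# --------------------------------------------------------------------------
# forward primitives

def conv_forward(
    patch: np.ndarray, bank: KernelBank, activation: str = "relu"
) -> np.ndarray:
    """Valid stride-1 correlation of a patch (or batch) with the kernel bank.

    An ``s x s x d`` patch yields ``K`` feature maps of side ``s - n + 1``.
    """
    single = patch.ndim == 3
    x = patch[None] if single else patch
    if x.shape[-1] != bank.d:
        raise ValueError(f"channel mismatch: patch d={x.shape[-1]}, bank d={bank.d}")
    conv = _nn.ConvND(bank.d, bank.K, (bank.n, bank.n), frozen=True)
    conv.W = bank.kernels
    conv.b = np.zeros(bank.K)
    out = conv.forward(x)
    if activation == "relu":
        out = np.maximum(out, 0.0)
    elif activation != "identity":
        raise ValueError(f"unknown activation {activation!r}")
    return out[0] if single else out


def max_pool(fmap: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping p-by-p max pooling of one 2-D feature map.

    When p does not divide the side, the remainder is padded with -inf (so
    partial windows keep their true maximum).
    """
    if p <= 0:
        raise ValueError("pool size must be positive")
    fmap = np.asarray(fmap, dtype=float)
    if fmap.ndim != 2:
        raise ValueError("max_pool expects a single 2-D feature map")
    pool = _nn.MaxPoolND((p, p))
    return pool.forward(fmap[None, :, :, None])[0, :, :, 0]


# --------------------------------------------------------------------------
# the network

@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 100
    patience: int = 10
    batch_size: int = 64
    fc_hidden: int = 64   # width of the fully connected layer before softmax
    seed: int = 0


@dataclass
class PreLearnedCNN:
    bank: KernelBank
    classes: int
    pool_p: int = 2
    feature_mode: str = "flatten"  # or "global_pool"
    activation: str = "relu"
    fc: _nn.Sequential | None = None
    history: dict = field(default_factory=dict)

    def features(self, patches: np.ndarray) -> np.ndarray:
        """Frozen conv + pool features, flattened per sample."""
        fmaps = conv_forward(patches, self.bank, self.activation)
        if self.feature_mode == "global_pool":
            return fmaps.max(axis=(1, 2))
        pool = _nn.MaxPoolND((self.pool_p, self.pool_p))
        pooled = pool.forward(fmaps)
        return pooled.reshape(pooled.shape[0], -1)

    def logits(self, patches: np.ndarray) -> np.ndarray:
        if self.fc is None:
            raise ValueError("network is untrained")
        return self.fc.forward(self.features(patches))


def _build_fc(n_features: int, classes: int, hidden: int, rng) -> _nn.Sequential:
    layers: list[_nn.Layer] = []
    if hidden > 0:
        layers += [_nn.Dense(n_features, hidden, rng=rng), _nn.ReLU()]
        n_features = hidden
    layers.append(_nn.Dense(n_features, classes, rng=rng))
    return _nn.Sequential(layers)


def train_classifier(
    net: PreLearnedCNN,
    train: PatchSet,
    val: PatchSet,
    hyper: TrainConfig | None = None,
) -> PreLearnedCNN:
    """Fit the fully connected part by Adam on cross-entropy.

    The conv kernels are frozen by construction (only FC parameters are ever
    touched); early stopping restores the FC weights of the best validation
    epoch.  Training history (loss, val accuracy per epoch) is recorded on
    the returned network.
    """
    hyper = hyper or TrainConfig()
    if train.n_classes < 2:
        raise ValueError("training set must contain at least 2 classes")
    rng = np.random.default_rng(hyper.seed)

    x_train = net.features(train.patches)
    y_train = train.labels - 1
    x_val = net.features(val.patches) if len(val) else None
    y_val = val.labels - 1 if len(val) else None

    net.fc = _build_fc(x_train.shape[1], net.classes, hyper.fc_hidden, rng)
    opt = _nn.Adam(net.fc.params(), net.fc.grads(), lr=hyper.lr)

    best_acc, best_state, since_best = -1.0, None, 0
    losses, val_accs = [], []
    n = x_train.shape[0]
    for epoch in range(hyper.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            logits = net.fc.forward(x_train[idx], train=True)
            loss, grad = _nn.softmax_cross_entropy(logits, y_train[idx])
            net.fc.backward(grad)
            opt.step()
            epoch_loss += loss * idx.size
        losses.append(epoch_loss / n)

        if x_val is not None and len(x_val):
            acc = float(np.mean(net.fc.forward(x_val).argmax(axis=1) == y_val))
        else:
            acc = float(np.mean(net.fc.forward(x_train).argmax(axis=1) == y_train))
        val_accs.append(acc)
        if acc > best_acc + 1e-12:
            best_acc, since_best = acc, 0
            best_state = [p.copy() for p in net.fc.params()]
        else:
            since_best += 1
            if since_best >= hyper.patience:
                break
    if best_state is not None:
        for p, b in zip(net.fc.params(), best_state):
            p[...] = b
    net.history = {"loss": losses, "val_acc": val_accs, "best_val_acc": best_acc}
    return net


def predict(net: PreLearnedCNN, patches: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (1..C) and softmax probabilities for a patch batch."""
    if patches.ndim == 3:
        patches = patches[None]
    probs = _nn.softmax(net.logits(patches))
    return probs.argmax(axis=1) + 1, probs


# --------------------------------------------------------------------------
# persistence

def save_model(net: PreLearnedCNN, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "kernels.npz", kernels=net.bank.kernels)
    arch = {
        "classes": net.classes,
        "pool_p": net.pool_p,
        "feature_mode": net.feature_mode,
        "activation": net.activation,
        "provenance": net.bank.provenance,
        "normalisation": net.bank.normalisation,
        "fc_shapes": [list(p.shape) for p in (net.fc.params() if net.fc else [])],
    }
    (directory / "architecture.json").write_text(json.dumps(arch, indent=2))
    if net.fc is not None:
        np.savez(directory / "fc_weights.npz",
                 **{f"p{i}": p for i, p in enumerate(net.fc.params())})


def load_model(directory) -> PreLearnedCNN:
    directory = Path(directory)
    arch = json.loads((directory / "architecture.json").read_text())
    kernels = np.load(directory / "kernels.npz")["kernels"]
    bank = KernelBank(kernels, provenance=arch["provenance"],
                      normalisation=arch["normalisation"])
    net = PreLearnedCNN(bank, arch["classes"], pool_p=arch["pool_p"],
                        feature_mode=arch["feature_mode"], activation=arch["activation"])
    fcw = directory / "fc_weights.npz"
    if fcw.exists() and arch["fc_shapes"]:
        data = np.load(fcw)
        params = [data[f"p{i}"] for i in range(len(data.files))]
        # rebuild the FC stack from the stored shapes
        hidden = params[0].shape[1] if len(params) > 2 else 0
        net.fc = _build_fc(params[0].shape[0], arch["classes"], hidden,
                           np.random.default_rng(0))
        for p, stored in zip(net.fc.params(), params):
            p[...] = stored
    return net
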