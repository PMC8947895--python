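"""Synthetic fixtures: 2-D blob sets, labelled hyperspectral scenes, SR pairs.

Everything downstream (clustering, classification, spectral super-resolution)
is testable without external downloads:

* :func:`make_blobs` draws isotropic Gaussian clusters for decision-graph and
  center-count experiments (a seeded analogue of a small 2-D point set with a
  known number of density peaks).
* :func:`make_scene` builds a labelled hyperspectral cube: per-class
  endmember spectra are smooth positive curves (sums of Gaussian bumps over
  band index), spatial structure is a seeded Voronoi partition, and each
  pixel spectrum is its endmember scaled by multiplicative illumination
  jitter plus additive Gaussian noise at a prescribed SNR.  Pixels near
  Voronoi boundaries are linearly mixed.
* :func:`make_sr_pairs` produces degraded/reference spectral-difference
  pairs for super-resolution training: the reference is the first-order band
  difference of the cube; the input is the same difference computed after
  band-block-averaging and linear re-interpolation to the full band count.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .hsi_io import HyperCube

__all__ = [
    "BlobSet",
    "SceneSpec",
    "make_blobs",
    "make_scene",
    "make_sr_pairs",
    "degrade_bands",
]


@dataclass
class BlobSet:
    points: np.ndarray       # N x 2
    true_labels: np.ndarray  # N ints in 1..k_true
    k_true: int
    seed: int


@dataclass
class SceneSpec:
    rows: int = 64
    cols: int = 64
    n_classes: int = 4
    n_bands: int = 32
    snr_db: float = 30.0
    smoothness: float = 2.0      # px, spatial scale of illumination jitter
    jitter: float = 0.05         # relative std of illumination jitter
    mixing_width: float = 0.0    # px, linear boundary mixing
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_bands < 8:
            raise ValueError("n_bands must be >= 8")
        if not np.isfinite(self.snr_db) and self.snr_db != np.inf:
            raise ValueError("snr_db must be finite or +inf")
        if self.rows < 2 or self.cols < 2:
            raise ValueError("scene must be at least 2x2")


def make_blobs(n: int, k: int, separation: float, seed: int) -> BlobSet:
    """``k`` isotropic unit-variance Gaussian blobs with centroid spacing
    ``separation`` (in units of the within-cluster standard deviation)."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    # place blob centroids with pairwise distance >= separation
    centers = []
    box = separation * max(1.0, np.sqrt(k))
    while len(centers) < k:
        cand = rng.uniform(-box, box, size=2)
        if all(np.linalg.norm(cand - c) >= separation for c in centers):
            centers.append(cand)
    centers = np.array(centers)

    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    points = np.vstack(
        [centers[i] + rng.standard_normal((sizes[i], 2)) for i in range(k)]
    )
    labels = np.repeat(np.arange(1, k + 1), sizes)
    perm = rng.permutation(n)
    return BlobSet(points[perm], labels[perm], k, seed)


def _endmembers(n_classes: int, n_bands: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive per-class spectra: baseline plus 2-4 Gaussian bumps."""
    b = np.arange(n_bands, dtype=float)
    em = np.empty((n_classes, n_bands))
    for c in range(n_classes):
        spectrum = np.full(n_bands, 0.1)
        for _ in range(rng.integers(2, 5)):
            amp = rng.uniform(0.4, 1.2)
            mu = rng.uniform(0, n_bands - 1)
            sig = rng.uniform(n_bands / 20, n_bands / 6)
            spectrum += amp * np.exp(-0.5 * ((b - mu) / sig) ** 2)
        em[c] = spectrum
    return em


def make_scene(spec: SceneSpec) -> tuple[HyperCube, np.ndarray, np.ndarray]:
    """Generate ``(cube, label_map, endmembers)`` for a labelled scene."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    em = _endmembers(spec.n_classes, spec.n_bands, rng)

    # seeded Voronoi partition of the image grid
    seeds = np.column_stack(
        [rng.uniform(0, spec.rows, spec.n_classes), rng.uniform(0, spec.cols, spec.n_classes)]
    )
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    grid = np.stack([rr, cc], axis=-1).astype(float)          # R x C x 2
    d = np.linalg.norm(grid[:, :, None, :] - seeds[None, None, :, :], axis=-1)
    order = np.argsort(d, axis=2)
    labels = order[:, :, 0] + 1                               # 1..C

    # abundance weights: pure class except near Voronoi boundaries
    weights = np.zeros((spec.rows, spec.cols, spec.n_classes))
    np.put_along_axis(weights, (labels - 1)[:, :, None], 1.0, axis=2)
    if spec.mixing_width > 0:
        d1 = np.take_along_axis(d, order[:, :, :1], axis=2)[:, :, 0]
        d2 = np.take_along_axis(d, order[:, :, 1:2], axis=2)[:, :, 0]
        margin = d2 - d1
        w2 = 0.5 * np.clip(1.0 - margin / spec.mixing_width, 0.0, 0.5 * 2)
        second = order[:, :, 1]
        np.put_along_axis(weights, (labels - 1)[:, :, None], (1.0 - w2)[:, :, None], axis=2)
        np.put_along_axis(weights, second[:, :, None], w2[:, :, None], axis=2)

    clean = weights @ em                                      # R x C x B

    # spatially smooth multiplicative illumination jitter
    illum = rng.standard_normal((spec.rows, spec.cols))
    if spec.smoothness > 0:
        illum = gaussian_filter(illum, spec.smoothness)
        illum /= max(illum.std(), 1e-12)
    illum = 1.0 + spec.jitter * illum
    signal = clean * illum[:, :, None]

    if np.isinf(spec.snr_db):
        noisy = signal
    else:
        p_signal = float(np.mean(signal**2))
        noise_var = p_signal / 10 ** (spec.snr_db / 10.0)
        noisy = signal + rng.normal(0.0, np.sqrt(noise_var), signal.shape)

    cube = HyperCube(noisy.astype(np.float64), interleave="bip")
    return cube, labels.astype(np.int64), em


def make_sr_pairs(
    cube: HyperCube, down_factor: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Degraded/reference spectral-difference pair for SR training.

    ``reference_diff[..., b] = cube[..., b+1] - cube[..., b]``; the input is
    the same first difference of the cube after band-block averaging by
    ``down_factor`` and linear interpolation back to the full band count.
    ``down_factor=1`` is the identity degradation.
    """
    data = np.asarray(cube.data, dtype=float)
    bands = data.shape[2]
    if down_factor < 1:
        raise ValueError("down_factor must be >= 1")
    if bands % down_factor != 0:
        raise ValueError(f"bands ({bands}) not divisible by down_factor ({down_factor})")

    reference_diff = np.diff(data, axis=2)
    if down_factor == 1:
        return reference_diff.copy(), reference_diff
    input_diff = np.diff(degrade_bands(data, down_factor), axis=2)
    return input_diff, reference_diff


def degrade_bands(data: np.ndarray, down_factor: int) -> np.ndarray:
    """Spectral degradation operator: band-block average then linear
    interpolation back to the full band count."""
    data = np.asarray(data, dtype=float)
    bands = data.shape[-1]
    if down_factor == 1:
        return data.copy()
    if bands % down_factor != 0:
        raise ValueError(f"bands ({bands}) not divisible by down_factor ({down_factor})")
    low = data.reshape(*data.shape[:-1], bands // down_factor, down_factor).mean(axis=-1)
    centers = (np.arange(bands // down_factor) + 0.5) * down_factor - 0.5
    full = np.arange(bands, dtype=float)
    flat = low.reshape(-1, low.shape[-1])
    up = np.empty((flat.shape[0], bands))
    for i in range(flat.shape[0]):
        up[i] = np.interp(full, centers, flat[i])
    return up.reshape(*data.shape[:-1], bands)
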