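"""Data preprocessing: PCA spectral reduction, patch and sub-patch extraction.

The classification pipeline cuts one spatial-spectral patch per labelled
pixel from a (usually PCA-reduced) cube, splits patches into train /
validation / test sets stratified by class, and samples kernel-sized
sub-image blocks from the training patches — the clustering units from
which convolution kernels are pre-learned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .hsi_io import HyperCube

__all__ = [
    "PatchSet",
    "SubPatchSet",
    "pca_reduce",
    "extract_patches",
    "extract_subpatches",
]


@dataclass
class PatchSet:
    """Labelled spatial-spectral patches centred on labelled pixels."""

    patches: np.ndarray        # N x s x s x d
    labels: np.ndarray         # N ints, 1..C
    source_coords: np.ndarray  # N x 2 (row, col)
    split: str                 # train / val / test

    def __post_init__(self):
        n = self.patches.shape[0]
        if not (self.labels.shape == (n,) and self.source_coords.shape == (n, 2)):
            raise ValueError("inconsistent PatchSet field lengths")
        if n and self.labels.min() < 1:
            raise ValueError("patch labels must be positive")

    def __len__(self) -> int:
        return self.patches.shape[0]

    @property
    def patch_size(self) -> int:
        return self.patches.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) if len(self) else 0


@dataclass
class SubPatchSet:
    """Kernel-sized blocks sampled inside training patches."""

    blocks: np.ndarray        # M x n x n x d
    parent_index: np.ndarray  # M ints into the parent PatchSet

    def __len__(self) -> int:
        return self.blocks.shape[0]


def pca_reduce(
    cube: HyperCube,
    n_components: int,
    standardize: bool = True,
) -> tuple[HyperCube, float]:
    """Project per-pixel spectra onto the top principal axes.

    The pixel-by-band matrix is mean-centred (and, by default, scaled to
    unit variance per band) before the eigendecomposition.  Returns the
    reduced cube and the cumulative explained-variance ratio.
    """
    bands = cube.bands
    if n_components > bands:
        raise ValueError(f"n_components ({n_components}) > bands ({bands})")
    x = cube.data.reshape(-1, bands).astype(float)
    if standardize:
        std = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(std > 0, std, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    explained = float(np.sum(pca.explained_variance_ratio_))
    reduced = HyperCube(
        scores.reshape(cube.rows, cube.cols, n_components),
        interleave=cube.interleave,
    )
    return reduced, explained


def _stratified_split(
    labels: np.ndarray,
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-class split into 0=train / 1=val / 2=test respecting fractions."""
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("split fractions must sum to 1")
    out = np.zeros(labels.size, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 3:
            warnings.warn(
                f"class {c} has {idx.size} sample(s); kept whole in train",
                stacklevel=3,
            )
            continue
        idx = rng.permutation(idx)
        n_tr = int(round(f_train * idx.size))
        n_va = int(round(f_val * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 2) if f_val and f_test else n_tr
        out[idx[n_tr : n_tr + n_va]] = 1
        out[idx[n_tr + n_va :]] = 2
    return out


def extract_patches(
    cube: HyperCube,
    labels: np.ndarray,
    s: int = 27,
    splits: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[PatchSet, PatchSet, PatchSet]:
    """One s-by-s patch per labelled pixel, mirror-padded at the border,
    split into stratified train/val/test sets."""
    if s % 2 == 0 or s < 1:
        raise ValueError("patch size s must be odd and positive")
    labels = np.asarray(labels)
    if labels.shape != (cube.rows, cube.cols):
        raise ValueError("label map shape does not match cube")
    half = s // 2
    padded = np.pad(cube.data, ((half, half), (half, half), (0, 0)), mode="reflect")
    coords = np.argwhere(labels > 0)
    patches = np.stack(
        [padded[r : r + s, c : c + s, :] for r, c in coords]
    ) if coords.size else np.empty((0, s, s, cube.bands))
    y = labels[coords[:, 0], coords[:, 1]]

    rng = np.random.default_rng(seed)
    split_id = _stratified_split(y, splits, rng)
    sets = []
    for sid, name in enumerate(("train", "val", "test")):
        m = split_id == sid
        sets.append(PatchSet(patches[m], y[m], coords[m], name))
    return tuple(sets)


def extract_subpatches(
    train: PatchSet,
    n: int,
    per_patch: int = 1,
    seed: int = 0,
) -> SubPatchSet:
    """Sample ``per_patch`` uniformly random n-by-n blocks inside each patch."""
    s = train.patch_size
    if n > s:
        raise ValueError(f"sub-patch size {n} exceeds patch size {s}")
    if per_patch < 1:
        raise ValueError("per_patch must be >= 1")
    rng = np.random.default_rng(seed)
    blocks = []
    parents = []
    hi = s - n + 1
    for i in range(len(train)):
        offs = rng.integers(0, hi, size=(per_patch, 2))
        for r, c in offs:
            blocks.append(train.patches[i, r : r + n, c : c + n, :])
            parents.append(i)
    return SubPatchSet(np.stack(blocks), np.asarray(parents))
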