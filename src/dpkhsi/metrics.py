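"""Evaluation measures for classification maps, partitions and restored spectra.

Classification maps are scored with overall accuracy (OA, the trace fraction
of the confusion matrix), average accuracy (AA, the mean per-class recall)
and Cohen's kappa (chance-corrected agreement from the confusion-matrix
marginals).  Cluster partitions are scored with the Rand index

    RI = (a + b) / C(n, 2),

where ``a`` counts pairs placed together in both partitions and ``b`` pairs
separated in both, and with normalised mutual information,
``I(A;B) / sqrt(H(A) H(B))`` with base-2 logarithms.  Restored signals are
scored with PSNR and mean local SSIM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.special import comb

__all__ = [
    "EvalReport",
    "PartitionScores",
    "confusion_matrix",
    "classification_report",
    "rand_index",
    "nmi",
    "psnr",
    "ssim",
    "partition_scores",
]


@dataclass
class EvalReport:
    """Confusion matrix plus the accuracy summary used for map classification."""

    confusion: np.ndarray  # C x C, rows = truth
    oa: float              # percent
    aa: float              # percent
    kappa: float
    per_class_acc: np.ndarray  # percent, per true class

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "oa_percent": self.oa,
            "aa_percent": self.aa,
            "kappa": self.kappa,
            "kappa_x100": 100.0 * self.kappa,
            "per_class_acc_percent": self.per_class_acc.tolist(),
        }

    def format_table(self) -> str:
        """Aligned text block in the OA / AA / Kappa x 100 reporting convention."""
        lines = [f"class {i + 1}: {acc:6.2f}" for i, acc in enumerate(self.per_class_acc)]
        lines.append(f"OA (%)      {self.oa:6.2f}")
        lines.append(f"AA (%)      {self.aa:6.2f}")
        lines.append(f"Kappa × 100 {100.0 * self.kappa:6.2f}")
        return "\n".join(lines)


@dataclass
class PartitionScores:
    rand_index: float
    nmi: float


def confusion_matrix(truth: np.ndarray, pred: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.size == 0:
        raise ValueError("empty label arrays")
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have the same length")
    if truth.min() < 1 or pred.min() < 1:
        raise ValueError("labels must be in 1..C (0 is reserved for background)")
    C = int(n_classes or max(truth.max(), pred.max()))
    cm = np.zeros((C, C), dtype=np.int64)
    np.add.at(cm, (truth - 1, pred - 1), 1)
    return cm


def classification_report(truth: np.ndarray, pred: np.ndarray, n_classes: int | None = None) -> EvalReport:
    """OA/AA/kappa report from per-pixel truth and prediction labels (1..C)."""
    cm = confusion_matrix(truth, pred, n_classes)
    total = cm.sum()
    oa = 100.0 * np.trace(cm) / total
    row_sums = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recalls = np.where(row_sums > 0, np.diag(cm) / np.maximum(row_sums, 1), np.nan)
    per_class = 100.0 * recalls
    aa = float(np.nanmean(per_class))
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1))) / total**2
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return EvalReport(cm, float(oa), aa, float(kappa), per_class)


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def rand_index(a_labels: np.ndarray, b_labels: np.ndarray) -> float:
    """Fraction of point pairs on which two partitions agree (same/different)."""
    a = np.asarray(a_labels).ravel()
    b = np.asarray(b_labels).ravel()
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 points")
    t = _contingency(a, b)
    # pair counts from the contingency table
    same_both = comb(t, 2).sum()
    same_a = comb(t.sum(axis=1), 2).sum()
    same_b = comb(t.sum(axis=0), 2).sum()
    total = comb(n, 2)
    diff_both = total - same_a - same_b + same_both
    return float((same_both + diff_both) / total)


def nmi(a_labels: np.ndarray, b_labels: np.ndarray) -> float:
    """Mutual information normalised by sqrt(H(A) H(B)), base-2 logs.

    Degenerate single-cluster sides give 0 by convention.
    """
    a = np.asarray(a_labels).ravel()
    b = np.asarray(b_labels).ravel()
    if a.size == 0:
        raise ValueError("empty label arrays")
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    t = _contingency(a, b).astype(float)
    n = t.sum()
    p_ab = t / n
    p_a = p_ab.sum(axis=1)
    p_b = p_ab.sum(axis=0)
    h_a = -np.sum(p_a[p_a > 0] * np.log2(p_a[p_a > 0]))
    h_b = -np.sum(p_b[p_b > 0] * np.log2(p_b[p_b > 0]))
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    outer = np.outer(p_a, p_b)
    nz = p_ab > 0
    mi = np.sum(p_ab[nz] * np.log2(p_ab[nz] / outer[nz]))
    return float(mi / np.sqrt(h_a * h_b))


def partition_scores(a_labels: np.ndarray, b_labels: np.ndarray) -> PartitionScores:
    return PartitionScores(rand_index(a_labels, b_labels), nmi(a_labels, b_labels))


def psnr(x: np.ndarray, ref: np.ndarray, peak: float = 1.0) -> float:
    """10 log10(peak^2 / MSE) in dB; identical inputs give +inf."""
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    mse = float(np.mean((x - ref) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def ssim(
    x: np.ndarray,
    ref: np.ndarray,
    window: int = 7,
    data_range: float | None = None,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Mean local structural similarity over a sliding uniform window.

    Local means/variances/covariance are computed with a ``window``-sided
    uniform filter; the two stabilising constants are ``(k1*L)^2`` and
    ``(k2*L)^2`` with ``L`` the data range.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {ref.shape}")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if window > min(x.shape):
        raise ValueError(f"window {window} exceeds smallest dimension {min(x.shape)}")
    if data_range is None:
        lo = min(x.min(), ref.min())
        hi = max(x.max(), ref.max())
        data_range = hi - lo if hi > lo else 1.0
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    mu_x = uniform_filter(x, size=window)
    mu_y = uniform_filter(ref, size=window)
    var_x = uniform_filter(x * x, size=window) - mu_x**2
    var_y = uniform_filter(ref * ref, size=window) - mu_y**2
    cov = uniform_filter(x * ref, size=window) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    # crop the filter's edge effects: keep fully-valid centre
    pad = window // 2
    ssim_map = num / den
    core = tuple(slice(pad, s - pad) for s in x.shape)
    if all(sl.stop > sl.start for sl in core):
        ssim_map = ssim_map[core]
    return float(ssim_map.mean())
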