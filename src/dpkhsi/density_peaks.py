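"""Density-peaks clustering (CFSFDP) and the adaptive kernel-count rule (MCFSFDP).

CFSFDP ("clustering by fast search and find of density peaks") characterises
every point by two quantities computed from the pairwise distance matrix:

* local density ``rho[i]`` — under the hard-cutoff indicator kernel, the
  number of points strictly closer than the cutoff distance ``d_c``;
* separation ``delta[i]`` — the minimum distance from ``i`` to any point of
  higher density; the globally densest point instead takes its maximum
  distance to any other point.

Cluster centers are the joint outliers of the ``(rho, delta)`` decision
graph; the product ``gamma = rho * delta`` ranks candidates when the graph
is not visually separable.  Non-center points are assigned, in order of
decreasing density, to the cluster of their nearest higher-density
neighbour.

MCFSFDP replaces the two-threshold center criterion by a sweep of a single
distance threshold ``delta_v``: ``num(delta_v)`` counts points whose delta
exceeds the threshold, its finite-difference slope ``con_v`` and the
consecutive-slope ratio ``quo_v`` locate the plateau of the ``num`` curve,
and the plateau value is the decided number of cluster centers — hence the
number of convolution kernels for the pre-learned-kernel CNN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DecisionGraph",
    "ClusterResult",
    "ThresholdSweep",
    "pairwise_distances",
    "local_density",
    "choose_dc",
    "delta_distance",
    "compute_decision_graph",
    "select_centers",
    "assign_clusters",
    "mcfsfdp_num_kernels",
    "count_decision_outliers",
    "cluster",
]

DEFAULT_DC_FRACTION = 0.02  # target mean neighbour fraction for d_c


@dataclass
class DecisionGraph:
    """Per-point (rho, delta, gamma) triples plus the cutoff used."""

    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray = field(init=False)
    d_c: float = 0.0
    distance_metric: str = "euclidean"

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.gamma = self.rho * self.delta

    def __len__(self) -> int:
        return self.rho.size

    def to_csv(self, path) -> None:
        rows = np.column_stack([np.arange(len(self)), self.rho, self.delta, self.gamma])
        np.savetxt(path, rows, delimiter=",", header="point,rho,delta,gamma",
                   comments="", fmt=["%d", "%.10g", "%.10g", "%.10g"])


@dataclass
class ClusterResult:
    centers: np.ndarray      # indices of center points
    assignment: np.ndarray   # N ints, cluster id = position in `centers`
    num_centers: int
    threshold_used: float | None = None


@dataclass
class ThresholdSweep:
    """num/con/quo curves of the MCFSFDP distance-threshold sweep."""

    deltas_v: np.ndarray  # sorted candidate thresholds
    num_v: np.ndarray     # centers surviving each threshold
    con_v: np.ndarray     # finite-difference slope, length len(deltas_v)-1
    quo_v: np.ndarray     # |con_v / con_{v+1}|, length len(con_v)-1
    selected: int         # index into deltas_v (plateau midpoint)
    num_centers: int
    threshold: float      # delta_A, the selected distance threshold

    def to_csv(self, path) -> None:
        n = self.deltas_v.size
        con = np.concatenate([self.con_v, [np.nan]])
        quo = np.concatenate([self.quo_v, [np.nan, np.nan]])
        rows = np.column_stack([self.deltas_v, self.num_v, con[:n], quo[:n]])
        np.savetxt(path, rows, delimiter=",", header="delta_v,num_v,con_v,quo_v",
                   comments="", fmt="%.10g")


# --------------------------------------------------------------------------
# rho / d_c / delta

def pairwise_distances(points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return squareform(pdist(points, metric="euclidean"))


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return D


def local_density(D: np.ndarray, d_c: float, kernel: str = "indicator") -> np.ndarray:
    """Local density of each point.

    ``indicator`` (default): integer count of points strictly within ``d_c``.
    ``gaussian``: the classic soft variant ``sum exp(-(d/d_c)^2)``, offered
    behind this flag.
    """
    D = _check_distance_matrix(D)
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    off = ~np.eye(D.shape[0], dtype=bool)
    if kernel == "indicator":
        return ((D < d_c) & off).sum(axis=1).astype(float)
    if kernel == "gaussian":
        return (np.exp(-((D / d_c) ** 2)) * off).sum(axis=1)
    raise ValueError(f"unknown density kernel {kernel!r}")


def choose_dc(D: np.ndarray, target_fraction: float = DEFAULT_DC_FRACTION) -> float:
    """Smallest cutoff so the mean neighbour count reaches the target fraction.

    Returns the smallest ``d_c`` with
    ``mean_i #{j != i : d_ij < d_c} >= target_fraction * (N - 1)``.
    """
    D = _check_distance_matrix(D)
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    offdiag = D[~np.eye(n, dtype=bool)]
    unique = np.unique(offdiag)
    if unique.size == 1:
        warnings.warn("all pairwise distances equal; d_c degenerate", stacklevel=2)
        return float(unique[0])
    target_pairs = target_fraction * (n - 1) * n  # sum over i of counts
    # counts with d_c just above unique[j] include all distances <= unique[j]
    cum = np.searchsorted(np.sort(offdiag), unique, side="right")
    j = int(np.searchsorted(cum, target_pairs, side="left"))
    j = min(j, unique.size - 1)
    return float(np.nextafter(unique[j], np.inf))


def _density_order(rho: np.ndarray) -> np.ndarray:
    """Indices sorted by decreasing density; ties broken by lower index first
    (a lower index counts as denser)."""
    n = rho.size
    return np.lexsort((np.arange(n), -np.asarray(rho)))


def delta_distance(D: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separation ``delta`` and nearest-denser-neighbour index for each point.

    ``delta[i]`` is the minimum distance to any point of strictly higher
    density (ties broken by point index); the globally densest point takes
    the maximum distance to any other point and its own index as neighbour.
    """
    D = _check_distance_matrix(D)
    rho = np.asarray(rho, dtype=float)
    n = rho.size
    delta = np.zeros(n)
    nneigh = np.arange(n)
    if n == 1:
        return delta, nneigh
    order = _density_order(rho)
    top = order[0]
    delta[top] = D[top].max()
    for pos in range(1, n):
        i = order[pos]
        denser = order[:pos]
        k = np.argmin(D[i, denser])
        nneigh[i] = denser[k]
        delta[i] = D[i, denser[k]]
    return delta, nneigh


def compute_decision_graph(
    points: np.ndarray | None = None,
    D: np.ndarray | None = None,
    d_c: float | str = "auto",
    dc_fraction: float = DEFAULT_DC_FRACTION,
    kernel: str = "indicator",
) -> tuple[DecisionGraph, np.ndarray, np.ndarray]:
    """Full decision graph from points or a distance matrix.

    Returns ``(graph, D, nneigh)`` so downstream assignment can reuse the
    distance matrix and nearest-denser-neighbour links.
    """
    if D is None:
        if points is None:
            raise ValueError("provide points or a distance matrix")
        D = pairwise_distances(points)
    D = _check_distance_matrix(D)
    if d_c == "auto":
        n = D.shape[0]
        # small-sample floor: keep the mean neighbour count >= 2 so the
        # indicator density stays informative on tiny point sets
        frac = min(max(dc_fraction, 2.0 / max(n - 1, 1)), 0.99)
        d_c = choose_dc(D, frac)
    rho = local_density(D, float(d_c), kernel=kernel)
    delta, nneigh = delta_distance(D, rho)
    return DecisionGraph(rho, delta, d_c=float(d_c)), D, nneigh


# --------------------------------------------------------------------------
# center selection and assignment

def assign_clusters(
    dg: DecisionGraph,
    nneigh: np.ndarray,
    centers: np.ndarray,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """Propagate labels in decreasing-density order along nearest-denser links.

    A chain root (a densest point that is not itself a center) falls back to
    the cluster of its nearest center, which needs the distance matrix ``D``.
    """
    n = len(dg)
    centers = np.asarray(centers, dtype=int)
    if centers.size == 0:
        raise ValueError("no centers to assign from")
    assignment = np.full(n, -1, dtype=int)
    for cid, c in enumerate(centers):
        assignment[c] = cid
    for i in _density_order(dg.rho):
        if assignment[i] < 0:
            a = assignment[nneigh[i]]
            if a < 0:
                if D is None:
                    raise ValueError(
                        "densest point is not a center; pass D for fallback assignment"
                    )
                a = int(np.argmin(D[i, centers]))
            assignment[i] = a
    return assignment


def select_centers(
    dg: DecisionGraph,
    nneigh: np.ndarray,
    k: int | None = None,
    rho_min: float | None = None,
    delta_min: float | None = None,
    D: np.ndarray | None = None,
) -> ClusterResult:
    """Pick cluster centers by top-k gamma or by (rho, delta) thresholds.

    Exactly one mode applies: pass ``k`` for the gamma ranking (ties broken
    by index), or ``rho_min`` and ``delta_min`` for the joint-threshold rule.
    """
    n = len(dg)
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        order = np.lexsort((np.arange(n), -dg.gamma))
        centers = np.sort(order[:k])
        threshold = None
    else:
        if rho_min is None or delta_min is None:
            raise ValueError("pass k, or both rho_min and delta_min")
        centers = np.flatnonzero((dg.rho > rho_min) & (dg.delta > delta_min))
        if centers.size == 0:
            raise ValueError("no point exceeds both thresholds")
        threshold = float(delta_min)
    assignment = assign_clusters(dg, nneigh, centers, D=D)
    return ClusterResult(centers, assignment, int(centers.size), threshold)


def count_decision_outliers(dg: DecisionGraph) -> int:
    """Number of joint (rho, delta) outliers via the largest gamma gap.

    Sorts gamma in decreasing order and splits at the largest ratio between
    consecutive values over the top half of the ranking; the split position
    is the outlier count (the decision-graph points that stand apart).
    """
    g = np.sort(dg.gamma)[::-1]
    n = g.size
    if n < 3:
        return n
    eps = max(g[0], 1.0) * 1e-12
    upper = max(2, n // 2)
    ratios = (g[:upper] + eps) / (g[1 : upper + 1] + eps)
    return int(np.argmax(ratios)) + 1


# --------------------------------------------------------------------------
# MCFSFDP threshold sweep

def _default_candidates(delta: np.ndarray, steps: int = 50) -> np.ndarray:
    """Candidate thresholds spanning 5%-95% of the delta range (0, max delta)."""
    dmax = float(np.max(delta))
    if dmax <= 0:
        raise ValueError("degenerate deltas: all zero")
    return np.linspace(0.05 * dmax, 0.95 * dmax, steps)


def mcfsfdp_num_kernels(
    dg: DecisionGraph,
    candidate_deltas: np.ndarray | None = None,
    plateau_rule: str = "first_wide",
    min_width_fraction: float = 0.5,
) -> ThresholdSweep:
    """Sweep a distance threshold and decide the number of cluster centers.

    For each candidate threshold ``delta_v``, ``num_v`` counts the points
    whose separation exceeds it (the distance-only center criterion).  The
    slope ``con_v`` and slope ratio ``quo_v`` of the num curve expose its
    plateaus; the decided center count is the num value on the selected
    plateau and ``threshold`` (delta_A) is the plateau midpoint.

    ``plateau_rule``:
      * ``first_wide`` (default) — among maximal zero-slope runs, take the
        first whose width is at least ``min_width_fraction`` of the widest.
      * ``widest`` — take the widest zero-slope run outright.

    Falls back to the largest-gamma-gap count (with a warning) when the num
    curve has no plateau over the candidates.
    """
    if candidate_deltas is None:
        candidate_deltas = _default_candidates(dg.delta)
    deltas_v = np.sort(np.asarray(candidate_deltas, dtype=float))
    if deltas_v.size < 3:
        raise ValueError("need at least 3 candidate thresholds")

    num_v = (dg.delta[None, :] > deltas_v[:, None]).sum(axis=1)
    widths = np.diff(deltas_v)
    con_v = np.diff(num_v) / widths
    with np.errstate(divide="ignore", invalid="ignore"):
        quo_v = np.abs(con_v[:-1] / con_v[1:])
    quo_v[np.isnan(quo_v)] = 1.0  # 0/0 -> 1: flat stays flat

    # Maximal runs of zero slope.  Run width is measured on the log-delta
    # scale: separations of true centers spread multiplicatively (they sit at
    # inter-cluster distances), so gaps between consecutive center deltas can
    # be wide in absolute delta yet narrow relatively, while the plateau at
    # the true count spans a large delta *ratio*.
    runs: list[tuple[int, int, float]] = []  # (start slot, stop slot, log-width)
    log_d = np.log(np.maximum(deltas_v, np.finfo(float).tiny))
    v = 0
    while v < con_v.size:
        if con_v[v] == 0:
            start = v
            while v < con_v.size and con_v[v] == 0:
                v += 1
            runs.append((start, v - 1, float(log_d[v] - log_d[start])))
        else:
            v += 1

    if not runs:
        warnings.warn(
            "num(delta) strictly decreasing over candidates; "
            "falling back to the gamma-gap center count",
            stacklevel=2,
        )
        k = count_decision_outliers(dg)
        sel = int(np.argmin(np.abs(num_v - k)))
        return ThresholdSweep(deltas_v, num_v, con_v, quo_v, sel, int(k),
                              float(deltas_v[sel]))

    max_width = max(r[2] for r in runs)
    if plateau_rule == "widest":
        start, stop, _ = max(runs, key=lambda r: r[2])
    elif plateau_rule == "first_wide":
        start, stop, _ = next(r for r in runs if r[2] >= min_width_fraction * max_width)
    else:
        raise ValueError(f"unknown plateau_rule {plateau_rule!r}")

    sel = (start + stop + 1) // 2  # midpoint slot of the plateau
    return ThresholdSweep(
        deltas_v, num_v, con_v, quo_v, int(sel), int(num_v[sel]), float(deltas_v[sel])
    )


# --------------------------------------------------------------------------
# convenience front end

def cluster(
    points: np.ndarray,
    mode: str = "mcfsfdp",
    k: int | None = None,
    d_c: float | str = "auto",
    dc_fraction: float = DEFAULT_DC_FRACTION,
    **sweep_kwargs,
) -> tuple[ClusterResult, DecisionGraph, ThresholdSweep | None]:
    """One-call clustering of a point set.

    ``mode='mcfsfdp'`` decides the center count by the threshold sweep;
    ``mode='gamma_topk'`` uses the supplied ``k``.
    """
    dg, D, nneigh = compute_decision_graph(points=points, d_c=d_c, dc_fraction=dc_fraction)
    sweep = None
    if mode == "mcfsfdp":
        sweep = mcfsfdp_num_kernels(dg, **sweep_kwargs)
        k = sweep.num_centers
    elif mode != "gamma_topk":
        raise ValueError(f"unknown mode {mode!r}")
    if k is None:
        raise ValueError("gamma_topk mode needs k")
    result = select_centers(dg, nneigh, k=k, D=D)
    if sweep is not None:
        result.threshold_used = sweep.threshold
    return result, dg, sweep
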