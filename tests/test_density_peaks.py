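"""Density-peaks clustering against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpkhsi import make_blobs
from dpkhsi.density_peaks import (
    DecisionGraph,
    assign_clusters,
    choose_dc,
    cluster,
    compute_decision_graph,
    count_decision_outliers,
    delta_distance,
    local_density,
    mcfsfdp_num_kernels,
    pairwise_distances,
    select_centers,
)
from dpkhsi.metrics import rand_index


# --------------------------------------------------------------------------
# independent O(N^2) oracle: explicit double loops, same tie convention
# (a lower index counts as denser on exact density ties)

def brute_force_cfsfdp(D, d_c):
    n = D.shape[0]
    rho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and D[i, j] - d_c < 0:
                rho[i] += 1
    delta = np.zeros(n)
    for i in range(n):
        best = np.inf
        for j in range(n):
            denser = rho[j] > rho[i] or (rho[j] == rho[i] and j < i)
            if denser and D[i, j] < best:
                best = D[i, j]
        if np.isinf(best):  # the globally densest point
            best = max(D[i, j] for j in range(n)) if n > 1 else 0.0
        delta[i] = best
    return rho, delta, rho * delta


class TestLocalDensity:
    def test_isolated_points(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert np.array_equal(local_density(D, 1.0), [0, 0])

    def test_three_collinear_points(self):
        D = pairwise_distances(np.array([[0.0, 0], [1, 0], [2, 0]]))
        assert np.array_equal(local_density(D, 1.5), [1, 2, 1])

    def test_rho_sum_counts_pairs_twice(self, rng):
        pts = rng.standard_normal((40, 2))
        D = pairwise_distances(pts)
        d_c = 0.8
        pairs = sum(
            1
            for i in range(40)
            for j in range(i + 1, 40)
            if np.linalg.norm(pts[i] - pts[j]) < d_c
        )
        assert local_density(D, d_c).sum() == 2 * pairs

    def test_cutoff_is_strict(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert np.array_equal(local_density(D, 1.0), [0, 0])
        assert np.array_equal(local_density(D, 1.0 + 1e-9), [1, 1])

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            local_density(D, 1.0)

    def test_gaussian_kernel_variant(self):
        D = pairwise_distances(np.array([[0.0, 0], [1, 0], [2, 0]]))
        rho = local_density(D, 1.0, kernel="gaussian")
        expected = np.array(
            [np.exp(-1) + np.exp(-4), 2 * np.exp(-1), np.exp(-1) + np.exp(-4)]
        )
        np.testing.assert_allclose(rho, expected)


class TestChooseDc:
    def test_saturation_at_high_target(self, rng):
        D = pairwise_distances(rng.standard_normal((20, 2)))
        d_c = choose_dc(D, 0.999)
        assert d_c >= D.max()

    def test_equally_spaced_grid(self):
        # unit-step 1-D grid: interior points have 2 unit-distance
        # neighbours but endpoints only 1, so a mean of 2 needs the cutoff
        # just above two grid steps
        pts = np.arange(10, dtype=float)[:, None]
        D = pairwise_distances(pts)
        d_c = choose_dc(D, 2.0 / 9.0)
        assert 2.0 < d_c < 2.0 + 1e-9
        d_c_lo = choose_dc(D, 1.5 / 9.0)
        assert 1.0 < d_c_lo < 1.0 + 1e-9

    def test_mean_neighbour_contract(self, rng):
        """Smallest cutoff whose mean neighbour count reaches the target."""
        D = pairwise_distances(rng.standard_normal((30, 2)))
        t = 0.1
        d_c = choose_dc(D, t)
        count = ((D < d_c).sum() - 30) / 30
        assert count >= t * 29
        smaller = np.nextafter(d_c, 0)
        prev = np.unique(D[D < smaller])
        if prev.size > 1:
            count_prev = ((D < prev[-1]).sum() - 30) / 30
            assert count_prev < t * 29

    def test_degenerate_equal_distances_warns(self):
        D = np.array([[0.0, 2, 2], [2, 0, 2], [2, 2, 0]])
        with pytest.warns(UserWarning, match="degenerate"):
            assert choose_dc(D, 0.5) == 2.0


class TestDeltaDistance:
    def test_singleton(self):
        delta, nneigh = delta_distance(np.zeros((1, 1)), np.zeros(1))
        assert delta[0] == 0.0 and nneigh[0] == 0

    def test_two_far_blobs_maxima_take_largest_deltas(self):
        bs = make_blobs(60, 2, 10.0, seed=0)
        dg, D, _ = compute_decision_graph(points=bs.points)
        top2 = np.argsort(dg.delta)[-2:]
        # the two blob density maxima own the two largest deltas
        dense_labels = {bs.true_labels[i] for i in top2}
        assert dense_labels == {1, 2}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((50, 2))
        D = pairwise_distances(pts)
        d_c = choose_dc(D, 0.1)
        rho = local_density(D, d_c)
        delta, _ = delta_distance(D, rho)
        b_rho, b_delta, b_gamma = brute_force_cfsfdp(D, d_c)
        np.testing.assert_array_equal(rho, b_rho)
        np.testing.assert_allclose(delta, b_delta)
        np.testing.assert_allclose(rho * delta, b_gamma)


class TestSelectCenters:
    def test_k_equals_n(self):
        pts = np.random.default_rng(0).standard_normal((6, 2))
        dg, D, nn = compute_decision_graph(points=pts, d_c=1.0)
        res = select_centers(dg, nn, k=6, D=D)
        assert res.num_centers == 6
        assert np.array_equal(np.sort(res.assignment), np.arange(6))

    def test_two_blob_assignment_matches_truth(self):
        bs = make_blobs(80, 2, 10.0, seed=3)
        dg, D, nn = compute_decision_graph(points=bs.points)
        res = select_centers(dg, nn, k=2, D=D)
        assert rand_index(res.assignment, bs.true_labels) == 1.0

    def test_centers_self_assigned_and_propagation_consistent(self):
        bs = make_blobs(90, 3, 9.0, seed=5)
        dg, D, nn = compute_decision_graph(points=bs.points)
        res = select_centers(dg, nn, k=3, D=D)
        for cid, c in enumerate(res.centers):
            assert res.assignment[c] == cid
        # every non-center shares its nearest-denser neighbour's cluster
        for i in range(len(dg)):
            if i not in res.centers:
                assert res.assignment[i] == res.assignment[nn[i]]

    def test_threshold_mode(self):
        bs = make_blobs(60, 2, 10.0, seed=1)
        dg, D, nn = compute_decision_graph(points=bs.points)
        rho_min = np.median(dg.rho)
        delta_min = 0.5 * dg.delta.max()
        res = select_centers(dg, nn, rho_min=rho_min, delta_min=delta_min, D=D)
        assert res.num_centers == 2

    def test_k_out_of_range(self):
        dg, D, nn = compute_decision_graph(points=np.eye(3), d_c=1.0)
        with pytest.raises(ValueError):
            select_centers(dg, nn, k=4, D=D)

    def test_fig4_style_set_has_two_decision_outliers(self):
        """A 21-point two-cluster set shows exactly 2 (rho, delta) outliers."""
        bs = make_blobs(21, 2, 8.0, seed=4)
        dg, _, _ = compute_decision_graph(points=bs.points)
        assert count_decision_outliers(dg) == 2


class TestThresholdSweep:
    def test_degenerate_equal_deltas(self):
        dg = DecisionGraph(rho=np.ones(5), delta=np.full(5, 2.0))
        sweep = mcfsfdp_num_kernels(dg, candidate_deltas=[0.5, 1.0, 1.5, 2.5])
        assert np.array_equal(sweep.num_v, [5, 5, 5, 0])
        assert sweep.num_centers == 5

    def test_sweep_curves_match_brute_force(self):
        bs = make_blobs(60, 2, 8.0, seed=2)
        dg, _, _ = compute_decision_graph(points=bs.points)
        cand = np.linspace(0.05 * dg.delta.max(), 0.95 * dg.delta.max(), 40)
        sweep = mcfsfdp_num_kernels(dg, candidate_deltas=cand)
        for v, dv in enumerate(cand):
            assert sweep.num_v[v] == sum(1 for d in dg.delta if d > dv)
        np.testing.assert_allclose(
            sweep.con_v, np.diff(sweep.num_v) / np.diff(cand)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            expected_quo = np.abs(sweep.con_v[:-1] / sweep.con_v[1:])
        expected_quo[np.isnan(expected_quo)] = 1.0
        np.testing.assert_allclose(sweep.quo_v, expected_quo)

    def test_two_blob_plateau_is_two_over_wide_range(self):
        bs = make_blobs(80, 2, 8.0, seed=6)
        dg, _, _ = compute_decision_graph(points=bs.points)
        sweep = mcfsfdp_num_kernels(dg)
        assert sweep.num_centers == 2

    def test_num_v_non_increasing(self, rng):
        for _ in range(10):
            pts = rng.standard_normal((30, 2))
            dg, _, _ = compute_decision_graph(points=pts)
            sweep = mcfsfdp_num_kernels(dg)
            assert np.all(np.diff(sweep.num_v) <= 0)

    def test_invariant_lengths(self):
        bs = make_blobs(40, 2, 8.0, seed=7)
        dg, _, _ = compute_decision_graph(points=bs.points)
        sweep = mcfsfdp_num_kernels(dg)
        assert sweep.con_v.size == sweep.deltas_v.size - 1
        assert sweep.quo_v.size == sweep.con_v.size - 1

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_blob_center_count_recovery(self, k):
        hits = 0
        for seed in range(20):
            bs = make_blobs(30 * k, k, 8.0, seed=1000 * k + seed)
            res, _, _ = cluster(bs.points)
            hits += res.num_centers == k
        assert hits >= 19


class TestEquivalenceAndProperties:
    @pytest.mark.parametrize("seed,n", [(0, 20), (1, 57), (2, 113), (3, 200)])
    def test_full_equivalence_with_oracle(self, seed, n):
        """rho/delta/gamma and top-k centers equal the O(N^2) brute force."""
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n, 3)) * rng.uniform(0.5, 2.0)
        D = pairwise_distances(pts)
        d_c = choose_dc(D, 0.05)
        rho = local_density(D, d_c)
        delta, nn = delta_distance(D, rho)
        b_rho, b_delta, b_gamma = brute_force_cfsfdp(D, d_c)
        np.testing.assert_array_equal(rho, b_rho)
        np.testing.assert_allclose(delta, b_delta)
        gamma = rho * delta
        k = 4
        ours = set(np.argsort(-gamma, kind="stable")[:k])
        theirs = set(np.argsort(-b_gamma, kind="stable")[:k])
        assert ours == theirs

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_rho_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((25, 2))
        perm = rng.permutation(25)
        D = pairwise_distances(pts)
        Dp = pairwise_distances(pts[perm])
        rho = local_density(D, 0.7)
        rho_p = local_density(Dp, 0.7)
        np.testing.assert_array_equal(rho[perm], rho_p)

    def test_gamma_ranks_true_modes_first(self):
        """With 8-sigma separation the k modes outrank all other points."""
        for k in (2, 3, 4):
            bs = make_blobs(50 * k, k, 8.0, seed=k)
            dg, _, _ = compute_decision_graph(points=bs.points)
            top = np.argsort(-dg.gamma, kind="stable")[:k]
            assert {bs.true_labels[i] for i in top} == set(range(1, k + 1))
            assert dg.gamma[top].min() > np.sort(dg.gamma)[-(k + 1)]

    def test_assignment_root_fallback_uses_distance(self):
        dg, D, nn = compute_decision_graph(
            points=np.array([[0.0, 0], [0.1, 0], [5, 0], [5.1, 0]]), d_c=0.5
        )
        # force centers that exclude the densest point
        centers = np.array([2])
        a = assign_clusters(dg, nn, centers, D=D)
        assert np.all(a == 0)
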