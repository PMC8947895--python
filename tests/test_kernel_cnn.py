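"""Pre-learned-kernel CNN: kernel bank, conv/pool primitives, frozen training."""

import numpy as np
import pytest

from dpkhsi import (
    KernelBank,
    PreLearnedCNN,
    SceneSpec,
    TrainConfig,
    centers_to_kernels,
    conv_forward,
    extract_patches,
    extract_subpatches,
    make_scene,
    max_pool,
    pca_reduce,
    predict,
    train_classifier,
)
from dpkhsi import cluster as dp_cluster
from dpkhsi.density_peaks import ClusterResult
from dpkhsi.kernel_cnn import load_model, random_kernels, save_model
from dpkhsi.preprocess import SubPatchSet


def toy_subpatches(rng, m=6, n=3, d=2):
    return SubPatchSet(rng.standard_normal((m, n, n, d)), np.zeros(m, dtype=int))


class TestKernelBank:
    def test_counting_and_shapes(self, rng):
        sub = toy_subpatches(rng)
        result = ClusterResult(np.array([1, 4]), np.zeros(6, dtype=int), 2)
        bank = centers_to_kernels(sub, result)
        assert bank.K == 2 and bank.kernels.shape == (2, 3, 3, 2)

    def test_unnormalised_kernels_equal_center_blocks(self, rng):
        sub = toy_subpatches(rng)
        result = ClusterResult(np.array([0, 5]), np.zeros(6, dtype=int), 2)
        bank = centers_to_kernels(sub, result, normalisation="none")
        np.testing.assert_array_equal(bank.kernels, sub.blocks[[0, 5]])

    def test_zero_mean_unit_norm_contract(self, rng):
        sub = toy_subpatches(rng, m=4)
        result = ClusterResult(np.arange(4), np.zeros(4, dtype=int), 4)
        bank = centers_to_kernels(sub, result)
        means = bank.kernels.mean(axis=(1, 2, 3))
        norms = np.sqrt((bank.kernels**2).sum(axis=(1, 2, 3)))
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_constant_block_rejected(self, rng):
        sub = toy_subpatches(rng)
        sub.blocks[2] = 1.0
        result = ClusterResult(np.array([2]), np.zeros(6, dtype=int), 1)
        with pytest.raises(ValueError, match="constant"):
            centers_to_kernels(sub, result)

    def test_empty_centers_rejected(self, rng):
        sub = toy_subpatches(rng)
        result = ClusterResult(np.array([], dtype=int), np.zeros(6, dtype=int), 0)
        with pytest.raises(ValueError, match="no centers"):
            centers_to_kernels(sub, result)


class TestConvForward:
    def test_identity_1x1_kernel(self, rng):
        patch = rng.standard_normal((5, 5, 1))
        bank = KernelBank(np.ones((1, 1, 1, 1)), normalisation="none")
        out = conv_forward(patch, bank, activation="relu")
        np.testing.assert_allclose(out[:, :, 0], np.maximum(patch[:, :, 0], 0))

    def test_output_side_s_minus_n_plus_1(self, rng):
        patch = rng.standard_normal((27, 27, 4))
        bank = KernelBank(rng.standard_normal((3, 5, 5, 4)), normalisation="none")
        out = conv_forward(patch, bank, activation="identity")
        assert out.shape == (23, 23, 3)

    def test_linearity_and_quadruple_loop_oracle(self, rng):
        patch_x = rng.standard_normal((6, 6, 2))
        patch_y = rng.standard_normal((6, 6, 2))
        bank = KernelBank(rng.standard_normal((2, 3, 3, 2)), normalisation="none")
        fx = conv_forward(patch_x, bank, activation="identity")
        fy = conv_forward(patch_y, bank, activation="identity")
        combo = conv_forward(2.0 * patch_x - 0.5 * patch_y, bank, "identity")
        np.testing.assert_allclose(combo, 2.0 * fx - 0.5 * fy, atol=1e-10)
        # explicit quadruple-loop correlation oracle
        expect = np.zeros((4, 4, 2))
        for k in range(2):
            for i in range(4):
                for j in range(4):
                    acc = 0.0
                    for a in range(3):
                        for b in range(3):
                            for c in range(2):
                                acc += bank.kernels[k, a, b, c] * patch_x[i + a, j + b, c]
                    expect[i, j, k] = acc
        np.testing.assert_allclose(fx, expect, atol=1e-10)

    def test_channel_mismatch(self, rng):
        bank = KernelBank(rng.standard_normal((1, 3, 3, 4)), normalisation="none")
        with pytest.raises(ValueError, match="channel"):
            conv_forward(rng.standard_normal((5, 5, 3)), bank)


class TestMaxPool:
    def test_global_pooling(self, rng):
        fmap = rng.standard_normal((6, 6))
        assert max_pool(fmap, 6) == fmap.max()

    def test_hand_evaluated_2x2(self):
        assert max_pool(np.array([[1.0, 2.0], [3.0, 4.0]]), 2) == 4.0

    def test_dominates_mean_pooling(self, rng):
        for _ in range(100):
            fmap = rng.standard_normal((8, 8))
            pooled = max_pool(fmap, 2)
            mean_pooled = fmap.reshape(4, 2, 4, 2).mean(axis=(1, 3))
            assert np.all(pooled >= mean_pooled)

    def test_remainder_padded_with_neg_inf(self):
        fmap = np.arange(9.0).reshape(3, 3)
        out = max_pool(fmap, 2)
        np.testing.assert_array_equal(out, [[4.0, 5.0], [7.0, 8.0]])

    def test_invalid_pool_size(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros((4, 4)), 0)


@pytest.fixture(scope="module")
def trained_scene_net():
    spec = SceneSpec(rows=24, cols=24, n_classes=3, n_bands=16, snr_db=30.0, seed=2)
    cube, labels, _ = make_scene(spec)
    reduced, _ = pca_reduce(cube, 6)
    tr, va, te = extract_patches(reduced, labels, s=5, seed=0)
    sub = extract_subpatches(tr, 3, 1, seed=0)
    result, _, _ = dp_cluster(sub.blocks.reshape(len(sub), -1))
    bank = centers_to_kernels(sub, result)
    net = PreLearnedCNN(bank, classes=3)
    train_classifier(net, tr, va, TrainConfig(epochs=40, seed=0))
    return net, tr, va, te


class TestTraining:
    def test_frozen_kernels_unchanged_by_training(self, trained_scene_net):
        net, tr, va, _ = trained_scene_net
        before = net.bank.checksum()
        train_classifier(net, tr, va, TrainConfig(epochs=10, seed=1))
        assert net.bank.checksum() == before

    def test_separable_features_reach_high_training_accuracy(self, rng):
        # two classes with disjoint activation patterns are fit exactly
        from dpkhsi.preprocess import PatchSet

        n = 40
        patches = np.zeros((n, 4, 4, 1))
        labels = np.array([1, 2] * (n // 2))
        patches[labels == 1, :2, :2, 0] = 1.0
        patches[labels == 2, 2:, 2:, 0] = 1.0
        coords = np.zeros((n, 2), dtype=int)
        train = PatchSet(patches, labels, coords, "train")
        bank = random_kernels(3, 2, 1, seed=0)
        net = PreLearnedCNN(bank, classes=2)
        # tiny data set: one batch per epoch, so disable early stopping and
        # raise the learning rate to converge within the epoch budget
        train_classifier(net, train, train,
                         TrainConfig(epochs=150, lr=1e-2, patience=150,
                                     batch_size=8, seed=0))
        pred, _ = predict(net, patches)
        assert np.mean(pred == labels) == 1.0

    def test_single_class_training_rejected(self, rng):
        from dpkhsi.preprocess import PatchSet

        patches = rng.standard_normal((6, 4, 4, 1))
        train = PatchSet(patches, np.ones(6, dtype=int),
                         np.zeros((6, 2), dtype=int), "train")
        bank = random_kernels(2, 2, 1, seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(PreLearnedCNN(bank, classes=1), train, train)

    def test_scene_test_accuracy(self, trained_scene_net):
        net, _, _, te = trained_scene_net
        pred, _ = predict(net, te.patches)
        assert np.mean(pred == te.labels) >= 0.9


class TestPredict:
    def test_probabilities_sum_to_one(self, trained_scene_net):
        net, _, _, te = trained_scene_net
        _, probs = predict(net, te.patches[:16])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_order_invariance(self, trained_scene_net):
        net, _, _, te = trained_scene_net
        batch = te.patches[:10]
        perm = np.random.default_rng(0).permutation(10)
        pred_a, _ = predict(net, batch)
        pred_b, _ = predict(net, batch[perm])
        assert np.array_equal(pred_a[perm], pred_b)

    def test_agreement_with_single_sample_loop(self, trained_scene_net):
        net, _, _, te = trained_scene_net
        batch = te.patches[:8]
        pred_batch, probs_batch = predict(net, batch)
        for i in range(8):
            pred_i, probs_i = predict(net, batch[i])
            assert pred_i[0] == pred_batch[i]
            np.testing.assert_allclose(probs_i[0], probs_batch[i], atol=1e-10)


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path, trained_scene_net):
        net, _, _, te = trained_scene_net
        save_model(net, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        pred_a, probs_a = predict(net, te.patches[:12])
        pred_b, probs_b = predict(loaded, te.patches[:12])
        assert np.array_equal(pred_a, pred_b)
        np.testing.assert_allclose(probs_a, probs_b, atol=1e-12)
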