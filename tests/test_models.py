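"""MIL model forwards: attention normalization, permutation invariance,
determinism, aggregation oracles, instance clustering loss, boosted head."""

import math

import numpy as np
import pytest

from slidemil.abmil import Abmil, AbmilConfig, ClassAttention, three_branch_aggregate
from slidemil.autodiff import Adam, Tensor
from slidemil.clam import ClamConfig, ClamSB, clam_total_loss
from slidemil.milboost import (
    AttentionPool,
    BoostConfig,
    PoolConfig,
    SlideEmbedding,
    boosted_importance,
    enhanced_features,
    fit_boosted,
)
from slidemil.nn import AttentionOutput

D = 12


@pytest.fixture(scope="module")
def clam():
    return ClamSB(ClamConfig(input_dim=D, encoder_hidden=16, attn_hidden=8, cls_hidden=6, seed=0))


@pytest.fixture(scope="module")
def abmil():
    return Abmil(AbmilConfig(input_dim=D, n_heads=3, attn_space=8, head_dim=10, bottleneck=8, seed=0))


@pytest.fixture(scope="module")
def pool():
    return AttentionPool(PoolConfig(input_dim=D, attn_hidden=8, seed=0))


def finite_difference_grads(model, x, loss_fn, n_probe=3, eps=1e-6, seed=0):
    rng = np.random.default_rng(seed)
    errs = []
    loss = loss_fn(model, x)
    for p in model.parameters():
        p.grad = None
    loss.backward()
    for p in model.parameters():
        for _ in range(n_probe):
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            old = p.data[idx]
            p.data[idx] = old + eps
            lp = loss_fn(model, x).data
            p.data[idx] = old - eps
            lm = loss_fn(model, x).data
            p.data[idx] = old
            errs.append(abs((lp - lm) / (2 * eps) - p.grad[idx]))
    return max(errs)


class TestClam:
    def test_singleton_bag_attention_is_one(self, clam, rng):
        _, attn, _ = clam.forward(rng.standard_normal((1, D)))
        assert attn.weights.shape == (1,)
        assert attn.weights[0] == 1.0

    def test_identical_instances_split_evenly(self, clam, rng):
        row = rng.standard_normal(D)
        _, attn, _ = clam.forward(np.stack([row, row]))
        np.testing.assert_allclose(attn.weights, [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 100])
    def test_attention_simplex(self, clam, rng, n):
        _, attn, _ = clam.forward(rng.standard_normal((n, D)))
        assert attn.weights.min() >= 0
        assert attn.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariance(self, clam, rng):
        x = rng.standard_normal((15, D))
        perm = rng.permutation(15)
        l1 = clam.forward(x)[0].data
        l2 = clam.forward(x[perm])[0].data
        np.testing.assert_allclose(l1, l2, atol=1e-6)

    def test_eval_mode_deterministic(self, clam, rng):
        x = rng.standard_normal((7, D))
        a = clam.forward(x, mode="eval")[0].data
        b = clam.forward(x, mode="eval")[0].data
        np.testing.assert_array_equal(a, b)

    def test_train_mode_dropout_varies(self, rng):
        m = ClamSB(ClamConfig(input_dim=D, dropout=0.5, seed=1))
        x = rng.standard_normal((6, D))
        a = m.forward(x, mode="train")[0].data
        b = m.forward(x, mode="train")[0].data
        assert not np.allclose(a, b)

    def test_dim_mismatch_rejected(self, clam, rng):
        with pytest.raises(ValueError):
            clam.forward(rng.standard_normal((4, D + 1)))

    def test_instance_loss_random_classifier_near_ln2(self, rng):
        """With a near-zero instance classifier, sigmoid outputs ~0.5 so BCE
        on balanced pseudo-labels approaches ln 2."""
        m = ClamSB(ClamConfig(input_dim=D, encoder_hidden=16, attn_hidden=8, seed=2))
        m.inst_cls.W.data[:] = 0.0
        m.inst_cls.b.data[:] = 0.0
        _, attn, h = m.forward(rng.standard_normal((40, D)))
        loss = m.instance_cluster_loss(attn, h)
        assert loss.data == pytest.approx(math.log(2), abs=1e-9)

    def test_instance_loss_degenerate_single_instance(self, clam, rng):
        _, attn, h = clam.forward(rng.standard_normal((1, D)))
        assert np.isfinite(clam.instance_cluster_loss(attn, h).data)

    def test_separable_embeddings_drive_loss_to_zero(self, rng):
        m = ClamSB(ClamConfig(input_dim=D, encoder_hidden=16, attn_hidden=8, seed=3))
        x = rng.standard_normal((16, D))
        _, attn, h = m.forward(x)
        opt = Adam([m.inst_cls.W, m.inst_cls.b], lr=0.3)
        for _ in range(200):
            loss = m.instance_cluster_loss(attn, h)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert m.instance_cluster_loss(attn, h).data < 0.05

    @pytest.mark.parametrize("w,losses,expected", [(1.0, (0.6, 0.2), 0.6),
                                                   (0.5, (0.6, 0.2), 0.4),
                                                   (0.0, (0.6, 0.2), 0.2)])
    def test_total_loss_mix(self, w, losses, expected):
        got = clam_total_loss(Tensor(losses[0]), Tensor(losses[1]), w)
        assert float(got.data) == pytest.approx(expected)

    def test_gradients_match_finite_differences(self, rng):
        from slidemil.losses import FocalParams, make_bag_loss

        m = ClamSB(ClamConfig(input_dim=D, encoder_hidden=10, attn_hidden=6,
                              cls_hidden=5, dropout=0.0, seed=4))
        loss_fn_inner = make_bag_loss("focal", FocalParams(np.array([1.0, 3.0, 1.0]), 2.0), None)

        def loss_fn(model, x):
            logits, attn, h = model.forward(x)
            return clam_total_loss(loss_fn_inner(logits, 1),
                                   model.instance_cluster_loss(attn, h, 3), 0.5)

        err = finite_difference_grads(m, rng.standard_normal((8, D)), loss_fn)
        assert err < 1e-6

    def test_checkpoint_round_trip(self, clam, rng, tmp_path):
        x = rng.standard_normal((5, D))
        before = clam.forward(x)[0].data
        path = tmp_path / "clam.npz"
        clam.save(path)
        loaded = ClamSB.load(path)
        np.testing.assert_array_equal(loaded.forward(x)[0].data, before)


class TestAbmil:
    def test_column_simplexes(self, abmil, rng):
        for n in (1, 2, 50):
            _, ca, _ = abmil.forward(rng.standard_normal((n, D)))
            assert ca.weights.shape == (n, 3)
            np.testing.assert_allclose(ca.weights.sum(axis=0), np.ones(3), atol=1e-6)
            assert ca.weights.min() >= 0

    def test_singleton_columns_are_one(self, abmil, rng):
        _, ca, _ = abmil.forward(rng.standard_normal((1, D)))
        np.testing.assert_allclose(ca.weights, np.ones((1, 3)))

    def test_zero_features_zero_biases_give_zero_scores(self):
        m = Abmil(AbmilConfig(input_dim=D, n_heads=2, attn_space=4, head_dim=6, seed=5))
        for head in m.heads:
            for layer in (head.proj, head.base, head.gate, head.score):
                layer.b.data[:] = 0.0
        _, ca, _ = m.forward(np.zeros((4, D)))
        np.testing.assert_allclose(ca.raw_scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(ca.weights, 0.25, atol=1e-12)  # uniform softmax

    def test_permutation_invariance(self, abmil, rng):
        x = rng.standard_normal((20, D))
        perm = rng.permutation(20)
        np.testing.assert_allclose(
            abmil.forward(x)[0].data, abmil.forward(x[perm])[0].data, atol=1e-6
        )

    def test_eval_determinism(self, abmil, rng):
        x = rng.standard_normal((6, D))
        np.testing.assert_array_equal(abmil.forward(x)[0].data, abmil.forward(x)[0].data)

    def test_three_branch_matches_loop_oracle(self, rng):
        x = rng.standard_normal((7, 5))
        raw = rng.standard_normal((7, 3))
        w = np.exp(raw) / np.exp(raw).sum(axis=0, keepdims=True)
        ca = ClassAttention(weights=w, raw_scores=raw)
        got = three_branch_aggregate(x, ca)
        expected = np.zeros((3, 5))
        for c in range(3):
            for i in range(7):
                expected[c] += w[i, c] * x[i]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_uniform_attention_gives_instance_mean(self, rng):
        x = rng.standard_normal((8, 5))
        w = np.full((8, 3), 1 / 8)
        got = three_branch_aggregate(x, ClassAttention(w, w))
        for c in range(3):
            np.testing.assert_allclose(got[c], x.mean(axis=0), atol=1e-12)

    def test_onehot_attention_selects_instance(self, rng):
        x = rng.standard_normal((6, 4))
        w = np.zeros((6, 3))
        w[2, 0] = w[4, 1] = w[0, 2] = 1.0
        got = three_branch_aggregate(x, ClassAttention(w, w))
        np.testing.assert_allclose(got, x[[2, 4, 0]], atol=1e-12)

    def test_gate_telemetry_recorded(self, abmil, rng):
        abmil.forward(rng.standard_normal((5, D)))
        assert 0.0 < abmil.last_gate_mean < 1.0  # sigmoid range

    def test_gradients_match_finite_differences(self, rng):
        from slidemil.losses import weighted_ce_on_logits

        m = Abmil(AbmilConfig(input_dim=D, n_heads=2, attn_space=4, head_dim=5,
                              bottleneck=6, seed=6))

        def loss_fn(model, x):
            return weighted_ce_on_logits(model.forward(x)[0], 1, np.array([1.0, 3.0, 1.0]))

        err = finite_difference_grads(m, rng.standard_normal((6, D)), loss_fn)
        assert err < 1e-6


class TestAttentionPool:
    def test_singleton_embedding_is_the_instance(self, pool, rng):
        x = rng.standard_normal((1, D))
        _, _, pooled = pool.forward(x)
        np.testing.assert_allclose(pooled.data, x[0], atol=1e-12)

    def test_constant_scores_give_column_mean(self, rng):
        m = AttentionPool(PoolConfig(input_dim=D, attn_hidden=4, seed=7))
        m.attn_out.W.data[:] = 0.0  # constant raw scores -> uniform attention
        x = rng.standard_normal((9, D))
        _, attn, pooled = m.forward(x)
        np.testing.assert_allclose(attn.weights, 1 / 9, atol=1e-12)
        np.testing.assert_allclose(pooled.data, x.mean(axis=0), atol=1e-12)

    def test_pool_matches_loop_oracle(self, rng):
        m = AttentionPool(PoolConfig(input_dim=6, attn_hidden=4, seed=8))
        x = rng.standard_normal((9, 6))
        _, attn, pooled = m.forward(x)
        expected = sum(attn.weights[i] * x[i] for i in range(9))
        np.testing.assert_allclose(pooled.data, expected, atol=1e-6)

    def test_permutation_invariance(self, pool, rng):
        x = rng.standard_normal((11, D))
        perm = rng.permutation(11)
        np.testing.assert_allclose(pool.forward(x)[0].data, pool.forward(x[perm])[0].data,
                                   atol=1e-6)


def uniform_embedding(n, k=3):
    w = np.full(n, 1.0 / n)
    return SlideEmbedding(S=np.zeros(4), attention=AttentionOutput(w, w),
                          mil_logits=np.zeros(k), mil_probs=np.full(k, 1 / k))


class TestEnhancedFeatures:
    def test_uniform_weights_identities(self):
        n = 10
        from slidemil.milboost import ENHANCED_FEATURE_NAMES

        vec = enhanced_features(uniform_embedding(n))
        names = dict(zip(ENHANCED_FEATURE_NAMES, vec))
        assert names["attn_entropy"] == pytest.approx(math.log(n), abs=1e-9)
        assert names["attn_entropy_norm"] == pytest.approx(1.0, abs=1e-9)
        assert names["attn_gini"] == pytest.approx(0.0, abs=1e-9)
        assert names["attn_top1"] == pytest.approx(1 / n)

    def test_onehot_weights_identities(self):
        n = 8
        w = np.zeros(n)
        w[3] = 1.0
        emb = SlideEmbedding(np.zeros(4), AttentionOutput(w, w), np.zeros(3), np.full(3, 1 / 3))
        vec = enhanced_features(emb)
        from slidemil.milboost import ENHANCED_FEATURE_NAMES

        names = dict(zip(ENHANCED_FEATURE_NAMES, vec))
        assert names["attn_entropy"] == pytest.approx(0.0, abs=1e-9)
        assert names["attn_top1"] == pytest.approx(1.0)
        assert names["attn_frac_above_mean"] == pytest.approx(1 / n)

    @pytest.mark.parametrize("n", [1, 2, 50])
    def test_length_23_for_any_bag_size(self, n, rng):
        w = rng.random(n)
        w /= w.sum()
        emb = SlideEmbedding(np.zeros(4), AttentionOutput(w, w), rng.standard_normal(3),
                             np.full(3, 1 / 3))
        assert enhanced_features(emb).shape == (23,)

    def test_permutation_invariant(self, rng):
        w = rng.random(20)
        w /= w.sum()
        perm = rng.permutation(20)
        e1 = enhanced_features(SlideEmbedding(np.zeros(2), AttentionOutput(w, w),
                                              np.zeros(3), np.full(3, 1 / 3)))
        e2 = enhanced_features(SlideEmbedding(np.zeros(2), AttentionOutput(w[perm], w[perm]),
                                              np.zeros(3), np.full(3, 1 / 3)))
        np.testing.assert_allclose(e1, e2, atol=1e-12)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    centers = np.zeros((3, 23))
    centers[0, 0], centers[1, 1], centers[2, 2] = 10, 10, 10
    x = np.vstack([rng.normal(centers[c], 0.3, size=(20, 23)) for c in range(3)])
    x[:, 5] = 1.23  # constant feature: should never be split on
    y = np.repeat([0, 1, 2], 20)
    return x, y


class TestBoostedHead:

    def test_separable_training_accuracy(self, separable):
        x, y = separable
        clf = fit_boosted(x, y, BoostConfig(seed=0))
        assert (clf.predict(x) == y).mean() == 1.0

    def test_constant_feature_zero_importance(self, separable):
        x, y = separable
        imp = boosted_importance(fit_boosted(x, y, BoostConfig(seed=0)))
        assert imp.shape == (23,)
        assert imp[5] == 0.0
        assert np.all(imp >= 0)

    def test_probs_are_simplex(self, separable):
        x, y = separable
        probs = fit_boosted(x, y, BoostConfig(seed=0)).predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_missing_class_rejected(self, separable):
        x, y = separable
        keep = y != 1
        with pytest.raises(ValueError, match="classes"):
            fit_boosted(x[keep], y[keep], BoostConfig())

    def test_reproducible(self, separable):
        x, y = separable
        p1 = fit_boosted(x, y, BoostConfig(seed=3)).predict_proba(x)
        p2 = fit_boosted(x, y, BoostConfig(seed=3)).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)
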