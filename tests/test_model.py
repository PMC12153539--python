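"""ABMIL model: attention algebra, MIL invariances, gradients, training."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import slidemil as sm
from slidemil.model import _PARAM_FIELDS, _loss_and_grads, AbmilParams


def _tiny_params():
    """Hand-set 1-1-1 network so every score is a scalar calculation."""
    return AbmilParams(
        W_proj=np.array([[1.0]]),
        b_proj=np.array([0.0]),
        V=np.array([[0.7]]),
        b_V=np.array([0.1]),
        U=np.array([[-0.4]]),
        b_U=np.array([0.2]),
        w_att=np.array([1.3]),
        b_att=np.asarray(0.5),
        W_clf=np.array([[0.9], [-0.3]]),
        b_clf=np.array([0.0, 0.0]),
    )


def _bag(features, slide_id="b"):
    features = np.atleast_2d(np.asarray(features, dtype=float))
    coords = np.stack(
        [np.arange(len(features)) * 256, np.zeros(len(features), dtype=int)], axis=1
    )
    return sm.FeatureBag(slide_id, features, coords, "test")


class TestInit:
    def test_seed_determinism(self):
        a, b = sm.init_params(16, seed=3), sm.init_params(16, seed=3)
        for k in _PARAM_FIELDS:
            np.testing.assert_array_equal(getattr(a, k), getattr(b, k))
        c = sm.init_params(16, seed=4)
        assert not np.array_equal(a.W_proj, c.W_proj)

    def test_default_hidden_scales_down(self):
        assert sm.default_hidden(1024) == (512, 256)
        assert sm.default_hidden(32) == (32, 128)

    def test_dim_mismatch_at_forward(self):
        p = sm.init_params(8, seed=0)
        with pytest.raises(ValueError, match="feature dim"):
            sm.predict_slide(p, _bag(np.zeros((2, 5))))


class TestAttention:
    def test_single_patch_weight_is_one(self):
        w = sm.attention_weights(_tiny_params(), _bag([[2.0]]))
        np.testing.assert_allclose(w, [1.0])

    def test_identical_patches_uniform(self):
        p = sm.init_params(6, seed=1)
        bag = _bag(np.tile(np.linspace(-1, 1, 6), (5, 1)))
        np.testing.assert_allclose(sm.attention_weights(p, bag), np.full(5, 0.2))

    def test_two_instance_hand_softmax(self):
        # independent scalar recomputation of the gated attention scores
        p = _tiny_params()
        xs = [0.8, 2.0]
        scores = [
            1.3 * math.tanh(0.7 * x + 0.1) / (1 + math.exp(0.4 * x - 0.2)) + 0.5
            for x in xs
        ]
        e = [math.exp(s - max(scores)) for s in scores]
        expected = np.array(e) / sum(e)
        got = sm.attention_weights(p, _bag([[xs[0]], [xs[1]]]))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_weights_normalised(self):
        p = sm.init_params(4, seed=2)
        w = sm.attention_weights(p, _bag(np.random.default_rng(0).normal(size=(9, 4))))
        assert np.all(w >= 0) and np.all(w <= 1)
        assert abs(w.sum() - 1.0) < 1e-6


class TestAggregateClassify:
    def test_uniform_weights_give_mean(self):
        p = sm.init_params(4, seed=0)
        x = np.random.default_rng(1).normal(size=(6, 4))
        bag = _bag(x)
        h = np.maximum(x @ p.W_proj.T + p.b_proj, 0)
        np.testing.assert_allclose(
            sm.aggregate(p, np.full(6, 1 / 6), bag), h.mean(axis=0)
        )

    def test_one_hot_selects_patch(self):
        p = sm.init_params(4, seed=0)
        x = np.random.default_rng(2).normal(size=(3, 4))
        w = np.array([0.0, 1.0, 0.0])
        h1 = np.maximum(x[1] @ p.W_proj.T + p.b_proj, 0)
        np.testing.assert_allclose(sm.aggregate(p, w, _bag(x)), h1)

    def test_convex_combination(self):
        p = _tiny_params()
        bag = _bag([[1.0], [3.0]])
        np.testing.assert_allclose(
            sm.aggregate(p, np.array([0.25, 0.75]), bag), [0.25 * 1 + 0.75 * 3]
        )

    def test_softmax_closed_forms(self):
        p = sm.init_params(2, hidden=(2, 2), seed=0)
        p.W_clf = np.eye(2)
        p.b_clf = np.zeros(2)
        np.testing.assert_allclose(sm.classify(p, [1.0, 1.0]), [0.5, 0.5])
        np.testing.assert_allclose(
            sm.classify(p, [math.log(2), 0.0]), [2 / 3, 1 / 3], rtol=1e-12
        )
        p.b_clf = np.full(2, 10.0)  # shared logit shift changes nothing
        np.testing.assert_allclose(
            sm.classify(p, [math.log(2), 0.0]), [2 / 3, 1 / 3], rtol=1e-12
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sm.classify(_tiny_params(), [np.nan])


class TestPredictSlide:
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p = sm.init_params(5, seed=0)
        x = rng.normal(size=(7, 5))
        perm = rng.permutation(7)
        a = sm.predict_slide(p, _bag(x))
        b = sm.predict_slide(p, _bag(x[perm]))
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)
        np.testing.assert_allclose(a.attention[perm], b.attention, atol=1e-12)

    def test_duplication_invariance(self):
        p = sm.init_params(5, seed=1)
        x = np.random.default_rng(3).normal(size=(4, 5))
        a = sm.predict_slide(p, _bag(x))
        b = sm.predict_slide(p, _bag(np.vstack([x, x])))
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-12)
        np.testing.assert_allclose(b.attention, np.tile(a.attention / 2, 2), atol=1e-12)

    def test_single_patch_composition(self):
        p = sm.init_params(5, seed=2)
        x = np.random.default_rng(4).normal(size=(1, 5))
        pred = sm.predict_slide(p, _bag(x))
        z = sm.aggregate(p, np.ones(1), _bag(x))
        np.testing.assert_allclose(pred.probs, sm.classify(p, z), atol=1e-12)
        assert pred.predicted_label in sm.LABELS
        assert abs(pred.probs.sum() - 1) < 1e-6


class TestGradients:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        p = sm.init_params(6, hidden=(5, 4), seed=1)
        x = rng.standard_normal((7, 6))
        _, grads = _loss_and_grads(p, x, 1, 1.3, 0.0, None)
        eps = 1e-6
        for k in _PARAM_FIELDS:
            flat = np.atleast_1d(getattr(p, k)).ravel()
            ana = np.atleast_1d(grads[k]).ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _loss_and_grads(p, x, 1, 1.3, 0.0, None)
                flat[i] = orig - eps
                lm, _ = _loss_and_grads(p, x, 1, 1.3, 0.0, None)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - ana[i]) < 1e-6, f"{k}[{i}]: fd={fd} ana={ana[i]}"


class TestTrain:
    def _data(self, n=10, seed=0):
        bags, labels = sm.generate_feature_bags(
            sm.BagSimSpec(n_bags_per_class=n, bag_size_range=(5, 15),
                          feature_dim=8, seed=seed)
        )
        return bags, labels

    def test_zero_epochs_is_noop(self):
        bags, labels = self._data()
        p = sm.init_params(8, seed=0)
        cfg = sm.TrainConfig(max_epochs=0, seed=0)
        out, hist = sm.train(p, bags, labels, cfg, bags, labels)
        assert hist == []
        for k in _PARAM_FIELDS:
            np.testing.assert_array_equal(getattr(out, k), getattr(p, k))

    def test_training_reproducible(self):
        bags, labels = self._data()
        vb, vl = self._data(4, seed=1)
        cfg = sm.TrainConfig(max_epochs=8, min_epochs=1, patience=3, seed=5)
        runs = [
            sm.train(sm.init_params(8, seed=0), bags, labels, cfg, vb, vl)
            for _ in range(2)
        ]
        for k in _PARAM_FIELDS:
            np.testing.assert_array_equal(
                getattr(runs[0][0], k), getattr(runs[1][0], k)
            )
        assert runs[0][1] == runs[1][1]

    def test_missing_class_rejected(self):
        bags, labels = self._data(4)
        pos = [b for b, l in zip(bags, labels) if l == "metastatic"]
        p = sm.init_params(8, seed=0)
        cfg = sm.TrainConfig(max_epochs=2)
        with pytest.raises(ValueError, match="both classes"):
            sm.train(p, pos, ["metastatic"] * len(pos), cfg, bags, labels)
        with pytest.raises(ValueError, match="both classes"):
            sm.train(p, bags, labels, cfg, pos, ["metastatic"] * len(pos))

    def test_validation_loss_improves_on_separable_data(self, bag_study):
        hist = bag_study["history"]
        assert min(h["val_loss"] for h in hist) < hist[0]["val_loss"]


class TestEnsemble:
    def test_identical_members_idempotent(self):
        p = sm.init_params(5, seed=0)
        bag = _bag(np.random.default_rng(0).normal(size=(4, 5)))
        single = sm.predict_slide(p, bag)
        ens = sm.ensemble_predict([p, p, p], bag)
        np.testing.assert_allclose(ens.probs, single.probs, atol=1e-12)
        np.testing.assert_allclose(ens.attention, single.attention, atol=1e-12)

    def test_probability_averaging(self):
        # members with metastatic probs 0.9, 0.8, 0.7, 0.6, 0.55 -> 0.71
        probs = [0.9, 0.8, 0.7, 0.6, 0.55]
        members = []
        for q in probs:
            p = sm.init_params(1, hidden=(1, 1), seed=0)
            p.W_proj = np.array([[0.0]])
            p.b_proj = np.array([1.0])
            p.W_clf = np.array([[0.0], [0.0]])
            p.b_clf = np.array([0.0, math.log(q / (1 - q))])
            members.append(p)
        ens = sm.ensemble_predict(members, _bag([[0.0]]))
        np.testing.assert_allclose(ens.probs[1], 0.71, atol=1e-9)
        assert ens.predicted_label == "metastatic"

    def test_two_member_mean(self):
        # (0.8, 0.2) and (0.6, 0.4) -> (0.7, 0.3)
        members = []
        for q in (0.2, 0.4):
            p = sm.init_params(1, hidden=(1, 1), seed=0)
            p.W_proj = np.array([[0.0]])
            p.b_proj = np.array([1.0])
            p.W_clf = np.array([[0.0], [0.0]])
            p.b_clf = np.array([0.0, math.log(q / (1 - q))])
            members.append(p)
        ens = sm.ensemble_predict(members, _bag([[0.0]]))
        np.testing.assert_allclose(ens.probs, [0.7, 0.3], atol=1e-9)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        p = sm.init_params(8, seed=3)
        cfg = sm.TrainConfig(seed=3)
        path = sm.save_checkpoint(p, tmp_path / "m.npz", "toy-v1", cfg)
        back, meta = sm.load_checkpoint(path)
        for k in _PARAM_FIELDS:
            np.testing.assert_array_equal(getattr(back, k), getattr(p, k))
        assert meta["extractor_id"] == "toy-v1"
        assert meta["train_config"]["seed"] == 3
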