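"""The soft decision tree of attention-weighted logistic units."""

import numpy as np
import pandas as pd
import pytest

from vdt2 import tree
from vdt2.exceptions import ConfigError, VDT2Error


def _finite_difference(params, X, y, config, h=1e-6):
    vec = params.to_vector()
    grad = np.zeros_like(vec)
    for i in range(len(vec)):
        vp, vm = vec.copy(), vec.copy()
        vp[i] += h
        vm[i] -= h
        lp = tree.loss_and_grad(
            tree.VDTParams.from_vector(vp, params.depth, params.n_features),
            X, y, config,
        )[0]
        lm = tree.loss_and_grad(
            tree.VDTParams.from_vector(vm, params.depth, params.n_features),
            X, y, config,
        )[0]
        grad[i] = (lp - lm) / (2 * h)
    return grad


class TestInit:
    @pytest.mark.parametrize("depth, internal, leaves", [(1, 1, 2), (2, 3, 4), (4, 15, 16)])
    def test_complete_tree_sizes(self, depth, internal, leaves):
        p = tree.init_params(depth, n_features=5, seed=42)
        assert p.n_internal == internal
        assert p.w.shape == (internal, 5)
        assert p.theta.shape == (leaves,)

    def test_seeded_determinism(self):
        a = tree.init_params(4, 13, seed=42)
        b = tree.init_params(4, 13, seed=42)
        assert np.array_equal(a.to_vector(), b.to_vector())

    def test_vector_roundtrip(self):
        p = tree.init_params(3, 7, seed=1)
        back = tree.VDTParams.from_vector(p.to_vector(), 3, 7)
        assert np.array_equal(back.to_vector(), p.to_vector())

    def test_invalid_depth(self):
        with pytest.raises(ConfigError):
            tree.init_params(0, 5)


class TestForward:
    def test_path_probabilities_normalize(self):
        rng = np.random.default_rng(0)
        for depth in (1, 2, 4):
            p = tree.init_params(depth, 6, init_sd=2.0, seed=depth)
            X = rng.standard_normal((50, 6)) * 3
            pi = tree.leaf_path_probs(p, X)
            assert np.all(np.abs(pi.sum(axis=1) - 1.0) < 1e-12)
            assert np.all(pi >= 0)

    def test_depth_one_saturated_leaves_reduce_to_logistic(self):
        rng = np.random.default_rng(1)
        p = tree.init_params(1, 4, init_sd=0.8, seed=3)
        p.theta = np.array([-500.0, 500.0])  # leaves pinned to 0 and 1
        X = rng.standard_normal((40, 4))
        alpha = p.attention()[0]
        logistic = 1.0 / (1.0 + np.exp(-(X @ (p.w[0] * alpha) + p.b[0])))
        assert np.max(np.abs(tree.forward(p, X) - logistic)) < 1e-9

    def test_zero_parameters_give_half(self):
        p = tree.init_params(3, 5, init_sd=0.0, seed=0)
        X = np.random.default_rng(2).standard_normal((10, 5))
        assert np.allclose(tree.forward(p, X), 0.5)

    def test_attention_is_convex_combination(self):
        p = tree.init_params(4, 13, init_sd=1.0, seed=42)
        alpha = p.attention()
        assert np.allclose(alpha.sum(axis=1), 1.0)
        assert np.all(alpha > 0)

    def test_feature_permutation_consistency(self):
        rng = np.random.default_rng(4)
        p = tree.init_params(2, 6, init_sd=1.0, seed=5)
        X = rng.standard_normal((30, 6))
        perm = rng.permutation(6)
        p2 = tree.VDTParams(
            depth=2, n_features=6,
            w=p.w[:, perm], b=p.b.copy(), a=p.a[:, perm], theta=p.theta.copy(),
        )
        assert np.allclose(tree.forward(p, X), tree.forward(p2, X[:, perm]))

    def test_dimension_mismatch(self):
        p = tree.init_params(2, 6)
        with pytest.raises(VDT2Error):
            tree.forward(p, np.zeros((3, 5)))


class TestLossAndGrad:
    @pytest.mark.parametrize("attention", ["softmax", "sigmoid"])
    def test_gradient_matches_finite_differences(self, attention):
        rng = np.random.default_rng(0)
        p = tree.init_params(2, 3, init_sd=0.5, seed=1)
        X = rng.standard_normal((20, 3))
        y = rng.integers(0, 2, 20).astype(float)
        config = tree.FitConfig(l2_penalty=0.01, attention=attention)
        _, grad = tree.loss_and_grad(p, X, y, config)
        numeric = _finite_difference(p, X, y, config)
        rel = np.abs(grad - numeric) / np.maximum(np.abs(numeric), 1e-8)
        assert rel.max() < 1e-5

    def test_balanced_zero_params_loss_is_ln2(self):
        p = tree.init_params(2, 4, init_sd=0.0, seed=0)
        X = np.random.default_rng(1).standard_normal((30, 4))
        y = np.array([0.0, 1.0] * 15)
        loss, _ = tree.loss_and_grad(p, X, y)
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_ridge_increases_loss_for_nonzero_weights(self):
        p = tree.init_params(2, 4, init_sd=0.5, seed=2)
        X = np.random.default_rng(3).standard_normal((30, 4))
        y = np.array([0.0, 1.0] * 15)
        plain, _ = tree.loss_and_grad(p, X, y, tree.FitConfig(l2_penalty=0.0))
        ridged, _ = tree.loss_and_grad(p, X, y, tree.FitConfig(l2_penalty=0.1))
        assert ridged > plain

    def test_nonbinary_labels_rejected(self):
        p = tree.init_params(1, 2)
        with pytest.raises(VDT2Error):
            tree.loss_and_grad(p, np.zeros((2, 2)), np.array([0.0, 2.0]))


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(13)
    X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(4, 1, (100, 2))])
    y = np.concatenate([np.zeros(100), np.ones(100)])
    return X, y


class TestFit:
    def test_separable_blobs_high_accuracy(self, blobs):
        X, y = blobs
        res = tree.VowelDiabetesTree(y, X, depth=2, seed=42).fit()
        assert (res.predict() == y).mean() >= 0.95

    def test_final_loss_never_worse_than_initial_or_trivial(self, blobs):
        X, y = blobs
        res = tree.VowelDiabetesTree(y, X, depth=2, seed=42).fit()
        assert res.final_loss <= res.trace["initial_loss"]
        assert res.final_loss <= np.log(2)

    def test_refit_identical_trace(self, blobs):
        X, y = blobs
        r1 = tree.VowelDiabetesTree(y, X, depth=2, seed=42).fit()
        r2 = tree.VowelDiabetesTree(y, X, depth=2, seed=42).fit()
        assert r1.trace["losses"] == r2.trace["losses"]
        assert np.array_equal(r1.params.to_vector(), r2.params.to_vector())

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(VDT2Error):
            tree.VowelDiabetesTree(np.zeros(10), X, depth=1).fit()

    def test_teacher_student_parameter_recovery(self):
        # a depth-2 student recovers a depth-2 teacher's decision function
        teacher = tree.init_params(depth=2, n_features=5, init_sd=2.0, seed=10)
        X = np.random.default_rng(11).standard_normal((2000, 5))
        labels = (tree.forward(teacher, X) >= 0.5).astype(float)
        student = tree.VowelDiabetesTree(labels, X, depth=2, seed=42).fit(max_iter=200)
        from vdt2.evaluate import roc_auc

        assert roc_auc(labels.astype(int), student.predict_proba(X)) >= 0.9


class TestPredict:
    def test_probability_at_threshold_is_positive(self):
        p = tree.init_params(2, 3, init_sd=0.0, seed=0)  # P = 0.5 everywhere
        X = np.zeros((4, 3))
        assert np.all(tree.predict(p, X, threshold=0.5) == 1)

    def test_raising_threshold_monotone(self):
        p = tree.init_params(3, 4, init_sd=1.0, seed=6)
        X = np.random.default_rng(7).standard_normal((100, 4))
        n_pos = [tree.predict(p, X, threshold=t).sum() for t in (0.2, 0.5, 0.8)]
        assert n_pos[0] >= n_pos[1] >= n_pos[2]

    def test_probabilities_match_forward(self):
        p = tree.init_params(2, 4, init_sd=1.0, seed=8)
        X = np.random.default_rng(9).standard_normal((25, 4))
        assert np.array_equal(tree.predict_proba(p, X), tree.forward(p, X))

    def test_hard_routing_uses_single_leaf(self):
        p = tree.init_params(2, 3, init_sd=3.0, seed=10)
        X = np.random.default_rng(11).standard_normal((20, 3))
        hard = tree.predict(p, X, hard_routing=True)
        assert set(hard) <= {0, 1}


class TestResultsInterface:
    def test_from_dataframe_and_summary(self, default_cohort):
        sub = default_cohort.groupby("group", group_keys=False).head(60)
        model = tree.VowelDiabetesTree.from_dataframe(
            sub, features=["meanF0", "HNR"], depth=2, seed=42
        )
        res = model.fit(max_iter=30)
        text = res.summary()
        assert "Soft Decision Tree" in text
        assert "meanF0" in text or "HNR" in text
        att = res.attention_frame()
        assert list(att.columns) == ["meanF0", "HNR"]
        assert np.allclose(att.sum(axis=1), 1.0)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 60)
        res = tree.VowelDiabetesTree(y, X, depth=2, seed=42).fit(max_iter=40)
        path = tmp_path / "model.json"
        res.save(path)
        loaded = tree.VDTResults.load(path)
        assert np.array_equal(loaded.params.to_vector(), res.params.to_vector())
        probe = rng.standard_normal((5, 3))
        assert np.allclose(loaded.predict_proba(probe), res.predict_proba(probe))
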