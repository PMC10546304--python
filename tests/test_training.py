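"""Loss functions (with finite-difference oracles) and end-to-end training."""

import numpy as np
import pytest

import cystfuse as cf
from cystfuse.training import (
    appearance_separation_grad,
    appearance_separation_loss,
    content_consistency_grad,
    content_consistency_loss,
    cross_entropy,
)

from conftest import make_separable_packs


class TestContentConsistency:
    def test_zero_iff_identical(self):
        f = np.tile(np.array([1.0, 2.0, 3.0]), (7, 1))
        assert content_consistency_loss(cf.FeatureSet(f, L_a=1)) == 0.0
        f[3, 2] += 1.0
        assert content_consistency_loss(cf.FeatureSet(f, L_a=1)) > 0.0

    def test_two_modality_worked_example(self):
        # c_1 = (0), c_2 = (2): mean 1, loss = (1 + 1) / (2 * 1) = 1
        f = np.array([[0.0], [2.0]])
        assert content_consistency_loss(f, L_a=0) == pytest.approx(1.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(7, 5))
        base = content_consistency_loss(f, L_a=2)
        for t in (0.5, 2.0, 3.0):
            g = f.copy()
            g[:, 2:] *= t
            assert content_consistency_loss(g, L_a=2) == pytest.approx(t**2 * base)

    def test_empty_content_part_warns_and_returns_zero(self, caplog):
        f = np.random.default_rng(1).normal(size=(7, 3))
        with caplog.at_level("WARNING"):
            assert content_consistency_loss(f, L_a=3) == 0.0
        assert "content" in caplog.text

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(2, 7, 4))
        L_a = 1
        g = content_consistency_grad(feats, L_a)
        eps = 1e-6

        def batch_loss(f):
            return np.mean([content_consistency_loss(f[b], L_a=L_a) for b in range(len(f))])

        for _ in range(15):
            idx = tuple(rng.integers(s) for s in feats.shape)
            fp = feats.copy(); fp[idx] += eps
            fm = feats.copy(); fm[idx] -= eps
            num = (batch_loss(fp) - batch_loss(fm)) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-6)


class TestAppearanceSeparation:
    def test_identical_vectors_give_one(self):
        f = np.tile(np.array([1.0, 2.0]), (7, 1))
        assert appearance_separation_loss(cf.FeatureSet(f, L_a=2)) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        f = np.eye(7)
        assert appearance_separation_loss(cf.FeatureSet(f, L_a=7)) == 0.0

    def test_worked_example_single_nonzero_pair(self):
        f = np.zeros((7, 2))
        f[0] = (1, 0)
        f[1] = (1, 1)
        # cos^2 between the only nonzero pair = 1/2; mean over 21 pairs
        expected = 0.5 / 21
        assert appearance_separation_loss(cf.FeatureSet(f, L_a=2)) == pytest.approx(expected)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = rng.normal(size=(7, 4))
            v = appearance_separation_loss(f, L_a=3)
            assert 0.0 <= v <= 1.0

    def test_empty_appearance_part_warns_and_returns_zero(self, caplog):
        f = np.random.default_rng(4).normal(size=(7, 3))
        with caplog.at_level("WARNING"):
            assert appearance_separation_loss(f, L_a=0) == 0.0
        assert "appearance" in caplog.text

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(2, 7, 4))
        L_a = 3
        g = appearance_separation_grad(feats, L_a)
        eps = 1e-6

        def batch_loss(f):
            return np.mean(
                [appearance_separation_loss(f[b], L_a=L_a) for b in range(len(f))]
            )

        for _ in range(15):
            idx = tuple(rng.integers(s) for s in feats.shape)
            fp = feats.copy(); fp[idx] += eps
            fm = feats.copy(); fm[idx] -= eps
            num = (batch_loss(fp) - batch_loss(fm)) / (2 * eps)
            assert g[idx] == pytest.approx(num, abs=1e-6)


class TestTotalLoss:
    def test_reduces_to_main_ce_when_lambdas_zero(self):
        main = cf.DiagnosisProb(0.3, 0.7)
        sec = [cf.DiagnosisProb(0.5, 0.5)] * 7
        w = cf.LossWeights(0.0, 0.0, 0.0)
        fs = cf.FeatureSet(np.random.default_rng(6).normal(size=(7, 4)), L_a=2)
        loss = cf.total_loss(main, sec, "MCN", fs, 2, w)
        assert loss == pytest.approx(-np.log(0.7))

    def test_uniform_prediction_costs_ln2(self):
        main = cf.DiagnosisProb(0.5, 0.5)
        loss = cf.total_loss(main, None, "SCN", None, 0, cf.LossWeights(0, 0, 0))
        assert loss == pytest.approx(np.log(2), abs=1e-12)

    def test_extra_terms_are_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            main = cf.DiagnosisProb(0.4, 0.6)
            sec = [cf.DiagnosisProb(p, 1 - p) for p in rng.uniform(0.01, 0.99, 7)]
            fs = cf.FeatureSet(rng.normal(size=(7, 5)), L_a=2)
            full = cf.total_loss(main, sec, "MCN", fs, 2, cf.LossWeights(1.0, 0.1, 0.1))
            base = cf.total_loss(main, None, "MCN", None, 2, cf.LossWeights(0, 0, 0))
            assert full >= base

    def test_finite_even_at_zero_probability(self):
        loss = cross_entropy(cf.DiagnosisProb(1.0, 0.0), "MCN")
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))

    def test_invalid_label_rejected(self):
        with pytest.raises(cf.ValidationError):
            cross_entropy(cf.DiagnosisProb(0.5, 0.5), "IPMN")


class TestTrainModel:
    MC = cf.ModelConfig(backbone="tiny", D=8, method="SUM", L_a=0, hidden=16)

    def test_zero_epochs_returns_initial_weights(self, separable_packs):
        tc = cf.TrainConfig(epochs=0, seed=0)
        fit = cf.FusionModel(separable_packs[:8], self.MC, tc).fit()
        init = cf.FusionNetwork(self.MC, seed=0)
        for (l1, n1), (l2, n2) in zip(
            fit.network.param_refs(), init.param_refs()
        ):
            np.testing.assert_array_equal(l1.params[n1], l2.params[n2])
        assert len(fit.loss_trace) == 1

    def test_deterministic_given_seed(self, separable_packs):
        tc = cf.TrainConfig(epochs=2, batch_size=8, seed=3)
        f1 = cf.FusionModel(separable_packs[:16], self.MC, tc).fit()
        f2 = cf.FusionModel(separable_packs[:16], self.MC, tc).fit()
        assert abs(f1.final_loss - f2.final_loss) <= 1e-10
        for (l1, n1), (l2, n2) in zip(f1.network.param_refs(), f2.network.param_refs()):
            np.testing.assert_array_equal(l1.params[n1], l2.params[n2])

    def test_empty_training_set_rejected(self):
        with pytest.raises(cf.ValidationError):
            cf.FusionModel([], self.MC, cf.TrainConfig())

    def test_learns_linearly_separable_task(self, separable_packs):
        """The network reaches >0.95 training accuracy on an intensity-
        separable task; a logistic-regression oracle on per-modality mean
        intensities confirms the task is separable at that level."""
        from sklearn.linear_model import LogisticRegression

        X = np.stack([p.slices.mean(axis=(1, 2)) for p in separable_packs])
        y = np.array([1 if p.label == "MCN" else 0 for p in separable_packs])
        oracle = LogisticRegression().fit(X, y)
        assert oracle.score(X, y) > 0.95

        tc = cf.TrainConfig(epochs=15, batch_size=8, learning_rate=2e-3, seed=0)
        fit = cf.FusionModel(separable_packs, self.MC, tc).fit()
        assert fit.training_accuracy() > 0.95

    def test_loss_decreases_over_epochs(self):
        """Full-training-set loss is non-increasing epoch over epoch for a
        small learning rate, across seeds."""
        for seed in range(3):
            packs = make_separable_packs(n_per_class=8, seed=seed)
            tc = cf.TrainConfig(epochs=5, batch_size=8, learning_rate=1e-3, seed=seed)
            fit = cf.FusionModel(packs, self.MC, tc).fit()
            diffs = fit.loss_trace["total"].diff().dropna()
            assert (diffs <= 1e-9).all(), fit.loss_trace

    def test_content_constraint_shrinks_under_training(self):
        """With a dominant content weight, the content-consistency term falls."""
        packs = make_separable_packs(n_per_class=8, seed=1)
        mc = cf.ModelConfig(backbone="tiny", D=8, method="DIS", L_a=4, hidden=16)
        tc = cf.TrainConfig(epochs=6, batch_size=8, learning_rate=2e-3, seed=0)
        w = cf.LossWeights(lambda_aux=0.0, lambda_content=5.0, lambda_appearance=0.0)
        fit = cf.FusionModel(packs, mc, tc, w).fit()
        trace = fit.loss_trace
        assert trace["content"].iloc[-1] < trace["content"].iloc[0]

    def test_train_model_wrapper_and_summary(self, separable_packs):
        tc = cf.TrainConfig(epochs=1, batch_size=8, seed=0)
        net, trace = cf.train_model(separable_packs[:8], self.MC, tc)
        assert len(trace) == 2
        fit = cf.FusionModel(separable_packs[:8], self.MC, tc).fit()
        text = fit.summary()
        assert "training accuracy" in text and "loss trace" in text
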