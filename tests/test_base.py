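"""Base learners: margin classifier, boosted stumps, and the per-source
training regimen."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from pogo import (
    AnnotationSet,
    PipelineConfig,
    ProteinSet,
    align_bundle,
    cross_validate,
    predict_base,
    train_boosted_linear,
    train_margin_classifier,
)
from pogo.base import fit_source_model
from pogo.io import BINARY_SPARSE, FeatureSource


class TestMarginClassifier:
    def test_separable_toy_set_training_error_zero(self):
        X = np.array([[1, 0], [1, 1], [0, 0], [0, 1]])
        y = np.array([1, 1, 0, 0])
        model = train_margin_classifier(X, y, seed=0)
        dec, _ = predict_base(model, X)
        assert dec.tolist() == y.tolist()

    def test_all_zero_features_predict_majority(self):
        X = np.zeros((6, 3))
        y = np.array([1, 1, 1, 1, 0, 0])
        model = train_margin_classifier(X, y, seed=0)
        dec, _ = predict_base(model, np.zeros((4, 3)))
        assert dec.tolist() == [1, 1, 1, 1]

    def test_retrain_same_seed_identical_decisions(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 10)) < 0.3).astype(float)
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        probe = (rng.random((15, 10)) < 0.3).astype(float)
        a, _ = predict_base(train_margin_classifier(X, y, seed=9), probe)
        b, _ = predict_base(train_margin_classifier(X, y, seed=9), probe)
        assert a.tolist() == b.tolist()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_margin_classifier(np.ones((3, 2)), np.ones(3))

    def test_dimensionality_mismatch_rejected(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = train_margin_classifier(X, np.array([0, 1]), seed=0)
        with pytest.raises(ValueError, match="features"):
            predict_base(model, np.ones((2, 5)))


class TestBoostedLinear:
    def test_separable_data_reaches_zero_error(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 5))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
        model = train_boosted_linear(X, y, rounds=50, seed=0)
        dec, _ = predict_base(model, X)
        assert (dec == y).all()

    def test_perfect_first_stump_gives_single_learner(self):
        X = np.linspace(0, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0.5).astype(int)
        model = train_boosted_linear(X, y, rounds=50, seed=0)
        assert len(model.stumps) == 1
        dec, _ = predict_base(model, X)
        assert (dec == y).all()

    def test_weights_renormalized_each_round(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        model = train_boosted_linear(X, y, rounds=20, seed=0)
        for s in model.metadata["weight_sums"]:
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_invalid_rounds_rejected(self):
        with pytest.raises(ValueError):
            train_boosted_linear(np.ones((4, 2)), np.array([0, 1, 0, 1]), rounds=0)

    def test_decisions_agree_with_score_sign(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.4).astype(int)
        y[:2] = [0, 1]
        model = train_boosted_linear(X, y, rounds=15, seed=0)
        probe = rng.normal(size=(20, 3))
        dec, scores = predict_base(model, probe)
        assert (dec == (scores > 0).astype(int)).all()

    def test_exponential_loss_nonincreasing_and_error_reduced(self):
        """The AdaBoost training bound: mean exp(-y f(x)) shrinks every
        round; the final 0/1 training error never exceeds round one's."""
        for s in range(20):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(40, 6))
            w = rng.normal(size=6)
            y = (X @ w + rng.normal(scale=1.5, size=40) > 0).astype(int)
            ys = np.where(y == 1, 1, -1)
            model = train_boosted_linear(X, y, rounds=30, seed=s)
            losses = [
                np.mean(np.exp(-ys * model.decision_scores(X, n_rounds=t)))
                for t in range(1, len(model.stumps) + 1)
            ]
            assert all(
                b <= a + 1e-9 for a, b in zip(losses, losses[1:])
            )
            err = lambda t: np.mean(
                (model.decision_scores(X, n_rounds=t) > 0).astype(int) != y
            )
            assert err(len(model.stumps)) <= err(1) + 1e-12


class TestSourceRegimen:
    def _binary_source(self, X, name="interpro", ids=None):
        return FeatureSource(
            name=name, matrix=sp.csr_matrix(X.astype(np.int8)),
            kind=BINARY_SPARSE,
            vocabulary=[f"f{j}" for j in range(X.shape[1])],
            protein_ids=ids or [f"p{i}" for i in range(X.shape[0])],
        )

    def test_binary_regimen_records_undersampling_and_selection(self):
        rng = np.random.default_rng(7)
        X = (rng.random((30, 12)) < 0.3).astype(int)
        y = (np.arange(30) < 10).astype(int)
        source = self._binary_source(X)
        model = fit_source_model(
            source, np.arange(30), y, PipelineConfig(), seed=0,
            undersampled=True,
        )
        assert model.metadata["undersampled"] is True
        assert model.metadata["selection"] is True
        assert model.kind == "max-margin"

    def test_numeric_regimen_skips_both(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 5))
        y = (np.arange(30) < 6).astype(int)
        source = FeatureSource(
            name="biochem", matrix=X, kind="numeric-dense",
            vocabulary=[f"d{j}" for j in range(5)],
            protein_ids=[f"p{i}" for i in range(30)],
        )
        model = fit_source_model(
            source, np.arange(30), y, PipelineConfig(), seed=0,
            undersampled=False,
        )
        assert model.metadata["undersampled"] is False
        assert model.metadata["selection"] is False
        assert model.kind == "boosted-linear"
        assert model.scaler_mean is not None  # training-fold standardization

    def test_single_informative_feature_perfect_under_cv(self):
        """A lone perfectly label-aligned binary feature yields F = 1 for
        the margin classifier in 10-fold CV."""
        n = 60
        ids = [f"p{i:02d}" for i in range(n)]
        y = (np.arange(n) % 3 == 0).astype(int)
        rng = np.random.default_rng(11)
        X = (rng.random((n, 6)) < 0.2).astype(int)
        X[:, 0] = y
        ann = AnnotationSet.from_triples([
            (ids[i], "GO:0000001", "IDA") for i in range(n) if y[i]
        ])
        bundle = align_bundle(
            ProteinSet(ids=ids), ann, [self._binary_source(X, ids=ids)]
        )
        report = cross_validate(
            bundle, PipelineConfig(), seed=0, folds=10, classifier="interpro"
        )
        assert report.per_term["f_measure"].iloc[0] == pytest.approx(1.0)
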