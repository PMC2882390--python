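"""Combiner protocol: splitting, cross-training, the Naïve Bayes
meta-learner, and per-term classifier assembly."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from pogo import (
    AnnotationSet,
    PipelineConfig,
    ProteinSet,
    align_bundle,
    build_meta_dataset,
    combiner_split,
    load_models,
    predict_terms,
    save_models,
    train_naive_bayes,
    train_term_classifier,
)
from pogo.io import BINARY_SPARSE, FeatureSource
from pogo.meta import CombinerSplit, MetaDataset


class TestCombinerSplit:
    def test_equal_halving_900(self):
        ids = [f"p{i}" for i in range(900)]
        split = combiner_split(ids, seed=0)
        assert len(split.t1) == len(split.t2) == 450
        assert set(split.t1) | set(split.t2) == set(ids)
        assert not set(split.t1) & set(split.t2)

    def test_odd_size_differs_by_one(self):
        split = combiner_split([f"p{i}" for i in range(9)], seed=1)
        assert sorted([len(split.t1), len(split.t2)]) == [4, 5]

    def test_same_seed_identical(self):
        ids = [f"p{i}" for i in range(40)]
        a = combiner_split(ids, seed=3)
        b = combiner_split(ids, seed=3)
        assert a.t1 == b.t1 and a.t2 == b.t2

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            combiner_split(["p0"], seed=0)


def _meta_dataset(X, y):
    n = len(y)
    ids = [f"p{i}" for i in range(n)]
    return MetaDataset(
        protein_ids=ids,
        source_names=[f"s{j}" for j in range(X.shape[1])],
        decisions=np.asarray(X, dtype=int),
        scores=np.asarray(X, dtype=float),
        labels=np.asarray(y, dtype=int),
        provenance=np.full((n, X.shape[1]), "T1", dtype=object),
        split=CombinerSplit(t1=ids[: n // 2], t2=ids[n // 2:]),
    )


class TestNaiveBayes:
    def test_hand_counted_smoothed_conditionals(self):
        # class +: 3 of 4 rows with f=1; class -: 1 of 6 rows with f=1
        X = np.array([[1]] * 3 + [[0]] + [[1]] + [[0]] * 5)
        y = np.array([1] * 4 + [0] * 6)
        model = train_naive_bayes(_meta_dataset(X, y), smoothing=1.0)
        assert model.feat_prob[1, 0] == pytest.approx(4 / 6)
        assert model.feat_prob[0, 0] == pytest.approx(2 / 8)
        assert model.priors.tolist() == [0.6, 0.4]

    def test_symmetric_input_posterior_half(self):
        X = np.array([[1, 0], [0, 1]])
        y = np.array([1, 0])
        model = train_naive_bayes(_meta_dataset(X, y))
        post = model.predict_posterior(np.array([[1, 1]]))
        assert post[0, 1] == pytest.approx(0.5)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(2)
        X = (rng.random((30, 4)) < 0.4).astype(int)
        y = (rng.random(30) < 0.3).astype(int)
        y[:2] = [0, 1]
        model = train_naive_bayes(_meta_dataset(X, y))
        post = model.predict_posterior((rng.random((10, 4)) < 0.5).astype(int))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_conditional_probability_rows_are_proper(self):
        rng = np.random.default_rng(3)
        X = (rng.random((20, 4)) < 0.5).astype(int)
        y = (np.arange(20) < 8).astype(int)
        model = train_naive_bayes(_meta_dataset(X, y))
        assert ((model.feat_prob > 0) & (model.feat_prob < 1)).all()

    def test_single_class_degenerate_model(self, caplog):
        X = np.array([[1], [0], [1]])
        y = np.array([1, 1, 1])
        with caplog.at_level("WARNING"):
            model = train_naive_bayes(_meta_dataset(X, y))
        assert model.degenerate_class == 1
        post = model.predict_posterior(np.array([[0], [1]]))
        assert (post[:, 1] == 1.0).all()

    def test_gaussian_mode_on_scores(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(2, 1, (15, 3)), rng.normal(-2, 1, (15, 3))])
        y = np.array([1] * 15 + [0] * 15)
        model = train_naive_bayes(_meta_dataset(X, y), mode="scores")
        assert model.kind == "gaussian"
        post = model.predict_posterior(np.array([[2.0, 2.0, 2.0]]))
        assert post[0, 1] > 0.9


def _mini_bundle(n=16, n_pos=6, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"p{i:02d}" for i in range(n)]
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    X = (rng.random((n, 8)) < 0.15).astype(np.int8)
    X[y == 1, 0] = 1
    src = FeatureSource(
        name="interpro", matrix=sp.csr_matrix(X), kind=BINARY_SPARSE,
        vocabulary=[f"f{j}" for j in range(8)], protein_ids=ids,
    )
    ann = AnnotationSet.from_triples(
        [(ids[i], "GO:0000001", "IDA") for i in range(n) if y[i]]
    )
    return align_bundle(ProteinSet(ids=ids), ann, [src])


class TestBuildMetaDataset:
    def test_shape_and_out_of_sample_provenance(self, tiny_bundle):
        term = tiny_bundle.annotations.terms()[0]
        split = combiner_split(list(tiny_bundle.proteins.ids), seed=0)
        meta = build_meta_dataset(
            tiny_bundle, term, split, PipelineConfig(), seed=1
        )
        n = len(tiny_bundle.proteins)
        assert meta.decisions.shape == (n, 4)
        assert meta.source_names == ["interpro", "blast", "biochem", "structure"]
        t1 = set(split.t1)
        for i, pid in enumerate(meta.protein_ids):
            expected = "T2" if pid in t1 else "T1"
            for k in range(4):
                assert meta.provenance[i, k] in (expected, "fill")

    def test_positives_confined_to_one_half_triggers_fill(self, caplog):
        bundle = _mini_bundle()
        positives = sorted(bundle.annotations.proteins_for("GO:0000001"))
        negatives = [p for p in bundle.proteins.ids if p not in positives]
        # all positives in T1: the T2-trained models see a single class
        split = CombinerSplit(
            t1=positives + negatives[: 8 - len(positives)],
            t2=negatives[8 - len(positives):],
        )
        with caplog.at_level("WARNING"):
            meta = build_meta_dataset(
                bundle, "GO:0000001", split, PipelineConfig(), seed=0
            )
        t1_rows = [i for i, p in enumerate(meta.protein_ids) if p in set(split.t1)]
        assert all(meta.provenance[i, 0] == "fill" for i in t1_rows)
        assert any("single-class" in r.message for r in caplog.records)

    def test_decision_meta_features_are_binary(self, tiny_bundle):
        term = tiny_bundle.annotations.terms()[1]
        split = combiner_split(list(tiny_bundle.proteins.ids), seed=2)
        meta = build_meta_dataset(
            tiny_bundle, term, split, PipelineConfig(), seed=3
        )
        assert set(np.unique(meta.decisions)) <= {0, 1}


class TestTermClassifier:
    def test_planted_positives_recovered(self, tiny_bundle):
        term = tiny_bundle.annotations.terms()[0]
        tc = train_term_classifier(tiny_bundle, term, PipelineConfig(), 5)
        predictions = predict_terms([tc], tiny_bundle)
        predicted = {p for p, t, _ in predictions.records if t == term}
        truth = tiny_bundle.annotations.proteins_for(term)
        jaccard = len(predicted & truth) / len(predicted | truth)
        assert jaccard > 0.8

    def test_term_independence(self, tiny_bundle):
        terms = tiny_bundle.annotations.terms()[:2]
        cfg = PipelineConfig()
        tc_a = train_term_classifier(tiny_bundle, terms[0], cfg, 7)
        tc_b = train_term_classifier(tiny_bundle, terms[1], cfg, 8)
        alone = {
            (p, t) for p, t, _ in predict_terms([tc_a], tiny_bundle).records
        }
        together = {
            (p, t)
            for p, t, _ in predict_terms([tc_a, tc_b], tiny_bundle).records
            if t == terms[0]
        }
        assert alone == together

    def test_serialization_round_trip_identical_predictions(
        self, tiny_bundle, tmp_path
    ):
        term = tiny_bundle.annotations.terms()[0]
        tc = train_term_classifier(tiny_bundle, term, PipelineConfig(), 11)
        save_models([tc], str(tmp_path / "models"))
        loaded = load_models(str(tmp_path / "models"))
        assert len(loaded) == 1
        np.testing.assert_array_equal(
            tc.posterior(tiny_bundle), loaded[0].posterior(tiny_bundle)
        )

    def test_empty_model_set_empty_predictions(self, tiny_bundle):
        assert len(predict_terms([], tiny_bundle)) == 0

    def test_missing_source_named(self, tiny_bundle):
        term = tiny_bundle.annotations.terms()[0]
        tc = train_term_classifier(tiny_bundle, term, PipelineConfig(), 5)
        stripped = align_bundle(
            tiny_bundle.proteins, tiny_bundle.annotations,
            [s for s in tiny_bundle.sources if s.name != "structure"],
        )
        with pytest.raises(KeyError, match="structure"):
            predict_terms([tc], stripped)
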