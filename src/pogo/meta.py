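"""Combiner meta-learning.

The training proteins T for a GO term are split into equal halves T1 and
T2.  Each evidence source's base learner is trained on T1 (under its own
regimen) and used to classify T2, then the roles are reversed, so every
training protein receives one strictly out-of-sample decision per source.
Those decisions become the features of a per-term meta-dataset — kept
unbalanced — on which a Naïve Bayes meta-classifier is trained.  For
deployment the base models are retrained on all of T.

Provenance of every meta-feature value (which half trained the producing
model) is tracked and asserted, so the out-of-sample discipline is checked
on every run rather than assumed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .base import (
    BOOSTED_LINEAR,
    MAX_MARGIN,
    BaseModel,
    Stump,
    fit_source_model,
    predict_base,
)
from .config import PipelineConfig
from .datasets import TermDataset, undersample
from .io import BINARY_SPARSE, AnnotationSet, DatasetBundle

log = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2^31) from one seed."""
    ss = np.random.SeedSequence(int(seed) % (2**31))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Combiner split
# ---------------------------------------------------------------------------

@dataclass
class CombinerSplit:
    """A disjoint equal halving of the training proteins."""

    t1: list[str]
    t2: list[str]

    def __post_init__(self) -> None:
        if set(self.t1) & set(self.t2):
            raise ValueError("T1 and T2 overlap")
        if abs(len(self.t1) - len(self.t2)) > 1:
            raise ValueError("T1 and T2 differ by more than one protein")


def combiner_split(training_ids: list[str], seed: int) -> CombinerSplit:
    """Uniform random halving of the training set, seed-controlled."""
    n = len(training_ids)
    if n < 2:
        raise ValueError("need at least 2 training proteins to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    t1 = [training_ids[i] for i in sorted(perm[:half])]
    t2 = [training_ids[i] for i in sorted(perm[half:])]
    return CombinerSplit(t1=t1, t2=t2)


# ---------------------------------------------------------------------------
# meta-dataset construction (cross-training)
# ---------------------------------------------------------------------------

@dataclass
class MetaDataset:
    """Out-of-sample base decisions for every training protein.

    ``provenance[i, k]`` records which half trained the model that produced
    row i's value for source k ("T1", "T2", or "fill" for the
    majority-class fallback when a half was untrainable for that source).
    """

    protein_ids: list[str]
    source_names: list[str]
    decisions: np.ndarray  # n × n_sources, {0,1}
    scores: np.ndarray     # n × n_sources, raw margins / votes
    labels: np.ndarray     # n, {0,1}
    provenance: np.ndarray  # n × n_sources of str
    split: CombinerSplit = None

    def X(self, mode: str = "decisions") -> np.ndarray:
        return self.decisions if mode == "decisions" else self.scores


def verify_provenance(meta: MetaDataset) -> None:
    """Assert the out-of-sample discipline: no row's value may come from a
    model whose training half contained that protein."""
    t1 = set(meta.split.t1)
    t2 = set(meta.split.t2)
    for i, pid in enumerate(meta.protein_ids):
        for k in range(len(meta.source_names)):
            src_half = meta.provenance[i, k]
            if src_half == "fill":
                continue
            half = t1 if src_half == "T1" else t2
            if pid in half:
                raise AssertionError(
                    f"meta-feature for {pid} produced by a model trained on "
                    f"its own half ({src_half})"
                )


def _train_half_model(
    bundle: DatasetBundle,
    source_idx: int,
    half_ids: list[str],
    labels_by_id: dict[str, int],
    config: PipelineConfig,
    seed: int,
) -> BaseModel | None:
    """Train one source's base model on one half; None if untrainable."""
    source = bundle.sources[source_idx]
    index = bundle.proteins.index()
    positives = [p for p in half_ids if labels_by_id[p] == 1]
    negatives = [p for p in half_ids if labels_by_id[p] == 0]
    if not positives or not negatives:
        return None
    if source.kind == BINARY_SPARSE:
        ds = TermDataset(go_term="half", positives=positives, negatives=negatives)
        ds = undersample(ds, seed)
        train_ids = ds.positives + ds.negatives
        undersampled = True
    else:
        train_ids = positives + negatives
        undersampled = False
    rows = np.array([index[p] for p in train_ids])
    y = np.array([labels_by_id[p] for p in train_ids])
    if len(np.unique(y)) < 2:
        return None
    return fit_source_model(source, rows, y, config, seed, undersampled)


def build_meta_dataset(
    bundle: DatasetBundle,
    term: str,
    split: CombinerSplit,
    config: PipelineConfig,
    seed: int,
) -> MetaDataset:
    """Cross-train the base classifiers over the Combiner halves and
    assemble the per-term meta-dataset.

    The assembled meta-dataset is NOT undersampled here: the unbalanced
    meta-data is the selected configuration (balancing, when requested, is
    applied by the meta-trainer).
    """
    index = bundle.proteins.index()
    all_ids = split.t1 + split.t2
    positives = bundle.annotations.proteins_for(term)
    labels_by_id = {p: (1 if p in positives else 0) for p in all_ids}

    n = len(all_ids)
    n_src = len(bundle.sources)
    decisions = np.zeros((n, n_src), dtype=int)
    scores = np.zeros((n, n_src))
    provenance = np.empty((n, n_src), dtype=object)
    row_of = {p: i for i, p in enumerate(all_ids)}

    seeds = _child_seeds(seed, 2 * n_src)
    for k, source in enumerate(bundle.sources):
        for j, (train_ids, pred_ids, half_name) in enumerate(
            ((split.t1, split.t2, "T1"), (split.t2, split.t1, "T2"))
        ):
            model = _train_half_model(
                bundle, k, train_ids, labels_by_id, config, seeds[2 * k + j]
            )
            pred_rows = np.array([index[p] for p in pred_ids])
            out_rows = [row_of[p] for p in pred_ids]
            if model is None:
                majority = int(
                    np.mean([labels_by_id[p] for p in train_ids]) >= 0.5
                )
                log.warning(
                    "%s/%s: half %s single-class; meta column filled with "
                    "majority decision %d", term, source.name, half_name, majority,
                )
                decisions[out_rows, k] = majority
                scores[out_rows, k] = 1.0 if majority == 1 else -1.0
                provenance[out_rows, k] = "fill"
                continue
            dec, sc = predict_base(model, source.matrix[pred_rows])
            decisions[out_rows, k] = dec
            scores[out_rows, k] = sc
            provenance[out_rows, k] = half_name

    meta = MetaDataset(
        protein_ids=list(all_ids),
        source_names=bundle.source_names(),
        decisions=decisions,
        scores=scores,
        labels=np.array([labels_by_id[p] for p in all_ids]),
        provenance=provenance,
        split=split,
    )
    verify_provenance(meta)
    return meta


# ---------------------------------------------------------------------------
# Naïve Bayes meta-learner
# ---------------------------------------------------------------------------

@dataclass
class NaiveBayesModel:
    """Bernoulli (decision features) or Gaussian (score features) Naïve
    Bayes over the per-source base outputs.

    ``degenerate_class`` short-circuits prediction when the meta-training
    labels held a single class.
    """

    kind: str  # "bernoulli" | "gaussian"
    priors: np.ndarray          # (2,)
    feat_prob: np.ndarray | None = None   # (2, n_features) P(f=1 | class)
    means: np.ndarray | None = None       # (2, n_features)
    variances: np.ndarray | None = None
    smoothing: float = 1.0
    degenerate_class: int | None = None

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        """Posterior P(class | x) per row, columns (negative, positive)."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.degenerate_class is not None:
            out = np.zeros((n, 2))
            out[:, self.degenerate_class] = 1.0
            return out
        log_post = np.tile(np.log(self.priors), (n, 1))
        if self.kind == "bernoulli":
            p = self.feat_prob  # (2, d)
            for c in range(2):
                log_post[:, c] += (
                    X @ np.log(p[c]) + (1.0 - X) @ np.log(1.0 - p[c])
                )
        else:
            for c in range(2):
                var = self.variances[c]
                log_post[:, c] += np.sum(
                    -0.5 * np.log(2 * np.pi * var)
                    - (X - self.means[c]) ** 2 / (2 * var),
                    axis=1,
                )
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


@dataclass
class MarginMetaModel:
    """Linear max-margin meta-learner (the SVM comparison arm); exposes the
    same posterior surface with a hard 0/1 posterior."""

    model: BaseModel

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        dec, _ = predict_base(self.model, np.asarray(X, dtype=float))
        out = np.zeros((len(dec), 2))
        out[np.arange(len(dec)), dec] = 1.0
        return out


def train_naive_bayes(
    meta: MetaDataset,
    smoothing: float = 1.0,
    mode: str = "decisions",
) -> NaiveBayesModel:
    """Fit the Naïve Bayes meta-model on the (unbalanced) meta-dataset.

    Class priors are the class frequencies.  Decision features get
    Bernoulli conditionals with additive smoothing alpha:
    P(f=1|c) = (count + alpha) / (n_c + 2 alpha).  Score features get
    Gaussian conditionals with a variance floor.
    """
    y = meta.labels
    X = meta.X(mode)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        only = int(classes[0])
        log.warning(
            "meta labels are single-class (%d); degenerate always-%d model",
            only, only,
        )
        priors = np.zeros(2)
        priors[only] = 1.0
        return NaiveBayesModel(
            kind="bernoulli" if mode == "decisions" else "gaussian",
            priors=priors, smoothing=smoothing, degenerate_class=only,
        )
    n = len(y)
    priors = np.array([(y == 0).sum() / n, (y == 1).sum() / n])
    if mode == "decisions":
        d = X.shape[1]
        feat_prob = np.zeros((2, d))
        for c in range(2):
            Xc = X[y == c]
            feat_prob[c] = (Xc.sum(axis=0) + smoothing) / (
                len(Xc) + 2.0 * smoothing
            )
        return NaiveBayesModel(
            kind="bernoulli", priors=priors, feat_prob=feat_prob,
            smoothing=smoothing,
        )
    means = np.zeros((2, X.shape[1]))
    variances = np.zeros((2, X.shape[1]))
    for c in range(2):
        Xc = X[y == c]
        means[c] = Xc.mean(axis=0)
        variances[c] = np.maximum(Xc.var(axis=0), 1e-9)
    return NaiveBayesModel(
        kind="gaussian", priors=priors, means=means, variances=variances,
        smoothing=smoothing,
    )


# ---------------------------------------------------------------------------
# per-term classifier
# ---------------------------------------------------------------------------

@dataclass
class TermClassifier:
    """Everything needed to score one GO term on new proteins: the four
    deployed base models (retrained on all of T) plus the meta-model."""

    go_term: str
    base_models: dict[str, BaseModel]
    meta_model: "NaiveBayesModel | MarginMetaModel"
    source_order: list[str]
    config: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    def posterior(self, bundle: DatasetBundle) -> np.ndarray:
        """Positive-class posterior for every bundle protein."""
        feats = []
        for name in self.source_order:
            model = self.base_models[name]
            source = bundle.source(name)  # KeyError names the missing source
            dec, sc = predict_base(model, source.matrix)
            feats.append(dec if self.config.meta_features == "decisions" else sc)
        X = np.column_stack(feats)
        return self.meta_model.predict_posterior(X)[:, 1]


def _balance_meta(meta: MetaDataset, seed: int) -> MetaDataset:
    """Undersample the meta-dataset (the balanced comparison arm)."""
    pos = [p for p, l in zip(meta.protein_ids, meta.labels) if l == 1]
    neg = [p for p, l in zip(meta.protein_ids, meta.labels) if l == 0]
    if not pos or len(neg) <= len(pos):
        return meta
    ds = undersample(
        TermDataset(go_term="meta", positives=pos, negatives=neg), seed
    )
    keep = set(ds.positives + ds.negatives)
    rows = [i for i, p in enumerate(meta.protein_ids) if p in keep]
    return MetaDataset(
        protein_ids=[meta.protein_ids[i] for i in rows],
        source_names=meta.source_names,
        decisions=meta.decisions[rows],
        scores=meta.scores[rows],
        labels=meta.labels[rows],
        provenance=meta.provenance[rows],
        split=meta.split,
    )


def train_term_classifier(
    bundle: DatasetBundle,
    term: str,
    config: PipelineConfig,
    seed: int,
) -> TermClassifier:
    """Full Combiner training for one GO term.

    Splits T, cross-trains the base classifiers, fits the meta-model on the
    out-of-sample decisions, then retrains the base models on all of T for
    deployment.
    """
    seeds = _child_seeds(seed, 3 + len(bundle.sources))
    split = combiner_split(list(bundle.proteins.ids), seeds[0])
    meta = build_meta_dataset(bundle, term, split, config, seeds[1])

    meta_fit = meta
    if config.meta_balanced:
        meta_fit = _balance_meta(meta, seeds[2])
    if config.meta_learner == "naive_bayes":
        meta_model: "NaiveBayesModel | MarginMetaModel" = train_naive_bayes(
            meta_fit, smoothing=config.meta_smoothing, mode=config.meta_features
        )
    else:
        from .base import train_margin_classifier

        X = meta_fit.X(config.meta_features).astype(float)
        y = meta_fit.labels
        if len(np.unique(y)) < 2:
            meta_model = train_naive_bayes(
                meta_fit, smoothing=config.meta_smoothing,
                mode=config.meta_features,
            )
        else:
            meta_model = MarginMetaModel(
                train_margin_classifier(X, y, config=config, seed=seeds[2])
            )

    # deployed base models: retrained on all of T
    index = bundle.proteins.index()
    positives = bundle.annotations.proteins_for(term)
    labels_by_id = {p: (1 if p in positives else 0) for p in bundle.proteins.ids}
    base_models: dict[str, BaseModel] = {}
    for k, source in enumerate(bundle.sources):
        model = _train_half_model(
            bundle, k, list(bundle.proteins.ids), labels_by_id, config,
            seeds[3 + k],
        )
        if model is None:
            # single-class training data: constant majority decision
            majority = int(np.mean(list(labels_by_id.values())) >= 0.5)
            model = BaseModel(
                source=source.name,
                kind=MAX_MARGIN if source.kind == BINARY_SPARSE else BOOSTED_LINEAR,
                n_input_features=source.n_features,
                coef=np.zeros(0) if source.kind == BINARY_SPARSE else None,
                intercept=1.0 if majority == 1 else -1.0,
                metadata={"degenerate": True},
            )
        base_models[source.name] = model

    return TermClassifier(
        go_term=term,
        base_models=base_models,
        meta_model=meta_model,
        source_order=bundle.source_names(),
        config=config,
        seed=int(seed),
    )


def predict_terms(
    model_set: list[TermClassifier], bundle: DatasetBundle
) -> AnnotationSet:
    """Apply every term classifier to the bundle; a term is assigned when
    its positive posterior exceeds the decision threshold.  Proteins may
    receive zero or many terms."""
    triples: list[tuple[str, str, str]] = []
    for tc in model_set:
        post = tc.posterior(bundle)
        thr = tc.config.decision_threshold
        for pid, p in zip(bundle.proteins.ids, post):
            if p > thr:
                triples.append((pid, tc.go_term, "PoGO"))
    return AnnotationSet.from_triples(triples)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _jsonable(x: Any) -> Any:
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _base_to_dict(m: BaseModel) -> dict:
    return _jsonable({
        "source": m.source,
        "kind": m.kind,
        "n_input_features": m.n_input_features,
        "feature_indices": m.feature_indices,
        "coef": m.coef,
        "intercept": m.intercept,
        "stumps": [[s.feature, s.threshold, s.polarity] for s in m.stumps],
        "alphas": m.alphas,
        "scaler_mean": m.scaler_mean,
        "scaler_std": m.scaler_std,
        "metadata": m.metadata,
    })


def _base_from_dict(d: dict) -> BaseModel:
    def arr(key, dtype=float):
        return None if d.get(key) is None else np.asarray(d[key], dtype=dtype)

    return BaseModel(
        source=d["source"],
        kind=d["kind"],
        n_input_features=int(d["n_input_features"]),
        feature_indices=arr("feature_indices", int),
        coef=arr("coef"),
        intercept=float(d["intercept"]),
        stumps=[Stump(int(f), float(t), int(p)) for f, t, p in d["stumps"]],
        alphas=arr("alphas") if d.get("alphas") is not None else np.zeros(0),
        scaler_mean=arr("scaler_mean"),
        scaler_std=arr("scaler_std"),
        metadata=d.get("metadata", {}),
    )


def save_models(models: list[TermClassifier], out_dir: str) -> None:
    """Write one directory per GO term with a JSON manifest of all fitted
    parameters and hyperparameters."""
    os.makedirs(out_dir, exist_ok=True)
    for tc in models:
        term_dir = os.path.join(out_dir, tc.go_term.replace(":", "_"))
        os.makedirs(term_dir, exist_ok=True)
        mm = tc.meta_model
        if isinstance(mm, MarginMetaModel):
            meta_payload = {"type": "margin", "model": _base_to_dict(mm.model)}
        else:
            meta_payload = _jsonable({
                "type": "naive_bayes",
                "kind": mm.kind,
                "priors": mm.priors,
                "feat_prob": mm.feat_prob,
                "means": mm.means,
                "variances": mm.variances,
                "smoothing": mm.smoothing,
                "degenerate_class": mm.degenerate_class,
            })
        manifest = {
            "go_term": tc.go_term,
            "source_order": tc.source_order,
            "seed": tc.seed,
            "config": tc.config.to_dict(),
            "meta_model": meta_payload,
            "base_models": {
                name: _base_to_dict(m) for name, m in tc.base_models.items()
            },
        }
        with open(os.path.join(term_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)


def load_models(model_dir: str) -> list[TermClassifier]:
    """Read back a model directory written by :func:`save_models`."""
    models: list[TermClassifier] = []
    for entry in sorted(os.listdir(model_dir)):
        manifest_path = os.path.join(model_dir, entry, "manifest.json")
        if not os.path.isfile(manifest_path):
            continue
        with open(manifest_path) as fh:
            d = json.load(fh)
        mp = d["meta_model"]
        if mp["type"] == "margin":
            meta_model: "NaiveBayesModel | MarginMetaModel" = MarginMetaModel(
                _base_from_dict(mp["model"])
            )
        else:
            def arr(key):
                return None if mp.get(key) is None else np.asarray(mp[key])

            meta_model = NaiveBayesModel(
                kind=mp["kind"],
                priors=np.asarray(mp["priors"]),
                feat_prob=arr("feat_prob"),
                means=arr("means"),
                variances=arr("variances"),
                smoothing=mp.get("smoothing", 1.0),
                degenerate_class=mp.get("degenerate_class"),
            )
        models.append(
            TermClassifier(
                go_term=d["go_term"],
                base_models={
                    name: _base_from_dict(bm)
                    for name, bm in d["base_models"].items()
                },
                meta_model=meta_model,
                source_order=list(d["source_order"]),
                config=PipelineConfig.from_dict(d["config"]),
                seed=int(d["seed"]),
            )
        )
    return models
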