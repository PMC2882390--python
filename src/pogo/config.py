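"""Pipeline configuration.

A single :class:`PipelineConfig` travels through dataset construction,
base-classifier training, the Combiner meta-layer and evaluation, so that a
trained model can snapshot exactly the settings it was built with.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: Canonical evidence-source names, in the fixed column order used everywhere.
SOURCE_ORDER = ("interpro", "blast", "biochem", "structure")

#: Binary sparse sources that get undersampling + chi-square selection.
BINARY_SOURCES = ("interpro", "blast", "structure")


@dataclass
class PipelineConfig:
    """Settings for the full per-term training pipeline.

    Parameters
    ----------
    min_proteins:
        Rare-term filter: GO terms annotating fewer than this many distinct
        proteins are removed from the label space (default 10).
    exclude_evidence:
        Evidence codes dropped when reading annotations (default IEA, the
        machine-inferred code).
    selection_policy / selection_k / selection_min_score:
        Chi-square feature selection for the binary sources.  ``top_k`` keeps
        the ``min(selection_k, n_features)`` best-scoring features; the
        ``min_score`` policy keeps features scoring at least
        ``selection_min_score``.
    svm_c:
        Regularization strength of the linear max-margin base learner.
    boost_rounds:
        Maximum AdaBoost rounds for the biochemical-descriptor base learner.
    meta_features:
        ``"decisions"`` feeds the base classifiers' binary decisions to the
        meta-learner (Bernoulli conditionals); ``"scores"`` feeds raw margins
        (Gaussian conditionals).
    meta_learner:
        ``"naive_bayes"`` (default) or ``"margin"`` — the latter reproduces
        the SVM-as-meta comparison arm.
    meta_balanced:
        Undersample the assembled meta-dataset before meta-training.  The
        default ``False`` is the winning unbalanced configuration.
    meta_smoothing:
        Additive smoothing for Bernoulli conditionals.
    decision_threshold:
        Posterior probability above which a term is assigned.
    histidine_positive:
        Count histidine among positively charged residues (pepstats
        convention).
    refilter_after_subset:
        Re-apply the rare-term filter after taxon subsetting.
    undersample_per_fold:
        Redraw the negative undersample inside every CV fold / Combiner half
        (default) instead of once globally.
    """

    min_proteins: int = 10
    exclude_evidence: tuple[str, ...] = ("IEA",)
    selection_policy: str = "top_k"
    selection_k: int = 500
    selection_min_score: float = 0.0
    svm_c: float = 1.0
    boost_rounds: int = 50
    meta_features: str = "decisions"
    meta_learner: str = "naive_bayes"
    meta_balanced: bool = False
    meta_smoothing: float = 1.0
    decision_threshold: float = 0.5
    histidine_positive: bool = True
    refilter_after_subset: bool = False
    undersample_per_fold: bool = True
    annotation_columns: tuple[str, str, str] = ("protein", "go", "evidence")

    def __post_init__(self) -> None:
        if self.selection_policy not in ("top_k", "min_score"):
            raise ValueError(f"unknown selection policy {self.selection_policy!r}")
        if self.meta_features not in ("decisions", "scores"):
            raise ValueError(f"unknown meta_features {self.meta_features!r}")
        if self.meta_learner not in ("naive_bayes", "margin"):
            raise ValueError(f"unknown meta_learner {self.meta_learner!r}")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision_threshold must lie in [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["exclude_evidence"] = list(self.exclude_evidence)
        d["annotation_columns"] = list(self.annotation_columns)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("exclude_evidence", "annotation_columns"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
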