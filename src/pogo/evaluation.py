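"""Evaluation protocols.

Two regimes are provided:

* **per-term 10-fold cross-validation** — each protein sits in exactly one
  test fold; the full pipeline (undersampling, selection, base training,
  Combiner cross-training, meta-training) is refit inside every fold; the
  per-term confusion counts are pooled across folds, per-term sensitivity /
  specificity / F-measure computed from the pooled counts, and the
  arithmetic mean over terms reported (macro-averaging);
* **per-protein hold-out evaluation** — metrics computed for each protein
  individually against the classifier's label space, then averaged over
  proteins.

Per-term classifiers can be gated on their cross-validated F-measure:
poorly performing terms are dropped from the deployable set, trading the
percentage of proteins that receive at least one annotation for the mean
quality of the retained classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import AnnotationSet, DatasetBundle, align_bundle
from .meta import _child_seeds, predict_terms, train_term_classifier

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN (excluded from macro means) when no positives
    were evaluated."""
    if c.tp + c.fn == 0:
        return float("nan")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP); NaN when no negatives were evaluated."""
    if c.tn + c.fp == 0:
        return float("nan")
    return c.tn / (c.tn + c.fp)


def f_measure(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0."""
    if c.tp == 0:
        return 0.0
    precision = c.tp / (c.tp + c.fp)
    recall = c.tp / (c.tp + c.fn)
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-term (or per-protein) metrics plus macro aggregates.

    ``per_term`` columns: term, n_pos, tp, fp, tn, fn, sensitivity,
    specificity, f_measure.  ``predictions`` maps each evaluated protein to
    its predicted term set (collected from the test folds), which gating
    and percent-annotated reporting reuse.
    """

    per_term: pd.DataFrame
    macro_sensitivity: float
    macro_specificity: float
    macro_f: float
    mode: str
    protein_ids: list[str] = field(default_factory=list)
    predictions: dict[str, set[str]] = field(default_factory=dict)
    per_protein: pd.DataFrame | None = None
    n_excluded_terms: int = 0

    def f_of(self, term: str) -> float:
        row = self.per_term[self.per_term["term"] == term]
        return float(row["f_measure"].iloc[0])


def _macro(values: "pd.Series | np.ndarray") -> float:
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def _report_from_counts(
    counts: dict[str, ConfusionCounts],
    n_pos: dict[str, int],
    mode: str,
    protein_ids: list[str],
    predictions: dict[str, set[str]],
) -> EvaluationReport:
    rows = []
    for term in sorted(counts):
        c = counts[term]
        rows.append({
            "term": term, "n_pos": n_pos.get(term, 0),
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "f_measure": f_measure(c),
        })
    per_term = pd.DataFrame(
        rows, columns=["term", "n_pos", "tp", "fp", "tn", "fn",
                       "sensitivity", "specificity", "f_measure"],
    )
    return EvaluationReport(
        per_term=per_term,
        macro_sensitivity=_macro(per_term["sensitivity"]) if len(per_term) else float("nan"),
        macro_specificity=_macro(per_term["specificity"]) if len(per_term) else float("nan"),
        macro_f=_macro(per_term["f_measure"]) if len(per_term) else float("nan"),
        mode=mode,
        protein_ids=protein_ids,
        predictions=predictions,
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _subset_bundle(bundle: DatasetBundle, keep: list[str]) -> DatasetBundle:
    proteins = bundle.proteins.subset(keep)
    annotations = bundle.annotations.restrict_proteins(set(keep))
    return align_bundle(proteins, annotations, bundle.sources, drop_extra=True)


def make_folds(ids: list[str], folds: int, seed: int) -> list[list[str]]:
    """Random partition of proteins into near-equal test folds."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(ids) < folds:
        raise ValueError(f"{len(ids)} proteins cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return [
        sorted(ids[i] for i in part) for part in np.array_split(perm, folds)
    ]


def cross_validate(
    bundle: DatasetBundle,
    config: PipelineConfig | None = None,
    seed: int = 0,
    folds: int = 10,
    classifier: str = "meta",
) -> EvaluationReport:
    """Protein-level k-fold CV of the full pipeline.

    ``classifier`` selects what is evaluated: ``"meta"`` runs the complete
    Combiner + Naïve Bayes system; a source name (e.g. ``"interpro"``)
    evaluates that single-source base classifier alone, trained on the full
    training split of each fold under its own regimen.

    Per-term confusion counts are pooled across folds before metrics are
    computed; the macro means exclude terms whose metric is undefined.
    """
    config = config or PipelineConfig()
    terms = bundle.annotations.terms()
    if not terms:
        raise ValueError("bundle has no annotated terms to evaluate")
    fold_sets = make_folds(list(bundle.proteins.ids), folds, seed)
    fold_seeds = _child_seeds(seed, folds)

    counts: dict[str, ConfusionCounts] = {t: ConfusionCounts() for t in terms}
    n_pos = {t: len(bundle.annotations.proteins_for(t)) for t in terms}
    predictions: dict[str, set[str]] = {p: set() for p in bundle.proteins.ids}

    for fold_idx, test_ids in enumerate(fold_sets):
        test_set = set(test_ids)
        train_ids = [p for p in bundle.proteins.ids if p not in test_set]
        train_bundle = _subset_bundle(bundle, train_ids)
        test_bundle = _subset_bundle(bundle, test_ids)
        term_seeds = _child_seeds(fold_seeds[fold_idx], len(terms))

        if classifier == "meta":
            for t_idx, term in enumerate(terms):
                tc = train_term_classifier(
                    train_bundle, term, config, term_seeds[t_idx]
                )
                post = tc.posterior(test_bundle)
                decided = post > config.decision_threshold
                _accumulate(
                    counts[term], term, decided, test_bundle, predictions
                )
        else:
            from .meta import _train_half_model
            from .base import predict_base

            src_idx = bundle.source_names().index(classifier)
            for t_idx, term in enumerate(terms):
                positives = train_bundle.annotations.proteins_for(term)
                labels_by_id = {
                    p: (1 if p in positives else 0)
                    for p in train_bundle.proteins.ids
                }
                model = _train_half_model(
                    train_bundle, src_idx, list(train_bundle.proteins.ids),
                    labels_by_id, config, term_seeds[t_idx],
                )
                if model is None:
                    decided = np.zeros(len(test_bundle.proteins), dtype=bool)
                else:
                    dec, _ = predict_base(
                        model, test_bundle.sources[src_idx].matrix
                    )
                    decided = dec.astype(bool)
                _accumulate(
                    counts[term], term, decided, test_bundle, predictions
                )

    return _report_from_counts(
        counts, n_pos, mode=f"cv-{classifier}",
        protein_ids=list(bundle.proteins.ids), predictions=predictions,
    )


def _accumulate(
    c: ConfusionCounts,
    term: str,
    decided: np.ndarray,
    test_bundle: DatasetBundle,
    predictions: dict[str, set[str]],
) -> None:
    truth = test_bundle.annotations.proteins_for(term)
    for pid, pred in zip(test_bundle.proteins.ids, decided):
        is_pos = pid in truth
        if pred:
            predictions[pid].add(term)
        if pred and is_pos:
            c.tp += 1
        elif pred and not is_pos:
            c.fp += 1
        elif not pred and is_pos:
            c.fn += 1
        else:
            c.tn += 1


# ---------------------------------------------------------------------------
# per-protein evaluation
# ---------------------------------------------------------------------------

def per_protein_evaluate(
    predictions: "AnnotationSet | dict[str, set[str]]",
    truth: AnnotationSet,
    label_space: set[str],
    proteins: list[str] | None = None,
) -> EvaluationReport:
    """Hold-out evaluation averaged over proteins.

    For each protein the label space is the negative universe: TP are
    predicted∩true terms, FP predicted-only, FN true-only (restricted to the
    label space), TN the rest of the space.  True terms outside the label
    space are tallied separately, not counted as errors.
    """
    if isinstance(predictions, AnnotationSet):
        pred_map: dict[str, set[str]] = {}
        for p, t, _ in predictions.records:
            pred_map.setdefault(p, set()).add(t)
    else:
        pred_map = {p: set(ts) for p, ts in predictions.items()}
    if proteins is None:
        proteins = sorted(set(pred_map) | truth.proteins())

    rows = []
    excluded_total = 0
    for pid in proteins:
        predicted = pred_map.get(pid, set()) & label_space
        true_all = truth.terms_for(pid)
        true_in = true_all & label_space
        excluded_total += len(true_all - label_space)
        c = ConfusionCounts(
            tp=len(predicted & true_in),
            fp=len(predicted - true_in),
            fn=len(true_in - predicted),
            tn=len(label_space - (predicted | true_in)),
        )
        rows.append({
            "protein": pid, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "f_measure": f_measure(c),
        })
    per_protein = pd.DataFrame(
        rows, columns=["protein", "tp", "fp", "tn", "fn",
                       "sensitivity", "specificity", "f_measure"],
    )
    return EvaluationReport(
        per_term=pd.DataFrame(
            columns=["term", "n_pos", "tp", "fp", "tn", "fn",
                     "sensitivity", "specificity", "f_measure"],
        ),
        macro_sensitivity=_macro(per_protein["sensitivity"]) if len(per_protein) else float("nan"),
        macro_specificity=_macro(per_protein["specificity"]) if len(per_protein) else float("nan"),
        macro_f=_macro(per_protein["f_measure"]) if len(per_protein) else float("nan"),
        mode="per-protein",
        protein_ids=list(proteins),
        predictions=pred_map,
        per_protein=per_protein,
        n_excluded_terms=excluded_total,
    )


# ---------------------------------------------------------------------------
# F-measure gating
# ---------------------------------------------------------------------------

@dataclass
class GatingResult:
    threshold: float
    retained_terms: list[str]
    mean_f: float
    percent_annotated: float


def gate_terms(report: EvaluationReport, f_threshold: float) -> GatingResult:
    """Drop term classifiers whose cross-validated F-measure falls below the
    threshold; report the mean F over the retained terms and the percentage
    of evaluation proteins still receiving at least one prediction."""
    if not 0.0 <= f_threshold <= 1.0:
        raise ValueError("f_threshold must lie in [0, 1]")
    keep = report.per_term[report.per_term["f_measure"] >= f_threshold]
    retained = sorted(keep["term"].tolist())
    retained_set = set(retained)
    mean_f = _macro(keep["f_measure"]) if len(keep) else float("nan")
    if report.protein_ids:
        annotated = sum(
            1 for p in report.protein_ids
            if report.predictions.get(p, set()) & retained_set
        )
        pct = 100.0 * annotated / len(report.protein_ids)
    else:
        pct = float("nan")
    return GatingResult(
        threshold=f_threshold, retained_terms=retained,
        mean_f=mean_f, percent_annotated=pct,
    )


def gating_curve(
    report: EvaluationReport,
    thresholds: "list[float] | np.ndarray" = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
) -> pd.DataFrame:
    """Mean retained-term F and percent-annotated across a threshold sweep."""
    rows = []
    for thr in thresholds:
        g = gate_terms(report, float(thr))
        rows.append({
            "threshold": g.threshold,
            "n_retained": len(g.retained_terms),
            "mean_f": g.mean_f,
            "percent_annotated": g.percent_annotated,
        })
    return pd.DataFrame(rows)
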