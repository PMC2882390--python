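"""Per-GO-term dataset construction.

Each GO term is an independent binary classification problem: the positive
class is every protein annotated with the term, the negative class is every
other protein in the bundle (including proteins with no annotations at
all).  Because prevalences are tiny, the negative class is undersampled to
the positive-class size before training the margin classifiers.

Also provides the training-corpus filters: removal of terms with fewer than
a minimum number of representative proteins, and taxon subsetting (plain or
expanded with out-of-taxon proteins sharing at least one in-taxon term).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationSet, DatasetBundle, align_bundle

log = logging.getLogger(__name__)


@dataclass
class TermDataset:
    """Positive/negative protein split for one GO term."""

    go_term: str
    positives: list[str]
    negatives: list[str]
    undersampled: bool = False

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(
                f"{self.go_term}: proteins in both classes: {sorted(overlap)[:5]}"
            )

    def labels(self, protein_order: list[str]) -> np.ndarray:
        """Binary label vector over ``protein_order`` (proteins outside the
        dataset get 0)."""
        pos = set(self.positives)
        return np.array([1 if p in pos else 0 for p in protein_order], dtype=int)


def filter_rare_terms(
    annotations: AnnotationSet, min_proteins: int = 10
) -> AnnotationSet:
    """Drop GO terms annotating fewer than ``min_proteins`` distinct
    proteins."""
    if min_proteins < 1:
        raise ValueError("min_proteins must be >= 1")
    counts: dict[str, set[str]] = {}
    for p, t, _ in annotations.records:
        counts.setdefault(t, set()).add(p)
    keep = {t for t, ps in counts.items() if len(ps) >= min_proteins}
    if not keep and len(annotations):
        log.warning(
            "all %d terms fall below the %d-protein threshold; "
            "resulting AnnotationSet is empty", len(counts), min_proteins,
        )
    return AnnotationSet(
        frozenset(r for r in annotations.records if r[1] in keep)
    )


def subset_taxon(
    bundle: DatasetBundle, taxon_label: str, expanded: bool = False
) -> DatasetBundle:
    """Restrict a bundle to one taxon group.

    With ``expanded=True``, out-of-taxon proteins that share at least one GO
    term with the taxon's term set are retained as well (the
    "taxon-expanded" training corpus).  The rare-term filter is *not*
    re-applied automatically.
    """
    if bundle.proteins.taxon is None:
        raise ValueError("ProteinSet carries no taxon labels")
    labels = set(bundle.proteins.taxon.values())
    if taxon_label not in labels:
        raise ValueError(
            f"unknown taxon {taxon_label!r}; available: {sorted(labels)}"
        )
    in_taxon = [
        p for p in bundle.proteins.ids
        if bundle.proteins.taxon.get(p) == taxon_label
    ]
    keep = list(in_taxon)
    if expanded:
        taxon_terms = {
            t for p, t, _ in bundle.annotations.records if p in set(in_taxon)
        }
        extra = [
            p for p in bundle.proteins.ids
            if p not in set(in_taxon)
            and bundle.annotations.terms_for(p) & taxon_terms
        ]
        keep = [p for p in bundle.proteins.ids if p in set(in_taxon) | set(extra)]
    proteins = bundle.proteins.subset(keep)
    annotations = bundle.annotations.restrict_proteins(set(keep))
    return align_bundle(proteins, annotations, bundle.sources, drop_extra=True)


def build_term_dataset(bundle: DatasetBundle, go_term: str) -> TermDataset:
    """Assign every bundle protein to the positive or negative class of one
    term."""
    positives = sorted(
        bundle.annotations.proteins_for(go_term) & set(bundle.proteins.ids)
    )
    if not positives:
        raise ValueError(f"term {go_term} has no positive proteins in the bundle")
    pos = set(positives)
    negatives = [p for p in bundle.proteins.ids if p not in pos]
    return TermDataset(go_term=go_term, positives=positives, negatives=negatives)


def undersample(dataset: TermDataset, seed: int) -> TermDataset:
    """Replace the negative class by a uniform random subset matching the
    positive-class size (drawn without replacement, seed-controlled).

    If the negatives are already no larger than the positives the dataset is
    returned unchanged with a warning.
    """
    n_pos, n_neg = len(dataset.positives), len(dataset.negatives)
    if n_neg < n_pos:
        log.warning(
            "%s: %d negatives < %d positives; undersampling skipped",
            dataset.go_term, n_neg, n_pos,
        )
        return dataset
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_neg, size=n_pos, replace=False)
    negatives = [dataset.negatives[i] for i in sorted(chosen)]
    return TermDataset(
        go_term=dataset.go_term,
        positives=list(dataset.positives),
        negatives=negatives,
        undersampled=True,
    )
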