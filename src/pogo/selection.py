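"""Chi-square feature selection for the binary evidence sources.

Each binary feature is scored against the binary term label on its 2×2
contingency table (feature present/absent × positive/negative) with the
classic sum of (O−E)²/E — no Yates continuity correction, matching the
standard machine-learning feature-scoring convention.  Selection applies
only to the sparse binary sources; the dense biochemical descriptors bypass
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class FeatureScoreSet:
    """Per-feature chi-square scores and the retained subset."""

    feature_names: list[str]
    scores: np.ndarray
    selected: np.ndarray  # indices into feature_names

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.scores):
            raise ValueError("one score per feature required")
        if self.selected.size and (
            self.selected.min() < 0 or self.selected.max() >= len(self.scores)
        ):
            raise ValueError("selected indices out of range")


def chi_square_scores(
    matrix: "sp.spmatrix | np.ndarray",
    labels: np.ndarray,
    feature_names: list[str] | None = None,
) -> FeatureScoreSet:
    """Score every binary feature against the binary label.

    For feature counts a (positive, present), b (positive, absent),
    c (negative, present), d (negative, absent) the statistic is

        chi2 = n (ad − bc)² / ((a+b)(c+d)(a+c)(b+d)),

    algebraically identical to the four-cell (O−E)²/E sum.  Features whose
    table has a zero marginal (hence a zero expected count) score 0 by
    convention.
    """
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary {0,1}")
    if y.min() == y.max():
        raise ValueError("both classes must be present to score features")
    if sp.issparse(matrix):
        X = matrix.tocsc()
        present_pos = np.asarray(X[y == 1].sum(axis=0)).ravel().astype(float)
        present_tot = np.asarray(X.sum(axis=0)).ravel().astype(float)
    else:
        X = np.asarray(matrix)
        present_pos = X[y == 1].sum(axis=0).astype(float)
        present_tot = X.sum(axis=0).astype(float)
    n = float(len(y))
    n_pos = float(y.sum())
    n_neg = n - n_pos

    a = present_pos                    # positive & present
    c = present_tot - present_pos      # negative & present
    b = n_pos - a                      # positive & absent
    d = n_neg - c                      # negative & absent

    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    names = feature_names if feature_names is not None else [
        f"f{j}" for j in range(scores.size)
    ]
    return FeatureScoreSet(
        feature_names=list(names),
        scores=scores,
        selected=np.arange(scores.size),
    )


def select_features(
    scores: FeatureScoreSet,
    policy: str = "top_k",
    k: int = 500,
    min_score: float = 0.0,
) -> np.ndarray:
    """Choose the retained feature indices.

    ``top_k`` keeps the min(k, n) best-scoring features; ``min_score`` keeps
    features scoring at least the threshold.  Output is ordered by
    descending score with ties broken by ascending feature name, so the
    selection is deterministic and invariant to input column permutation.
    """
    order = sorted(
        range(len(scores.scores)),
        key=lambda j: (-scores.scores[j], scores.feature_names[j]),
    )
    if policy == "top_k":
        if k <= 0:
            raise ValueError("k must be positive")
        chosen = order[: min(k, len(order))]
    elif policy == "min_score":
        chosen = [j for j in order if scores.scores[j] >= min_score]
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    return np.array(chosen, dtype=int)
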