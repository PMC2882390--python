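"""Per-term base classifiers.

Each GO term gets four independent base models, one per evidence source,
trained under the source's own regimen:

* InterPro, BLAST-hit and structure-template sources (sparse binary):
  negative-class undersampling, chi-square feature selection, then a linear
  max-margin classifier;
* biochemical descriptors (dense numeric): no undersampling and no
  selection — discrete adaptive boosting of one-dimensional linear
  thresholds (decision stumps), on z-standardized columns, trained on the
  unbalanced data.

A fitted model is stored as plain arrays (weights + bias, or per-round
stump parameters + round weights), so serialization is a JSON manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .config import PipelineConfig
from .io import BINARY_SPARSE, FeatureSource
from .selection import chi_square_scores, select_features

log = logging.getLogger(__name__)

MAX_MARGIN = "max-margin"
BOOSTED_LINEAR = "boosted-linear"


@dataclass
class Stump:
    """One boosting round: predict ``polarity`` when x[feature] > threshold,
    ``-polarity`` otherwise."""

    feature: int
    threshold: float
    polarity: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.where(X[:, self.feature] > self.threshold, 1, -1)
        return self.polarity * out


@dataclass
class BaseModel:
    """A fitted base classifier for one (source, GO term) pair."""

    source: str
    kind: str  # MAX_MARGIN | BOOSTED_LINEAR
    n_input_features: int
    feature_indices: np.ndarray | None = None  # selected columns (binary sources)
    coef: np.ndarray | None = None             # margin model
    intercept: float = 0.0
    stumps: list[Stump] = field(default_factory=list)  # boosted model
    alphas: np.ndarray | None = None
    scaler_mean: np.ndarray | None = None      # biochem standardization
    scaler_std: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def _prepare(self, X: "sp.spmatrix | np.ndarray") -> np.ndarray:
        if X.shape[1] != self.n_input_features:
            raise ValueError(
                f"{self.source}: expected {self.n_input_features} features, "
                f"got {X.shape[1]}"
            )
        if self.feature_indices is not None:
            X = X[:, self.feature_indices]
        if sp.issparse(X):
            X = np.asarray(X.todense())
        X = np.asarray(X, dtype=float)
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_std
        return X

    def decision_scores(
        self, X: "sp.spmatrix | np.ndarray", n_rounds: int | None = None
    ) -> np.ndarray:
        """Raw margins (max-margin) or weighted stump votes (boosted).

        ``n_rounds`` truncates the boosted ensemble (for staged-error
        inspection)."""
        Xp = self._prepare(X)
        if self.kind == MAX_MARGIN:
            if self.coef is None or self.coef.size == 0:
                return np.full(Xp.shape[0], self.intercept)
            return Xp @ self.coef + self.intercept
        scores = np.zeros(Xp.shape[0])
        stumps = self.stumps if n_rounds is None else self.stumps[:n_rounds]
        alphas = self.alphas if n_rounds is None else self.alphas[:n_rounds]
        if not stumps:
            return np.full(Xp.shape[0], self.intercept)
        for stump, alpha in zip(stumps, alphas):
            scores += alpha * stump.predict(Xp)
        return scores


def predict_base(
    model: BaseModel, X: "sp.spmatrix | np.ndarray"
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a base model: binary decisions plus raw scores.

    Decisions are the sign of the decision function mapped to {0, 1}; the
    scores feed the optional raw-margin meta-feature mode.
    """
    scores = model.decision_scores(X)
    decisions = (scores > 0).astype(int)
    return decisions, scores


# ---------------------------------------------------------------------------
# max-margin learner (sparse binary sources)
# ---------------------------------------------------------------------------

def train_margin_classifier(
    X: "sp.spmatrix | np.ndarray",
    y: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
    source: str = "binary",
    feature_indices: np.ndarray | None = None,
    n_input_features: int | None = None,
    metadata: dict[str, Any] | None = None,
) -> BaseModel:
    """Fit a linear max-margin model on (selected) binary features.

    ``X`` is the already-column-subset training matrix; ``feature_indices``
    records which columns of the full source it corresponds to.
    """
    config = config or PipelineConfig()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n_input = n_input_features if n_input_features is not None else X.shape[1]
    meta = dict(metadata or {})
    meta.update(seed=int(seed), class_counts={0: int((y == 0).sum()),
                                              1: int((y == 1).sum())})
    if X.shape[1] == 0:
        # nothing selected: fall back to a constant majority-class decision
        majority = 1 if (y == 1).sum() >= (y == 0).sum() else 0
        return BaseModel(
            source=source, kind=MAX_MARGIN, n_input_features=n_input,
            feature_indices=feature_indices, coef=np.zeros(0),
            intercept=1.0 if majority == 1 else -1.0, metadata=meta,
        )
    svc = LinearSVC(
        C=config.svm_c, random_state=int(seed) % (2**31), max_iter=5000,
    )
    Xf = X.astype(float) if not sp.issparse(X) else X.astype(float)
    svc.fit(Xf, y)
    return BaseModel(
        source=source,
        kind=MAX_MARGIN,
        n_input_features=n_input,
        feature_indices=feature_indices,
        coef=svc.coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# boosted linear learner (dense biochem source)
# ---------------------------------------------------------------------------

def _best_stump(
    Xs: np.ndarray, order: np.ndarray, X: np.ndarray,
    y_signed: np.ndarray, w: np.ndarray,
) -> tuple[Stump, float]:
    """Exhaustive weighted search over all (feature, threshold, polarity)
    stumps.

    ``Xs``/``order`` are the per-column sorted values and sort indices,
    precomputed once per fit.  For split index i (number of sorted points at
    or below the threshold) and polarity +1, the weighted error is
    W_neg + cumsum(w*y)[i-1]; polarity −1 errors are the complement.
    """
    n, d = X.shape
    s_sorted = (w * y_signed)[order]              # n×d signed weights
    cum = np.cumsum(s_sorted, axis=0)
    w_neg = w[y_signed < 0].sum()
    # errs_plus[i, j]: error of (feature j, split i, polarity +1), i in 0..n
    errs_plus = np.empty((n + 1, d))
    errs_plus[0, :] = w_neg
    errs_plus[1:, :] = w_neg + cum
    # thresholds can only sit between distinct sorted values
    invalid = np.zeros((n + 1, d), dtype=bool)
    if n > 1:
        invalid[1:n, :] = Xs[1:] == Xs[:-1]
    errs_plus = np.where(invalid, 0.5, errs_plus)
    errs = np.minimum(errs_plus, 1.0 - errs_plus)
    flat = int(np.argmin(errs))            # row-major: deterministic tie-break
    i, j = divmod(flat, d)
    polarity = 1 if errs_plus[i, j] <= 1.0 - errs_plus[i, j] else -1
    if i == 0:
        threshold = -np.inf
    elif i == n:
        threshold = np.inf
    else:
        threshold = 0.5 * (Xs[i - 1, j] + Xs[i, j])
    err = float(errs[i, j])
    return Stump(feature=j, threshold=float(threshold), polarity=polarity), err


def train_boosted_linear(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int = 50,
    seed: int = 0,
    source: str = "biochem",
    standardize: bool = True,
    metadata: dict[str, Any] | None = None,
) -> BaseModel:
    """Discrete adaptive boosting of decision stumps on numeric descriptors.

    Per round t: fit the best weighted stump, compute its weighted error
    eps_t, round weight alpha_t = ½ ln((1−eps_t)/eps_t), reweight
    multiplicatively and renormalize.  Stops early when eps_t ≥ 0.5 (no
    learner better than chance remains) or eps_t = 0 (a perfect learner;
    kept as a single-member ensemble).  Trained on the unbalanced data — no
    undersampling for this source.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    meta = dict(metadata or {})
    meta.update(seed=int(seed), class_counts={0: int((y == 0).sum()),
                                              1: int((y == 1).sum())})
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        Xz = (X - mean) / std
    else:
        mean = std = None
        Xz = X

    y_signed = np.where(y == 1, 1, -1)
    w = np.full(n, 1.0 / n)
    order = np.argsort(Xz, axis=0, kind="stable")
    Xs = np.take_along_axis(Xz, order, axis=0)

    stumps: list[Stump] = []
    alphas: list[float] = []
    weight_sums: list[float] = []
    eps_floor = 1e-10
    for _ in range(rounds):
        stump, eps = _best_stump(Xs, order, Xz, y_signed, w)
        if eps >= 0.5:
            break
        alpha = 0.5 * np.log((1.0 - max(eps, eps_floor)) / max(eps, eps_floor))
        stumps.append(stump)
        alphas.append(float(alpha))
        if eps <= eps_floor:
            break
        h = stump.predict(Xz)
        w = w * np.exp(-alpha * y_signed * h)
        w = w / w.sum()
        weight_sums.append(float(w.sum()))
    meta["rounds_used"] = len(stumps)
    meta["weight_sums"] = weight_sums
    model = BaseModel(
        source=source,
        kind=BOOSTED_LINEAR,
        n_input_features=d,
        stumps=stumps,
        alphas=np.array(alphas),
        scaler_mean=mean,
        scaler_std=std,
        metadata=meta,
    )
    if not stumps:
        majority = 1 if (y == 1).sum() >= (y == 0).sum() else 0
        model.intercept = 1.0 if majority == 1 else -1.0
    return model


# ---------------------------------------------------------------------------
# per-source training regimen
# ---------------------------------------------------------------------------

def fit_source_model(
    source: FeatureSource,
    train_rows: np.ndarray,
    y_train: np.ndarray,
    config: PipelineConfig,
    seed: int,
    undersampled: bool,
) -> BaseModel:
    """Train one base model under the source's regimen.

    ``train_rows`` indexes the source matrix (already undersampled for the
    binary sources); ``y_train`` aligns with it.  Binary sources get
    chi-square selection fitted on these rows only; the numeric source is
    boosted on the unbalanced rows with training-fold standardization.
    """
    y_train = np.asarray(y_train).astype(int)
    Xt = source.matrix[train_rows]
    if source.kind == BINARY_SPARSE:
        scores = chi_square_scores(Xt, y_train, source.vocabulary)
        selected = select_features(
            scores,
            policy=config.selection_policy,
            k=config.selection_k,
            min_score=config.selection_min_score,
        )
        model = train_margin_classifier(
            Xt[:, selected] if selected.size else Xt[:, :0],
            y_train,
            config=config,
            seed=seed,
            source=source.name,
            feature_indices=selected,
            n_input_features=source.n_features,
            metadata={"undersampled": undersampled,
                      "selection": True,
                      "n_selected": int(selected.size)},
        )
    else:
        model = train_boosted_linear(
            np.asarray(Xt, dtype=float),
            y_train,
            rounds=config.boost_rounds,
            seed=seed,
            source=source.name,
            metadata={"undersampled": False, "selection": False},
        )
    return model
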