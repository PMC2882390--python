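# Methods

## Model

Each GO term is an independent binary classification problem over a shared
protein set. The model makes no use of the GO graph: terms are neither
propagated to ancestors nor constrained to be consistent with each other.
This forgoes label-dependency information but lets every term be
(re)trained in isolation and lets different learners serve different
evidence sources.

For a term *g* the positive class is every protein annotated with *g* and
the negative class every other protein in the bundle, including proteins
with no annotations at all. Two corpus-level filters are applied before
training: annotations with excluded evidence codes are dropped when read
(default: IEA, machine-inferred annotations, which would otherwise let the
classifier learn its own upstream mappings), and terms with fewer than
`min_proteins` (default 10) distinct proteins are removed from the label
space. Taxon subsetting supports a plain mode (keep one taxon group) and
an expanded mode that additionally retains out-of-taxon proteins sharing
at least one GO term with the taxon's term set; the rare-term filter is
not automatically re-applied after subsetting (a flag re-enables it).

## Base classifiers

**Sparse binary sources** (`interpro`, `blast`, `structure`). Training
negatives are undersampled uniformly at random, without replacement, to
the positive-class size; undersampling is redrawn inside every CV fold and
Combiner half (never reusing a global draw, so no test protein influences
a training subsample). Features are then scored by the χ² statistic of the
2×2 (feature present/absent × positive/negative) table,

χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)),

with no Yates correction; features with a zero marginal score 0 by
convention. The default selection policy keeps the `min(500, d)`
best-scoring features, with ties broken by ascending feature name so
selection is deterministic and column-order invariant. A linear
max-margin classifier (liblinear, C = 1 by default) is fit on the selected
columns; its weight vector and bias are stored as plain arrays.

The BLAST reader consumes the 12-column tabular dialect, takes the
e-value from field 11, and marks cell (query, subject) = 1 iff any hit is
at or below the threshold (default 10⁻¹⁰). The structure reader keeps at
most the first 10 template ids listed per protein; templates a protein
does not have are simply zero, as are entire rows for proteins absent
from a binary source file. Numeric descriptor rows are never imputed: a
protein without a sequence is an error, not a zero row.

**Numeric source** (`biochem`). The 425 descriptor columns are, in fixed
order: 20 amino-acid fractions, 400 ordered dipeptide ratios (counts over
the L−1 adjacent pairs), average-mass molecular weight, the fractions of
negatively (D, E) and positively (K, R, H — histidine counted positive,
switchable) charged residues, GRAVY (mean Kyte–Doolittle hydropathy), and
the isoelectric point. Unknown residues (X) are excluded from every
numerator and denominator; dipeptide ratios of single-residue sequences
are zero with an explicit flag. The isoelectric point is the root of the
Henderson–Hasselbalch net charge (strictly decreasing in pH, so unique),
found by bisection on [0, 14] to |charge| < 10⁻⁴ or interval < 10⁻⁴,
using the EMBOSS pepstats pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1; table overridable).

This source is trained *unbalanced* and *unselected* with discrete
AdaBoost: per round, the exhaustively best decision stump (feature,
threshold, polarity) under the current weights; round weight
α_t = ½ln((1−ε_t)/ε_t); multiplicative reweighting and renormalization.
Training stops early when ε_t ≥ 0.5 or ε_t = 0 (a perfect stump is kept
as a single-member ensemble, with ε floored at 10⁻¹⁰ inside the
logarithm). Columns are z-standardized with training-fold statistics —
molecular weight is four orders of magnitude larger than the fractional
descriptors and would otherwise dominate threshold resolution — with
zero-variance columns given unit scale. Stump search scans split points
between distinct sorted values only, plus the two constant stumps;
ties are broken by scan order (lowest split index, then lowest feature
index), which makes training deterministic. Note that the raw 0/1
training error of the ensemble is not monotone round-to-round; the
monotone quantity, asserted in the tests, is the exponential-loss bound.

## Combiner meta-layer

The training proteins are halved uniformly at random (sizes differ by at
most one). Each source's base learner is trained on one half under its
own regimen and applied to the other, in both directions, yielding one
out-of-sample decision per (protein, source). Provenance of every value
is recorded and asserted on every run: no meta-feature may come from a
model whose training half contained that protein. When a half is
single-class for a term (all positives landed in the other half), that
direction's column is filled with the training half's majority-class
decision and a warning is logged — the classifier is still constructed.

The meta-learner is Naïve Bayes on the 4 binary decisions: priors are the
class frequencies of the *unbalanced* meta-dataset; conditionals are
Bernoulli with additive smoothing, P(f=1|c) = (count + α)/(n_c + 2α),
α = 1 by default; posteriors are computed in log space and renormalized.
A term is assigned when the positive posterior exceeds the decision
threshold (0.5 by default — the neutral choice). Three comparison arms
are available behind configuration flags: an undersampled (balanced)
meta-dataset, a linear max-margin meta-learner, and raw base *scores* as
meta-features, which switches the conditionals to Gaussians with a 10⁻⁹
variance floor. The defaults are the winning configuration
(unbalanced + Naïve Bayes + decisions).

For deployment the base models are retrained on all of *T*: the
cross-trained half-models exist to produce unbiased meta-features, and
discarding half the data at prediction time would be strictly worse. If
the meta-training labels are single-class the meta-model degenerates to
an always-that-class predictor, with a warning.

## Evaluation

Cross-validation partitions *proteins* (not annotations) into 10 random
test folds; the entire pipeline — undersampling, selection, base
training, Combiner split, meta-training, deployment retraining — is refit
within each fold. Per-term confusion counts are pooled across folds
before metrics are computed (micro within term), then macro-averaged
across terms; pooling is the stable choice for rare terms, where
individual folds may hold no positives at all. Sensitivity and
specificity are undefined (NaN) when their denominator is empty and such
terms are excluded from the macro mean rather than zero-filled — a term
that was never evaluable is not a term that failed. F-measure is 0
whenever TP = 0.

The per-protein protocol computes the same metrics per protein against
the classifier's label space (the only negative universe both a
classifier and a reference method share) and averages over proteins; true
terms outside the label space are tallied separately, not counted as
errors. Gating drops term classifiers with cross-validated F below a
threshold; `percent_annotated` is the share of evaluation proteins
receiving at least one prediction from the retained terms. Raising the
threshold provably never lowers the mean retained F and never raises
coverage.

## Synthetic data

The generator emulates the statistical structure the classifier assumes.
Per-term prevalences are drawn uniformly from (0.05, 0.30) and realized
as exact positive counts sampled without replacement; the lower bound is
chosen so that every simulated term clears the pipeline's own
10-protein rare-term filter at the default 300 proteins (0.02 would
produce ~6-positive terms the method itself would discard). Binary
sources have a configured dimensionality (defaults 200 / 150 / 300),
background density 0.02, and 3 planted features per informative
(term, source) pair that positives carry with probability `p_signal`
(default 0.95); setting `p_signal` equal to the background density yields
an exact null. Sequences are drawn i.i.d. per residue from a uniform
composition shifted by +0.10 probability mass on each positive term's
signature residue, and the biochemical descriptors are then *computed*
from those sequences — the biochem signal is weak and indirect by
design. The disjoint regime makes each quarter of the terms informative
in exactly one source (with a stronger +0.30 shift for the biochem
quarter, since composition is a much noisier channel than a planted
indicator), which is the condition under which the meta-layer must beat
every single-source classifier.

All randomness descends from one seed through named child streams
(labels, one per binary source, sequences), so bundles are bit-identical
across machines. The default fixture (300 proteins, 12 terms) keeps full
10-fold CV of the whole system under a minute; these sizes, not
corpus-scale ones, are what the tests and the acceptance script run.

What the generator does **not** emulate: homology structure among
proteins (features are conditionally independent given labels, which
flatters Naïve Bayes), correlated terms, evolutionary sequence structure,
InterPro/BLAST/HHpred noise characteristics, or corpus-scale label-space
sizes. Passing tests therefore demonstrate protocol correctness and
recoverability of planted signal, not expected performance on real
proteomes.

## Known limitations

* Terms are independent; predictions can be GO-inconsistent (a child
  without its ancestor).
* The evidence-code merge keeps one record per (protein, term) —
  the alphabetically smallest code — so multi-evidence provenance is not
  preserved.
* Single-class degenerate paths (majority fill, always-one-class meta)
  keep the system total but contribute noise for extremely rare terms;
  the rare-term filter is the intended guard.
* BLAST self-hits are taken as given: whether the query sequence is in
  the search database is an upstream concern the reader cannot detect.
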