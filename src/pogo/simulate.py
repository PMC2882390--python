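"""Synthetic dataset generation.

Produces fully self-contained :class:`~pogo.io.DatasetBundle` fixtures with
the statistical structure the classifier assumes: sparse binary evidence
sources with planted feature→term associations, realistic label imbalance
(per-term prevalences drawn from a configured range), and random protein
sequences whose residue composition is shifted for positive proteins so
that the biochemical descriptors carry (weak) signal.  Ground truth —
which features and residues were planted for which term — is returned for
oracle checks.

Two regimes are provided: :func:`simulate_bundle`, where every source is
informative for every term, and :func:`simulate_disjoint_source_signal`,
where each quarter of the terms is informative in exactly one source — the
regime in which the meta-layer must outperform any single-source
classifier.

All randomness flows from a single seed through per-component child
streams, so bundles are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .biochem import AA_ORDER, build_biochem_source
from .io import (
    BINARY_SPARSE,
    AnnotationSet,
    DatasetBundle,
    FeatureSource,
    ProteinSet,
    align_bundle,
    read_annotations,
    read_blast_features,
    read_fasta,
    read_term_features,
    write_annotations,
)

#: Binary-source dimensionalities of the default fixture (biochem is always
#: the 425 descriptor columns).
DEFAULT_DIMS = {"interpro": 200, "blast": 150, "structure": 300}


@dataclass
class SimulationConfig:
    """Generator settings.

    ``prevalence_range`` spans the per-term positive fractions (imbalance);
    ``p_signal`` is the probability that a planted feature is present in a
    positive protein, ``background_density`` the presence probability of
    every feature otherwise.  ``composition_shift`` is the probability mass
    added to a term's signature residue in its positive proteins (weak
    biochemical signal); ``disjoint_composition_shift`` is the stronger
    shift used for the biochem-informative quarter of the disjoint regime.
    """

    n_proteins: int = 300
    n_terms: int = 12
    prevalence_range: tuple[float, float] = (0.05, 0.30)
    p_signal: float = 0.95
    background_density: float = 0.02
    planted_per_term: int = 3
    interpro_dim: int = DEFAULT_DIMS["interpro"]
    blast_dim: int = DEFAULT_DIMS["blast"]
    structure_dim: int = DEFAULT_DIMS["structure"]
    seq_length_range: tuple[int, int] = (80, 300)
    composition_shift: float = 0.10
    disjoint_composition_shift: float = 0.30
    taxon_label: str = "Fungi"
    seed: int = 42

    def __post_init__(self) -> None:
        lo, hi = self.prevalence_range
        for p in (self.p_signal, self.background_density, lo, hi):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if lo > hi:
            raise ValueError("prevalence_range must be (low, high)")
        need = self.n_terms * self.planted_per_term
        for name, dim in (("interpro", self.interpro_dim),
                          ("blast", self.blast_dim),
                          ("structure", self.structure_dim)):
            if dim < need:
                raise ValueError(
                    f"{name} dimensionality {dim} < {need} planted features"
                )
        if self.n_proteins < 4 or self.n_terms < 1:
            raise ValueError("infeasible config")


_FEATURE_PREFIX = {"interpro": "IPR", "blast": "UP", "structure": "d"}


def _feature_names(source: str, dim: int) -> list[str]:
    return [f"{_FEATURE_PREFIX[source]}{j:06d}" for j in range(dim)]


def _generate(
    cfg: SimulationConfig,
    informative: dict[str, list[int]],
    shifts: np.ndarray,
) -> tuple[DatasetBundle, dict]:
    """Shared generator core.

    ``informative[source]`` lists the term indices for which that binary
    source carries planted signal; ``shifts[t]`` is the composition shift
    applied to term t's signature residue.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("labels", "interpro", "blast", "structure", "sequences"),
            root.spawn(5),
        )
    }

    pids = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    terms = [f"GO:{t + 1:07d}" for t in range(cfg.n_terms)]

    # labels: exact positive counts per term, drawn without replacement
    rng = streams["labels"]
    lo, hi = cfg.prevalence_range
    prevalences = rng.uniform(lo, hi, size=cfg.n_terms)
    label_matrix = np.zeros((cfg.n_proteins, cfg.n_terms), dtype=int)
    for t in range(cfg.n_terms):
        n_pos = max(1, int(round(prevalences[t] * cfg.n_proteins)))
        chosen = rng.choice(cfg.n_proteins, size=n_pos, replace=False)
        label_matrix[chosen, t] = 1

    annotations = AnnotationSet.from_triples([
        (pids[i], terms[t], "IDA")
        for i in range(cfg.n_proteins)
        for t in range(cfg.n_terms)
        if label_matrix[i, t]
    ])

    # binary sources: background everywhere, planted cells overridden with
    # Bernoulli(p_signal) for positive proteins of informative terms
    dims = {"interpro": cfg.interpro_dim, "blast": cfg.blast_dim,
            "structure": cfg.structure_dim}
    truth_terms: dict[str, dict] = {
        terms[t]: {
            "prevalence": float(prevalences[t]),
            "n_positives": int(label_matrix[:, t].sum()),
            "planted": {},
            "signature_residue": AA_ORDER[t % 20],
            "composition_shift": float(shifts[t]),
        }
        for t in range(cfg.n_terms)
    }
    sources: list[FeatureSource] = []
    binary_order = ("interpro", "blast", "structure")
    for name in binary_order:
        rng = streams[name]
        dim = dims[name]
        vocab = _feature_names(name, dim)
        X = (rng.random((cfg.n_proteins, dim)) < cfg.background_density)
        X = X.astype(np.int8)
        for t in informative[name]:
            cols = np.arange(
                t * cfg.planted_per_term, (t + 1) * cfg.planted_per_term
            )
            pos_rows = np.flatnonzero(label_matrix[:, t])
            X[np.ix_(pos_rows, cols)] = (
                rng.random((len(pos_rows), len(cols))) < cfg.p_signal
            ).astype(np.int8)
            truth_terms[terms[t]]["planted"][name] = [vocab[j] for j in cols]
        sources.append(FeatureSource(
            name=name, matrix=sp.csr_matrix(X), kind=BINARY_SPARSE,
            vocabulary=vocab, protein_ids=list(pids),
        ))

    # sequences: per-protein residue composition shifted toward the
    # signature residues of the terms the protein is positive for
    rng = streams["sequences"]
    aa = np.array(list(AA_ORDER))
    base = np.full(20, 1.0 / 20)
    sequences: dict[str, str] = {}
    lmin, lmax = cfg.seq_length_range
    for i, pid in enumerate(pids):
        probs = base.copy()
        for t in np.flatnonzero(label_matrix[i]):
            if shifts[t] > 0:
                probs[t % 20] += shifts[t]
        probs = probs / probs.sum()
        length = int(rng.integers(lmin, lmax + 1))
        sequences[pid] = "".join(rng.choice(aa, size=length, p=probs))

    proteins = ProteinSet(
        ids=pids, sequences=sequences,
        taxon={p: cfg.taxon_label for p in pids},
    )
    biochem = build_biochem_source(proteins)
    # fixed source order: interpro, blast, biochem, structure
    ordered = [sources[0], sources[1], biochem, sources[2]]
    bundle = align_bundle(proteins, annotations, ordered)

    truth = {
        "config": dataclasses.asdict(cfg),
        "terms": truth_terms,
        "informative": {k: [terms[t] for t in v] for k, v in informative.items()},
    }
    return bundle, truth


def simulate_bundle(cfg: SimulationConfig) -> tuple[DatasetBundle, dict]:
    """Default regime: every source is informative for every term (the
    biochemical signal is weak — a small composition shift)."""
    informative = {
        name: list(range(cfg.n_terms))
        for name in ("interpro", "blast", "structure")
    }
    shifts = np.full(cfg.n_terms, cfg.composition_shift)
    return _generate(cfg, informative, shifts)


def simulate_disjoint_source_signal(
    cfg: SimulationConfig,
) -> tuple[DatasetBundle, dict]:
    """Disjoint regime: each quarter of the terms is informative in exactly
    one source; the other sources are pure background noise for those
    terms.  Term quarters follow the fixed source order (interpro, blast,
    biochem, structure)."""
    if cfg.n_terms % 4 != 0:
        raise ValueError("n_terms must be divisible by 4")
    q = cfg.n_terms // 4
    quarters = {
        "interpro": list(range(0, q)),
        "blast": list(range(q, 2 * q)),
        "biochem": list(range(2 * q, 3 * q)),
        "structure": list(range(3 * q, 4 * q)),
    }
    informative = {name: quarters[name] for name in
                   ("interpro", "blast", "structure")}
    shifts = np.zeros(cfg.n_terms)
    shifts[quarters["biochem"]] = cfg.disjoint_composition_shift
    bundle, truth = _generate(cfg, informative, shifts)
    term_names = [f"GO:{t + 1:07d}" for t in range(cfg.n_terms)]
    truth["informative"]["biochem"] = [term_names[t] for t in quarters["biochem"]]
    for name, idxs in quarters.items():
        for t in idxs:
            truth["terms"][term_names[t]]["informative_source"] = name
    return bundle, truth


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------

def write_bundle(bundle: DatasetBundle, truth: dict, out_dir: str) -> None:
    """Write the full file set in the formats the readers consume: FASTA,
    annotation TSV, InterPro/structure pair TSVs, 12-column BLAST tabular
    (hits at 1e-20, plus an above-threshold decoy hit per protein so the
    e-value filter is exercised), a taxon TSV and the ground-truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "proteins.fasta"), "w") as fh:
        for pid in bundle.proteins.ids:
            fh.write(f">{pid}\n{bundle.proteins.sequences[pid]}\n")
    write_annotations(
        bundle.annotations, os.path.join(out_dir, "annotations.tsv")
    )
    for name, fname in (("interpro", "interpro.tsv"), ("structure", "structure.tsv")):
        src = bundle.source(name)
        X = src.matrix.tocsr()
        with open(os.path.join(out_dir, fname), "w") as fh:
            for i, pid in enumerate(bundle.proteins.ids):
                for j in X[i].indices:
                    fh.write(f"{pid}\t{src.vocabulary[j]}\n")
    blast = bundle.source("blast")
    Xb = blast.matrix.tocsr()
    with open(os.path.join(out_dir, "blast.tsv"), "w") as fh:
        for i, pid in enumerate(bundle.proteins.ids):
            for j in Xb[i].indices:
                fh.write(
                    f"{pid}\t{blast.vocabulary[j]}\t95.0\t200\t5\t1\t1\t200"
                    f"\t1\t200\t1e-20\t350.0\n"
                )
            # decoy hit above the default e-value threshold
            fh.write(
                f"{pid}\tDECOY00001\t40.0\t80\t40\t5\t1\t80\t1\t80"
                f"\t1e-03\t45.0\n"
            )
    if bundle.proteins.taxon:
        with open(os.path.join(out_dir, "taxon.tsv"), "w") as fh:
            for pid in bundle.proteins.ids:
                fh.write(f"{pid}\t{bundle.proteins.taxon[pid]}\n")
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)


def load_bundle(in_dir: str, exclude_evidence: tuple[str, ...] = ()) -> DatasetBundle:
    """Reload a directory written by :func:`write_bundle`, recomputing the
    biochemical descriptors from the FASTA sequences."""
    proteins = read_fasta(os.path.join(in_dir, "proteins.fasta"))
    taxon_path = os.path.join(in_dir, "taxon.tsv")
    if os.path.isfile(taxon_path):
        taxon = {}
        with open(taxon_path) as fh:
            for line in fh:
                pid, label = line.rstrip("\n").split("\t")
                taxon[pid] = label
        proteins = ProteinSet(
            ids=proteins.ids, sequences=proteins.sequences, taxon=taxon
        )
    annotations = read_annotations(
        os.path.join(in_dir, "annotations.tsv"),
        exclude_evidence=exclude_evidence,
    )
    interpro = read_term_features(
        os.path.join(in_dir, "interpro.tsv"), "interpro"
    )
    structure = read_term_features(
        os.path.join(in_dir, "structure.tsv"), "structure", max_per_protein=10
    )
    blast = read_blast_features(os.path.join(in_dir, "blast.tsv"))
    biochem = build_biochem_source(proteins)
    return align_bundle(
        proteins, annotations, [interpro, blast, biochem, structure]
    )
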