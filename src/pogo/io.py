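"""Domain types and file I/O.

The classifier consumes four heterogeneous evidence sources plus training
labels, all as plain text files:

* protein sequences — FASTA;
* GO annotations — TSV of (protein, GO term, evidence code);
* InterPro term and structure-template assignments — TSV of
  (protein, feature id) pairs;
* BLAST hits — 12-column tabular output (``-outfmt 6``).

Everything downstream operates on a :class:`DatasetBundle`, in which all
feature sources have been re-indexed onto a single protein ordering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from Bio import SeqIO

log = logging.getLogger(__name__)

GO_PATTERN = re.compile(r"^GO:\d{7}$")

#: Columns of the universal BLAST tabular interchange dialect; the e-value is
#: field 11 (1-based).
BLAST_TABULAR_NCOLS = 12
BLAST_EVALUE_COL = 10  # 0-based

BINARY_SPARSE = "binary-sparse"
NUMERIC_DENSE = "numeric-dense"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinSet:
    """An ordered collection of proteins, optionally with sequences and
    taxon-group labels."""

    ids: list[str]
    sequences: dict[str, str] | None = None
    taxon: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate protein id {dup!r}")
        idset = set(self.ids)
        for name, mapping in (("sequence", self.sequences), ("taxon", self.taxon)):
            if mapping is None:
                continue
            extra = set(mapping) - idset
            if extra:
                raise ValueError(f"{name} keys not in protein ids: {sorted(extra)}")
        if self.sequences:
            for pid, seq in self.sequences.items():
                if not seq:
                    raise ValueError(f"empty sequence for protein {pid!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {pid: i for i, pid in enumerate(self.ids)}

    def subset(self, keep: list[str]) -> "ProteinSet":
        keepset = set(keep)
        seqs = (
            {p: s for p, s in self.sequences.items() if p in keepset}
            if self.sequences is not None
            else None
        )
        tax = (
            {p: t for p, t in self.taxon.items() if p in keepset}
            if self.taxon is not None
            else None
        )
        return ProteinSet(ids=list(keep), sequences=seqs, taxon=tax)


@dataclass(frozen=True)
class AnnotationSet:
    """Protein → GO-term labels with evidence codes.

    ``records`` holds (protein id, GO id, evidence code) triples with at most
    one record per (protein, term) pair; when reading merges duplicates, the
    alphabetically smallest evidence code wins.
    """

    records: frozenset[tuple[str, str, str]]

    def __post_init__(self) -> None:
        pairs = {(p, t) for p, t, _ in self.records}
        if len(pairs) != len(self.records):
            raise ValueError("duplicate (protein, term) pairs in AnnotationSet")
        for _, term, _ in self.records:
            if not GO_PATTERN.match(term):
                raise ValueError(f"malformed GO id {term!r}")

    @staticmethod
    def from_triples(
        triples: "list[tuple[str, str, str]] | set[tuple[str, str, str]]",
    ) -> "AnnotationSet":
        """Build a set, merging duplicate (protein, term) pairs
        deterministically (smallest evidence code kept)."""
        best: dict[tuple[str, str], str] = {}
        for p, t, e in triples:
            key = (p, t)
            if key not in best or e < best[key]:
                best[key] = e
        return AnnotationSet(frozenset((p, t, e) for (p, t), e in best.items()))

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> set[tuple[str, str]]:
        return {(p, t) for p, t, _ in self.records}

    def terms(self) -> list[str]:
        return sorted({t for _, t, _ in self.records})

    def proteins(self) -> set[str]:
        return {p for p, _, _ in self.records}

    def proteins_for(self, term: str) -> set[str]:
        return {p for p, t, _ in self.records if t == term}

    def terms_for(self, protein: str) -> set[str]:
        return {t for p, t, _ in self.records if p == protein}

    def restrict_proteins(self, keep: set[str]) -> "AnnotationSet":
        return AnnotationSet(frozenset(r for r in self.records if r[0] in keep))


@dataclass
class FeatureSource:
    """A named proteins × features matrix.

    ``kind`` is ``binary-sparse`` (CSR of {0,1}) for the InterPro, BLAST-hit
    and structure-template sources, or ``numeric-dense`` (ndarray) for the
    biochemical descriptors.
    """

    name: str
    matrix: "sp.csr_matrix | np.ndarray"
    kind: str
    vocabulary: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        if self.kind not in (BINARY_SPARSE, NUMERIC_DENSE):
            raise ValueError(f"unknown source kind {self.kind!r}")
        n, d = self.matrix.shape
        if n != len(self.protein_ids):
            raise ValueError(
                f"source {self.name!r}: {n} rows for {len(self.protein_ids)} proteins"
            )
        if d != len(self.vocabulary):
            raise ValueError(
                f"source {self.name!r}: {d} columns for {len(self.vocabulary)} names"
            )
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError(f"source {self.name!r}: duplicate feature names")
        if self.kind == BINARY_SPARSE:
            if not sp.issparse(self.matrix):
                self.matrix = sp.csr_matrix(self.matrix)
            data = self.matrix.data
            if data.size and not np.isin(data, (0, 1)).all():
                raise ValueError(f"source {self.name!r}: non-binary values")

    @property
    def n_features(self) -> int:
        return len(self.vocabulary)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix)


@dataclass
class DatasetBundle:
    """Proteins + labels + aligned feature sources; the unit the trainer and
    evaluator consume."""

    proteins: ProteinSet
    annotations: AnnotationSet
    sources: list[FeatureSource] = field(default_factory=list)

    def __post_init__(self) -> None:
        for src in self.sources:
            if src.protein_ids != self.proteins.ids:
                raise ValueError(
                    f"source {src.name!r} is not aligned to the protein ordering"
                )
        missing = self.annotations.proteins() - set(self.proteins.ids)
        if missing:
            raise ValueError(
                f"annotated proteins absent from ProteinSet: {sorted(missing)[:5]}"
            )

    def source(self, name: str) -> FeatureSource:
        for src in self.sources:
            if src.name == name:
                return src
        raise KeyError(f"no source named {name!r}")

    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> ProteinSet:
    """Read a FASTA file into a :class:`ProteinSet`.

    The protein id is the first whitespace-delimited token of the header;
    sequences are uppercased and stop codons (``*``) stripped.
    """
    ids: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        pid = rec.id
        if pid in seqs:
            raise ValueError(f"duplicate FASTA id {pid!r} in {path}")
        ids.append(pid)
        seqs[pid] = str(rec.seq).upper().replace("*", "")
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return ProteinSet(ids=ids, sequences=seqs)


def read_annotations(
    path: str,
    exclude_evidence: "set[str] | tuple[str, ...]" = ("IEA",),
    columns: tuple[str, str, str] = ("protein", "go", "evidence"),
    header: bool = False,
) -> AnnotationSet:
    """Read a protein/GO/evidence TSV, dropping excluded evidence codes.

    ``columns`` names the on-file column order (any permutation of
    ``protein``, ``go``, ``evidence``) so GAF-like dialect variations can be
    accommodated without guessing.
    """
    order = {name: i for i, name in enumerate(columns)}
    if set(order) != {"protein", "go", "evidence"}:
        raise ValueError(f"columns must permute (protein, go, evidence), got {columns}")
    exclude = set(exclude_evidence)
    triples: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            protein = fields[order["protein"]].strip()
            go = fields[order["go"]].strip()
            evidence = fields[order["evidence"]].strip()
            if not GO_PATTERN.match(go):
                raise ValueError(f"{path}:{lineno}: malformed GO id {go!r}")
            if evidence in exclude:
                continue
            triples.append((protein, go, evidence))
    return AnnotationSet.from_triples(triples)


def write_annotations(annotations: AnnotationSet, path: str) -> None:
    """Write an AnnotationSet as a sorted protein/GO/evidence TSV."""
    with open(path, "w") as fh:
        for p, t, e in sorted(annotations.records):
            fh.write(f"{p}\t{t}\t{e}\n")


def write_predictions(predictions: AnnotationSet, path: str) -> None:
    """Write predicted terms as TSV (protein, GO id, source tag)."""
    with open(path, "w") as fh:
        for p, t, _ in sorted(predictions.records):
            fh.write(f"{p}\t{t}\tPoGO\n")


def read_blast_features(
    path: str,
    evalue_max: float = 1e-10,
    name: str = "blast",
) -> FeatureSource:
    """Read tabular BLAST output into a binary feature source.

    Features are the subject accessions; cell (query, subject) is 1 iff any
    hit between the two has e-value at or below ``evalue_max`` (default
    1e-10, the expect threshold used for GO-annotated-database searches).
    """
    hits: dict[str, set[str]] = {}
    subjects: dict[str, None] = {}
    queries: dict[str, None] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < BLAST_TABULAR_NCOLS:
                raise ValueError(
                    f"{path}:{lineno}: expected {BLAST_TABULAR_NCOLS} columns"
                )
            query, subject = fields[0], fields[1]
            try:
                evalue = float(fields[BLAST_EVALUE_COL])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric e-value {fields[BLAST_EVALUE_COL]!r}"
                ) from exc
            queries.setdefault(query)
            if evalue <= evalue_max:
                subjects.setdefault(subject)
                hits.setdefault(query, set()).add(subject)
    vocab = list(subjects)
    qids = list(queries)
    col = {s: j for j, s in enumerate(vocab)}
    rows, cols = [], []
    for i, q in enumerate(qids):
        for s in hits.get(q, ()):
            rows.append(i)
            cols.append(col[s])
    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(qids), len(vocab)),
    )
    return FeatureSource(
        name=name, matrix=matrix, kind=BINARY_SPARSE, vocabulary=vocab, protein_ids=qids
    )


def read_term_features(
    path: str,
    source_name: str,
    max_per_protein: int | None = None,
) -> FeatureSource:
    """Read a protein/feature-id pair TSV (InterPro terms or structure
    templates) into a binary feature source.

    For the structure source pass ``max_per_protein=10``: only the first ten
    template ids listed for a protein become features (the remaining
    templates are ignored, equivalent to being set to zero).
    """
    per_protein: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            per_protein.setdefault(fields[0], []).append(fields[1])
    vocab_seen: dict[str, None] = {}
    kept: dict[str, list[str]] = {}
    for pid, feats in per_protein.items():
        if max_per_protein is not None:
            feats = feats[:max_per_protein]
        # dedupe while preserving order
        uniq = list(dict.fromkeys(feats))
        kept[pid] = uniq
        for f in uniq:
            vocab_seen.setdefault(f)
    vocab = list(vocab_seen)
    pids = list(kept)
    col = {f: j for j, f in enumerate(vocab)}
    rows, cols = [], []
    for i, pid in enumerate(pids):
        for f in kept[pid]:
            rows.append(i)
            cols.append(col[f])
    matrix = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(pids), len(vocab)),
    )
    return FeatureSource(
        name=source_name,
        matrix=matrix,
        kind=BINARY_SPARSE,
        vocabulary=vocab,
        protein_ids=pids,
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_source(
    source: FeatureSource, proteins: ProteinSet, drop_extra: bool = False
) -> FeatureSource:
    """Re-index one source onto the ProteinSet ordering.

    Proteins missing from a binary source get all-zero rows.  A numeric
    source must cover every protein: silently imputing descriptor rows would
    corrupt them, so missing rows are an error.  Source rows for proteins
    outside the set are an error unless ``drop_extra`` (used when
    restricting an already-aligned bundle to a protein subset).
    """
    extra = set(source.protein_ids) - set(proteins.ids)
    if extra and not drop_extra:
        raise ValueError(
            f"source {source.name!r} has ids not in ProteinSet: {sorted(extra)[:5]}"
        )
    if source.protein_ids == proteins.ids:
        return source
    row_of = {pid: i for i, pid in enumerate(source.protein_ids)}
    if source.kind == BINARY_SPARSE:
        n = len(proteins)
        expander = sp.lil_matrix((n, len(source.protein_ids)), dtype=np.int8)
        for i, pid in enumerate(proteins.ids):
            if pid in row_of:
                expander[i, row_of[pid]] = 1
        matrix = (expander.tocsr() @ source.matrix).tocsr()
        matrix.data = matrix.data.astype(np.int8)
    else:
        missing = [p for p in proteins.ids if p not in row_of]
        if missing:
            raise ValueError(
                f"numeric source {source.name!r} lacks rows for proteins "
                f"{missing[:5]}; descriptor rows cannot be imputed"
            )
        idx = np.array([row_of[p] for p in proteins.ids])
        matrix = np.asarray(source.matrix)[idx]
    return FeatureSource(
        name=source.name,
        matrix=matrix,
        kind=source.kind,
        vocabulary=list(source.vocabulary),
        protein_ids=list(proteins.ids),
    )


def align_bundle(
    proteins: ProteinSet,
    annotations: AnnotationSet,
    sources: list[FeatureSource],
    drop_extra: bool = False,
) -> DatasetBundle:
    """Assemble a :class:`DatasetBundle` with every source re-indexed onto
    the shared protein ordering."""
    aligned = [align_source(s, proteins, drop_extra=drop_extra) for s in sources]
    return DatasetBundle(proteins=proteins, annotations=annotations, sources=aligned)
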