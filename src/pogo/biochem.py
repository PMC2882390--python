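"""Biochemical sequence descriptors.

Computes, natively from the amino-acid sequence, the descriptor set that
pepstats/compseq-style reports provide: amino-acid composition, molecular
weight, proportions of negatively (D, E) and positively (K, R, H) charged
residues, hydrophobicity (GRAVY, the mean Kyte–Doolittle hydropathy),
isoelectric point, and the 400 ordered amino-acid pair ratios.

Unknown residues (``X``) are excluded from every numerator and denominator.
The descriptor vector is the numeric-dense evidence source for the
boosted-linear base classifier: 20 amino-acid fractions, 400 dipeptide
ratios, molecular weight, charged-residue fractions, GRAVY and pI — 425
columns in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NUMERIC_DENSE, FeatureSource, ProteinSet

#: Canonical residue order for all composition vectors.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Average (not monoisotopic) residue masses in daltons.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
WATER_MASS = 18.01524

#: Kyte–Doolittle hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: EMBOSS pepstats default pKa set.  ``nterm``/``cterm`` are the free
#: termini; the rest are side chains.  Config-overridable.
EMBOSS_PKA = {
    "nterm": 8.6,
    "cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_ACIDIC_SIDE = ("D", "E", "C", "Y")
_BASIC_SIDE = ("H", "K", "R")

NEGATIVE_RESIDUES = ("D", "E")
POSITIVE_RESIDUES = ("K", "R", "H")

#: Number of descriptor columns: 20 + 400 + MW + frac_neg + frac_pos + gravy + pI.
N_DESCRIPTOR_COLUMNS = 425

DESCRIPTOR_COLUMNS: list[str] = (
    [f"frac_{aa}" for aa in AA_ORDER]
    + [f"dipep_{a}{b}" for a in AA_ORDER for b in AA_ORDER]
    + ["molecular_weight", "frac_negative", "frac_positive", "gravy",
       "isoelectric_point"]
)


@dataclass
class BiochemDescriptor:
    """The full descriptor record for one sequence.

    ``dipeptide_defined`` is False for single-residue sequences, whose 400
    pair ratios are all zero by convention.
    """

    aa_fractions: np.ndarray
    dipeptide_ratios: np.ndarray
    molecular_weight: float
    frac_negative: float
    frac_positive: float
    gravy: float
    isoelectric_point: float
    dipeptide_defined: bool = True

    def to_vector(self) -> np.ndarray:
        return np.concatenate([
            self.aa_fractions,
            self.dipeptide_ratios,
            [self.molecular_weight, self.frac_negative, self.frac_positive,
             self.gravy, self.isoelectric_point],
        ])


def _clean(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set(AA_ORDER) - {"X"}
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    return seq


def net_charge(sequence: str, ph: float, pka_table: dict | None = None) -> float:
    """Henderson–Hasselbalch net charge of a sequence at the given pH.

    Free N- and C-termini are always counted; side chains of D, E, C, Y
    (acidic) and H, K, R (basic) contribute per their pKa.  The function is
    strictly decreasing in pH, so a unique isoelectric point exists.
    """
    seq = _clean(sequence)
    pka = pka_table or EMBOSS_PKA

    def basic(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def acidic(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = basic(pka["nterm"]) + acidic(pka["cterm"])
    for aa in _BASIC_SIDE:
        n = seq.count(aa)
        if n:
            charge += n * basic(pka[aa])
    for aa in _ACIDIC_SIDE:
        n = seq.count(aa)
        if n:
            charge += n * acidic(pka[aa])
    return charge


def isoelectric_point(sequence: str, pka_table: dict | None = None) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    Iterates until |charge| < 1e-4 or the bracketing interval is narrower
    than 1e-4 pH units.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka_table)
        if abs(q) < 1e-4 or (hi - lo) < 1e-4:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def compute_descriptor(
    sequence: str,
    pka_table: dict | None = None,
) -> BiochemDescriptor:
    """Compute the full biochemical descriptor record for one sequence."""
    seq = _clean(sequence)
    counted = [aa for aa in seq if aa != "X"]
    if not counted:
        raise ValueError("sequence contains only unknown (X) residues")
    n = len(counted)

    counts = np.zeros(20)
    for aa in counted:
        counts[_AA_INDEX[aa]] += 1
    fractions = counts / n

    # ordered-pair counts over adjacent positions; pairs touching an X are
    # skipped, the denominator is the number of counted adjacent pairs
    dipep = np.zeros(400)
    n_pairs = 0
    for a, b in zip(seq, seq[1:]):
        if a == "X" or b == "X":
            continue
        dipep[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
        n_pairs += 1
    defined = n_pairs > 0
    if defined:
        dipep /= n_pairs

    mw = sum(RESIDUE_MASS[aa] for aa in counted) + WATER_MASS
    frac_neg = sum(counts[_AA_INDEX[aa]] for aa in NEGATIVE_RESIDUES) / n
    frac_pos = sum(counts[_AA_INDEX[aa]] for aa in POSITIVE_RESIDUES) / n
    gravy = sum(KYTE_DOOLITTLE[aa] for aa in counted) / n
    pi = isoelectric_point(seq, pka_table)

    return BiochemDescriptor(
        aa_fractions=fractions,
        dipeptide_ratios=dipep,
        molecular_weight=mw,
        frac_negative=frac_neg,
        frac_positive=frac_pos,
        gravy=gravy,
        isoelectric_point=pi,
        dipeptide_defined=defined,
    )


def build_biochem_source(
    proteins: ProteinSet,
    pka_table: dict | None = None,
) -> FeatureSource:
    """Compute the 425-column numeric-dense descriptor source for a
    ProteinSet.  Every protein must carry a sequence."""
    if proteins.sequences is None:
        raise ValueError("ProteinSet carries no sequences")
    rows = []
    for pid in proteins.ids:
        seq = proteins.sequences.get(pid)
        if seq is None:
            raise ValueError(f"protein {pid!r} has no sequence")
        rows.append(compute_descriptor(seq, pka_table).to_vector())
    matrix = np.vstack(rows) if rows else np.zeros((0, N_DESCRIPTOR_COLUMNS))
    return FeatureSource(
        name="biochem",
        matrix=matrix,
        kind=NUMERIC_DENSE,
        vocabulary=list(DESCRIPTOR_COLUMNS),
        protein_ids=list(proteins.ids),
    )
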