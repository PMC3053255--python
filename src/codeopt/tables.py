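"""Embedded reference data: bases, amino acids, the standard genetic code,
the polar requirement scale, and the default mistranslation weights.

Codon enumeration order is base1-major over U, C, A, G (first base slowest,
third fastest), mirroring the row order of NCBI translation tables with
T read as U.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

#: RNA alphabet in enumeration order.
BASES = "UCAG"

#: Purine/pyrimidine classes; a substitution within a set is a transition.
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("UC")

#: The 20 amino acids, one-letter codes, alphabetical; index 20 is stop.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"
STOP_INDEX = 20
N_AA = 20
N_CODONS = 64

#: All 64 codons in the declared order.
CODONS = tuple(b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# Woese's polar requirement: partition coefficient of each amino acid in a
# water/dimethylpyridine system, the hydrophobicity-like property used
# throughout the load-minimization literature (dimensionless).
POLAR_REQUIREMENT = {
    "A": 7.0, "C": 4.8, "D": 13.0, "E": 12.5, "F": 5.0,
    "G": 7.9, "H": 8.4, "I": 4.9, "K": 10.1, "L": 4.9,
    "M": 5.3, "N": 10.0, "P": 6.6, "Q": 8.6, "R": 9.1,
    "S": 7.5, "T": 6.6, "V": 5.6, "W": 5.2, "Y": 5.4,
}

# Relative mistranslation efficiency of each codon base, by substitution
# class: empirically, second-base errors are rare (and transversions there
# rarest) while third-base errors are common.
DEFAULT_MISTRANSLATION_WEIGHTS = {
    ("transition", 1): 1.0, ("transition", 2): 0.5, ("transition", 3): 1.0,
    ("transversion", 1): 0.5, ("transversion", 2): 0.1, ("transversion", 3): 1.0,
}


def _standard_code_labels() -> np.ndarray:
    """Label array of the standard genetic code (NCBI table 1), indices
    into AMINO_ACIDS with STOP_INDEX for the three stop codons."""
    table = CodonTable.unambiguous_rna_by_id[1]
    labels = np.empty(N_CODONS, dtype=np.int8)
    for codon, aa in table.forward_table.items():
        labels[CODON_INDEX[codon]] = AMINO_ACIDS.index(aa)
    for codon in table.stop_codons:
        labels[CODON_INDEX[codon]] = STOP_INDEX
    return labels


STANDARD_CODE_LABELS = _standard_code_labels()
STANDARD_CODE_LABELS.setflags(write=False)

#: Canonical stop codon indices (UAA, UAG, UGA).
STOP_CODON_INDICES = tuple(int(i) for i in np.flatnonzero(STANDARD_CODE_LABELS == STOP_INDEX))
SENSE_CODON_INDICES = tuple(int(i) for i in np.flatnonzero(STANDARD_CODE_LABELS != STOP_INDEX))
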