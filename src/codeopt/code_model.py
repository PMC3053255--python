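"""Genetic code tables, codon arithmetic, and random-code generators.

Two models of hypothetical codes are supported:

* **Model 1** (restrictive / block-permutation codes): the 64 codons keep
  the synonym-block structure of the standard code; an alternative code is
  a bijection of the 20 amino acids onto the 20 sense blocks.  The stop
  codons stay at their canonical positions, so the space has 20! members.
* **Model 2** (codon-reassignment codes): every one of the 61 sense codons
  may carry any amino acid, as long as all 20 amino acids are encoded
  somewhere; the 3 stop codons stay at their canonical positions.  This
  is the space reachable by natural single-codon reassignments.

Codes serialize to a 64-character one-letter amino-acid string ('*' for
stop) in base1-major U,C,A,G codon order, modeled on the "ncbieaa" strings
of NCBI translation tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .tables import (
    AMINO_ACIDS,
    BASES,
    CODON_INDEX,
    CODONS,
    N_AA,
    N_CODONS,
    PURINES,
    PYRIMIDINES,
    SENSE_CODON_INDICES,
    STANDARD_CODE_LABELS,
    STOP,
    STOP_CODON_INDICES,
    STOP_INDEX,
)

__all__ = [
    "CodeAssignment",
    "BlockStructure",
    "PropertyScale",
    "canonical_code",
    "canonical_blocks",
    "codon_neighbors",
    "is_transition",
    "random_permutation_code",
    "random_reassignment_code",
    "parse_code_table",
    "write_code_table",
    "parse_property_scale",
    "model1_code_space_size",
]

CODE_TABLE_HEADER = "# codon-order=U C A G, base1-major"


def _validate_codon(codon: str) -> str:
    codon = codon.upper().replace("T", "U")
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}: need 3 bases from U/C/A/G")
    return codon


def is_transition(a: str, b: str) -> bool:
    """True if the substitution a→b is a transition (purine↔purine or
    pyrimidine↔pyrimidine), False for a transversion.

    Raises ValueError if a == b (no mutation) or either base is invalid.
    """
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    if a not in BASES or b not in BASES:
        raise ValueError(f"invalid base in ({a!r}, {b!r})")
    if a == b:
        raise ValueError("identical bases do not form a mutation")
    return ({a, b} <= PURINES) or ({a, b} <= PYRIMIDINES)


def codon_neighbors(codon: str) -> list[tuple[str, int, str]]:
    """All 9 single-base mutants of a codon.

    Returns (neighbor, position, mutation_class) triples, where position is
    1-based and mutation_class is 'transition' or 'transversion'.
    """
    codon = _validate_codon(codon)
    out = []
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            cls = "transition" if is_transition(codon[pos], base) else "transversion"
            out.append((mutant, pos + 1, cls))
    return out


class CodeAssignment:
    """A genetic code: mapping of each of the 64 codons to one of the 20
    amino acids or the stop signal.

    Invariants (enforced on construction): all 64 codons labeled, exactly 3
    stop codons, every amino acid encoded by at least one codon.

    The canonical in-memory form is ``labels``, an int8 array of length 64
    in base1-major U,C,A,G codon order holding indices into
    :data:`codeopt.tables.AMINO_ACIDS`, with 20 for stop.
    """

    __slots__ = ("labels",)

    def __init__(self, labels: np.ndarray | Sequence[int]):
        labels = np.asarray(labels, dtype=np.int8)
        if labels.shape != (N_CODONS,):
            raise ValueError(f"need {N_CODONS} codon labels, got shape {labels.shape}")
        if labels.min() < 0 or labels.max() > STOP_INDEX:
            raise ValueError("labels must be amino-acid indices 0-19 or 20 (stop)")
        n_stop = int(np.sum(labels == STOP_INDEX))
        if n_stop != 3:
            raise ValueError(f"a code must have exactly 3 stop codons, got {n_stop}")
        present = np.unique(labels[labels != STOP_INDEX])
        if present.size != N_AA:
            missing = sorted(set(range(N_AA)) - set(int(i) for i in present))
            names = ", ".join(AMINO_ACIDS[i] for i in missing)
            raise ValueError(f"every amino acid must be encoded; missing: {names}")
        self.labels = labels
        self.labels.setflags(write=False)

    @classmethod
    def from_mapping(cls, assignment: Mapping[str, str]) -> "CodeAssignment":
        """Build from a codon→label dict ('*' or 'stop' for stop codons)."""
        labels = np.full(N_CODONS, -1, dtype=np.int8)
        for codon, label in assignment.items():
            idx = CODON_INDEX[_validate_codon(codon)]
            if label in (STOP, "stop", "Stop"):
                labels[idx] = STOP_INDEX
            else:
                labels[idx] = AMINO_ACIDS.index(label.upper())
        if (labels < 0).any():
            raise ValueError("assignment must cover all 64 codons")
        return cls(labels)

    def to_mapping(self) -> dict[str, str]:
        return {c: self[c] for c in CODONS}

    def __getitem__(self, codon: str) -> str:
        label = self.labels[CODON_INDEX[_validate_codon(codon)]]
        return STOP if label == STOP_INDEX else AMINO_ACIDS[label]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodeAssignment) and np.array_equal(self.labels, other.labels)

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def __repr__(self) -> str:
        return f"CodeAssignment({write_code_table(self, header=False)!r})"

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(CODONS[int(i)] for i in np.flatnonzero(self.labels == STOP_INDEX))

    def codons_for(self, amino_acid: str) -> tuple[str, ...]:
        idx = AMINO_ACIDS.index(amino_acid.upper())
        return tuple(CODONS[int(i)] for i in np.flatnonzero(self.labels == idx))

    def counts(self) -> np.ndarray:
        """Number of codons per amino-acid index (length 20)."""
        return np.bincount(self.labels[self.labels != STOP_INDEX], minlength=N_AA)


@dataclass(frozen=True)
class BlockStructure:
    """The canonical partition of the 64 codons into 21 synonym sets: one
    block per amino acid of the standard code (ordered alphabetically by
    its canonical amino acid) plus the stop block."""

    sense_blocks: tuple[tuple[int, ...], ...]  # 20 blocks of codon indices
    stop_block: tuple[int, ...]

    def __post_init__(self):
        covered = sorted(i for b in self.sense_blocks for i in b) + sorted(self.stop_block)
        if sorted(covered) != list(range(N_CODONS)):
            raise ValueError("blocks must partition the 64 codons")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.sense_blocks)

    def assemble(self, block_to_aa: Sequence[int]) -> CodeAssignment:
        """Code with block b assigned amino-acid index block_to_aa[b]."""
        perm = np.asarray(block_to_aa)
        if sorted(perm.tolist()) != list(range(N_AA)):
            raise ValueError("block_to_aa must be a permutation of the 20 amino acids")
        labels = np.full(N_CODONS, STOP_INDEX, dtype=np.int8)
        for block, aa in zip(self.sense_blocks, perm):
            labels[list(block)] = aa
        return CodeAssignment(labels)

    def permutation_of(self, code: CodeAssignment) -> np.ndarray:
        """Inverse of assemble: the block→amino-acid permutation of a
        model-1 code. Raises ValueError if the code does not respect the
        block structure."""
        perm = np.empty(N_AA, dtype=np.int8)
        for b, block in enumerate(self.sense_blocks):
            labels = {int(code.labels[i]) for i in block}
            if len(labels) != 1 or STOP_INDEX in labels:
                raise ValueError(f"code is not constant on sense block {b}")
            perm[b] = labels.pop()
        if set(code.stop_codons) != {CODONS[i] for i in self.stop_block}:
            raise ValueError("stop codons are not at canonical positions")
        return perm


def canonical_code() -> CodeAssignment:
    """The standard genetic code (NCBI translation table 1); stops at
    UAA, UAG, UGA."""
    return CodeAssignment(STANDARD_CODE_LABELS.copy())


def _build_canonical_blocks() -> BlockStructure:
    blocks = []
    for aa in range(N_AA):
        blocks.append(tuple(int(i) for i in np.flatnonzero(STANDARD_CODE_LABELS == aa)))
    return BlockStructure(tuple(blocks), STOP_CODON_INDICES)


_CANONICAL_BLOCKS = _build_canonical_blocks()


def canonical_blocks() -> BlockStructure:
    """The standard code's synonym-block partition (degeneracy pattern)."""
    return _CANONICAL_BLOCKS


def model1_code_space_size() -> int:
    """Number of distinct model-1 codes: one per bijection of the 20 amino
    acids onto the 20 canonical sense blocks, i.e. 20!."""
    return math.factorial(N_AA)


def random_permutation_code(rng: np.random.Generator) -> CodeAssignment:
    """Uniformly random model-1 code: canonical block structure with the 20
    amino acids randomly permuted over the 20 sense blocks."""
    return _CANONICAL_BLOCKS.assemble(rng.permutation(N_AA))


def random_reassignment_code(rng: np.random.Generator) -> CodeAssignment:
    """Uniformly random model-2 code: the 61 sense codons carry independent
    uniform amino acids, conditioned (by rejection) on all 20 amino acids
    being present; stops fixed at canonical positions."""
    sense = list(SENSE_CODON_INDICES)
    while True:
        draw = rng.integers(0, N_AA, size=len(sense))
        if np.unique(draw).size == N_AA:
            labels = np.full(N_CODONS, STOP_INDEX, dtype=np.int8)
            labels[sense] = draw
            return CodeAssignment(labels)


def write_code_table(code: CodeAssignment, header: bool = True) -> str:
    """Serialize a code to its 64-character amino-acid string (optionally
    preceded by the codon-order header line)."""
    chars = "".join(
        STOP if l == STOP_INDEX else AMINO_ACIDS[l] for l in code.labels
    )
    return f"{CODE_TABLE_HEADER}\n{chars}\n" if header else chars


def parse_code_table(text: str) -> CodeAssignment:
    """Parse a code-table string: comment lines (#) are skipped, the first
    remaining line must be the 64-character amino-acid string with '*' for
    stop.  Violated invariants raise ValueError with a message naming them."""
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty code table")
    s = lines[0].upper()
    if len(s) != N_CODONS:
        raise ValueError(f"code string must have 64 characters, got {len(s)}")
    labels = np.empty(N_CODONS, dtype=np.int8)
    for i, ch in enumerate(s):
        if ch == STOP:
            labels[i] = STOP_INDEX
        elif ch in AMINO_ACIDS:
            labels[i] = AMINO_ACIDS.index(ch)
        else:
            raise ValueError(f"illegal character {ch!r} at codon {CODONS[i]}")
    return CodeAssignment(labels)


class PropertyScale:
    """An amino-acid property scale: one finite real value per amino acid.

    The default instance used throughout is the polar requirement
    (:data:`codeopt.tables.POLAR_REQUIREMENT`)."""

    __slots__ = ("values",)

    def __init__(self, values: Mapping[str, float]):
        keys = set(values)
        if keys != set(AMINO_ACIDS):
            raise ValueError("scale must cover exactly the 20 amino acids")
        arr = np.array([float(values[aa]) for aa in AMINO_ACIDS])
        if not np.all(np.isfinite(arr)):
            raise ValueError("scale values must be finite")
        self.values = arr
        self.values.setflags(write=False)

    def __getitem__(self, aa: str) -> float:
        return float(self.values[AMINO_ACIDS.index(aa.upper())])

    def items(self) -> Iterator[tuple[str, float]]:
        return ((aa, float(v)) for aa, v in zip(AMINO_ACIDS, self.values))

    @classmethod
    def polar_requirement(cls) -> "PropertyScale":
        from .tables import POLAR_REQUIREMENT

        return cls(POLAR_REQUIREMENT)


def parse_property_scale(text: str) -> PropertyScale:
    """Parse a two-column TSV (amino-acid one-letter code TAB value)."""
    values: dict[str, float] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise ValueError(f"malformed scale line: {ln!r}")
        values[parts[0].upper()] = float(parts[1])
    return PropertyScale(values)
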