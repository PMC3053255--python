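"""Error-minimization fitness of genetic codes.

The MS (mean square) statistic of a code is the average squared change in
an amino-acid property over all single-base substitutions of all codons:

    MS = sum_ij N_ij (X_i - X_j)^2 / sum_ij N_ij

where N_ij counts ordered substitution events turning amino acid i into j
and X is the property scale (polar requirement by default).  Substitutions
from or to stop codons are ignored; synonymous substitutions (i = j) are
counted in the denominator and contribute zero to the numerator.  For the
standard code this leaves 526 of the 64x9 = 576 ordered codon pairs.

tMS is the weighted variant: each event is weighted by its codon position
(1-3) and substitution class (transition/transversion) to model empirical
mistranslation biases, and MS becomes a weighted mean.

Events are enumerated as ordered pairs (both directions of each
substitution).  (X_i - X_j)^2 is symmetric, so this doubles numerator and
denominator alike and leaves the statistic unchanged, while making the
526-event count reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .code_model import CodeAssignment, PropertyScale
from .tables import (
    AMINO_ACIDS,
    BASES,
    CODONS,
    DEFAULT_MISTRANSLATION_WEIGHTS,
    N_CODONS,
    PURINES,
    STANDARD_CODE_LABELS,
    STOP_INDEX,
)

__all__ = [
    "MistranslationWeights",
    "SubstitutionEvent",
    "substitution_events",
    "ms",
    "tms",
    "parse_weights_tsv",
]

MutationClass = str  # 'transition' | 'transversion'


class MistranslationWeights:
    """Per-(codon position, substitution class) weights for tMS.

    Six entries: positions 1-3 crossed with transition/transversion.  The
    defaults are the empirical mistranslation quantification used in the
    load-minimization literature: transitions (1, 0.5, 1), transversions
    (0.5, 0.1, 1) for bases 1-3.
    """

    __slots__ = ("_w",)

    def __init__(self, weights: Optional[Mapping[tuple[str, int], float]] = None):
        src = dict(DEFAULT_MISTRANSLATION_WEIGHTS if weights is None else weights)
        expected = {(c, p) for c in ("transition", "transversion") for p in (1, 2, 3)}
        if set(src) != expected:
            raise ValueError("weights need exactly the 6 (class, position) entries")
        vals = {k: float(v) for k, v in src.items()}
        if any(not np.isfinite(v) or v < 0 for v in vals.values()):
            raise ValueError("weights must be finite and nonnegative")
        if all(v == 0 for v in vals.values()):
            raise ValueError("all-zero weights leave the weighted mean undefined")
        self._w = vals

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self._w[key]

    def items(self):
        return self._w.items()

    @classmethod
    def uniform(cls) -> "MistranslationWeights":
        return cls({(c, p): 1.0 for c in ("transition", "transversion") for p in (1, 2, 3)})

    def as_array(self) -> np.ndarray:
        """(2, 3) array: row 0 transitions, row 1 transversions; columns
        are codon positions 1-3."""
        out = np.empty((2, 3))
        for j, cls_ in enumerate(("transition", "transversion")):
            for p in (1, 2, 3):
                out[j, p - 1] = self._w[(cls_, p)]
        return out


def parse_weights_tsv(text: str) -> MistranslationWeights:
    """Parse weights from TSV lines: position TAB class TAB weight."""
    entries: dict[tuple[str, int], float] = {}
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 3:
            raise ValueError(f"malformed weights line: {ln!r}")
        pos, cls_, w = int(parts[0]), parts[1].lower(), float(parts[2])
        entries[(cls_, pos)] = w
    return MistranslationWeights(entries)


# ---------------------------------------------------------------------------
# Precomputed neighbor-pair geometry (independent of any code)
# ---------------------------------------------------------------------------

def _build_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All 576 ordered (codon, single-base neighbor) pairs, with the mutated
    position (0-based) and transition flag."""
    src, dst, pos, ts = [], [], [], []
    for i, codon in enumerate(CODONS):
        for p in range(3):
            for b in BASES:
                if b == codon[p]:
                    continue
                mutant = codon[:p] + b + codon[p + 1:]
                src.append(i)
                dst.append(CODONS.index(mutant))
                pos.append(p)
                ts.append((codon[p] in PURINES) == (b in PURINES))
    return (np.array(src), np.array(dst), np.array(pos), np.array(ts, dtype=bool))

PAIR_SRC, PAIR_DST, PAIR_POS, PAIR_IS_TRANSITION = _build_pairs()

# Pairs whose endpoints are both sense codons under canonical stops: the
# fixed event set of every code with stops at the canonical positions.
_CANON_SENSE = (STANDARD_CODE_LABELS[PAIR_SRC] != STOP_INDEX) & (
    STANDARD_CODE_LABELS[PAIR_DST] != STOP_INDEX
)
CANON_PAIR_SRC = PAIR_SRC[_CANON_SENSE]
CANON_PAIR_DST = PAIR_DST[_CANON_SENSE]
CANON_PAIR_POS = PAIR_POS[_CANON_SENSE]
CANON_PAIR_IS_TRANSITION = PAIR_IS_TRANSITION[_CANON_SENSE]


def _pair_weights(w: MistranslationWeights, pos: np.ndarray, is_ts: np.ndarray) -> np.ndarray:
    arr = w.as_array()
    return arr[np.where(is_ts, 0, 1), pos]


@dataclass(frozen=True)
class SubstitutionEvent:
    """One counted single-base substitution between two sense codons."""

    aa_from: str
    aa_to: str
    position: int  # 1-based codon position
    mutation_class: MutationClass


def substitution_events(code: CodeAssignment) -> list[SubstitutionEvent]:
    """Enumerate the counted events of a code: every ordered (codon,
    neighbor) pair where both codons encode amino acids.  Stops are
    filtered by the code's own stop positions."""
    labels = code.labels
    keep = (labels[PAIR_SRC] != STOP_INDEX) & (labels[PAIR_DST] != STOP_INDEX)
    events = []
    for s, d, p, ts in zip(
        PAIR_SRC[keep], PAIR_DST[keep], PAIR_POS[keep], PAIR_IS_TRANSITION[keep]
    ):
        events.append(
            SubstitutionEvent(
                AMINO_ACIDS[labels[s]],
                AMINO_ACIDS[labels[d]],
                int(p) + 1,
                "transition" if ts else "transversion",
            )
        )
    return events


def _event_arrays(code: CodeAssignment, scale: PropertyScale):
    labels = code.labels
    keep = (labels[PAIR_SRC] != STOP_INDEX) & (labels[PAIR_DST] != STOP_INDEX)
    if not keep.any():
        raise ValueError("degenerate code: no substitution events between sense codons")
    x = scale.values
    diff = x[labels[PAIR_SRC[keep]]] - x[labels[PAIR_DST[keep]]]
    return diff, PAIR_POS[keep], PAIR_IS_TRANSITION[keep]


def ms(code: CodeAssignment, scale: Optional[PropertyScale] = None) -> float:
    """Mean squared property change of a code over all counted single-base
    substitutions (default scale: polar requirement)."""
    scale = scale or PropertyScale.polar_requirement()
    diff, _, _ = _event_arrays(code, scale)
    return float(np.sum(diff * diff) / diff.size)


def tms(
    code: CodeAssignment,
    scale: Optional[PropertyScale] = None,
    weights: Optional[MistranslationWeights] = None,
) -> float:
    """Mistranslation-weighted mean squared property change: each event is
    weighted by its codon position and transition/transversion class."""
    scale = scale or PropertyScale.polar_requirement()
    weights = weights or MistranslationWeights()
    diff, pos, is_ts = _event_arrays(code, scale)
    w = _pair_weights(weights, pos, is_ts)
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("all counted events have zero weight; tMS undefined")
    return float(np.sum(w * diff * diff) / wsum)


# ---------------------------------------------------------------------------
# Vectorized population evaluators (canonical stop positions assumed)
# ---------------------------------------------------------------------------

class PopulationEvaluator:
    """Scores whole populations of codes with canonical stop positions.

    Model-2 populations are (n, 64) label matrices; model-1 populations are
    (n, 20) block→amino-acid permutation matrices.  Both reduce to sums of
    (weighted) squared property differences over the fixed 526-pair event
    set, precomputed here once per (scale, weights) pair.
    """

    def __init__(
        self,
        scale: Optional[PropertyScale] = None,
        weights: Optional[MistranslationWeights] = None,
    ):
        self.scale = scale or PropertyScale.polar_requirement()
        self.weights = weights
        if weights is None:
            self._w = np.ones(CANON_PAIR_SRC.size)
        else:
            self._w = _pair_weights(weights, CANON_PAIR_POS, CANON_PAIR_IS_TRANSITION)
        self._wsum = self._w.sum()
        # model-1 reduction: weighted event counts between canonical blocks
        block_of = np.full(N_CODONS, -1)
        from .code_model import canonical_blocks

        for b, block in enumerate(canonical_blocks().sense_blocks):
            block_of[list(block)] = b
        bs, bd = block_of[CANON_PAIR_SRC], block_of[CANON_PAIR_DST]
        m = np.zeros((20, 20))
        np.add.at(m, (bs, bd), self._w)
        self._block_matrix = m + m.T  # symmetrized: quadratic-form kernel
        self._block_rowsum = self._block_matrix.sum(axis=1)

    def labels_fitness(self, labels: np.ndarray) -> np.ndarray:
        """Fitness of an (n, 64) population of label matrices (stops must
        sit at canonical positions; not rechecked here)."""
        x = self.scale.values
        props = np.where(labels == STOP_INDEX, 0.0, x[np.minimum(labels, 19)])
        d = props[:, CANON_PAIR_SRC] - props[:, CANON_PAIR_DST]
        return (d * d) @ self._w / self._wsum

    def permutation_fitness(self, perms: np.ndarray) -> np.ndarray:
        """Fitness of an (n, 20) population of model-1 block→amino-acid
        permutations, via the precomputed between-block event kernel."""
        x = self.scale.values[perms]  # (n, 20) property per block
        quad = np.einsum("ni,ij,nj->n", x, self._block_matrix, x)
        return ((x * x) @ self._block_rowsum - quad) / self._wsum
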