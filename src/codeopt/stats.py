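"""Optimality statistics for genetic codes.

Two classical ways of judging how optimized the standard code is:

* the **statistical approach** samples many random hypothetical codes and
  asks what fraction beats the canonical code (lower error);
* the **engineering approach** computes the percentage distance
  minimization (p.d.m.), placing the canonical code's error on the linear
  scale between the random-code mean (0%) and the best code found (100%):

      p.d.m. = 100 * (D_mean - D_code) / (D_mean - D_low)

Also provided: histograms of sampled code errors (with the bin holding the
canonical value, for random-vs-evolved population comparisons), and
quantitative proxies for the two qualitative regularities of optimized
codes — similarity of amino acids along the first codon position
(pattern I) and within second-position pyrimidine/purine sets (pattern II).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .code_model import CodeAssignment, PropertyScale
from .evolution import _init_population  # shared uniform generators
from .fitness import MistranslationWeights, PopulationEvaluator
from .tables import BASES, CODONS, PYRIMIDINES, STOP_INDEX

__all__ = [
    "FitnessSample",
    "PdmResult",
    "sample_random_codes",
    "fraction_better",
    "pdm",
    "histogram",
    "pattern_scores",
]


@dataclass(frozen=True)
class FitnessSample:
    """Error values of a sample of random codes, with provenance."""

    values: np.ndarray
    model: int
    fitness_kind: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("sample must be a non-empty 1-D array")
        if (self.values < 0).any():
            raise ValueError("error values must be nonnegative")


@dataclass(frozen=True)
class PdmResult:
    """Percentage distance minimization with its three inputs."""

    delta_mean: float
    delta_code: float
    delta_low: float

    @property
    def pdm(self) -> float:
        return 100.0 * (self.delta_mean - self.delta_code) / (self.delta_mean - self.delta_low)


def sample_random_codes(
    model: int,
    fitness_kind: str,
    n: int,
    rng: np.random.Generator,
    scale: Optional[PropertyScale] = None,
    weights: Optional[MistranslationWeights] = None,
) -> FitnessSample:
    """Draw n random codes from the chosen model's uniform generator and
    score each with MS or tMS."""
    if n < 1:
        raise ValueError("n must be >= 1")
    fitness_kind = fitness_kind.lower()
    if fitness_kind not in ("ms", "tms"):
        raise ValueError("fitness_kind must be 'ms' or 'tms'")
    from .evolution import EvolutionConfig

    cfg = EvolutionConfig(
        model=model,
        fitness_kind=fitness_kind,
        population_size=n,
        replicates=1,
        scale=scale,
        weights=weights,
    )
    evaluator = cfg.evaluator()
    pop = _init_population(cfg, rng)
    values = (
        evaluator.permutation_fitness(pop) if model == 1 else evaluator.labels_fitness(pop)
    )
    return FitnessSample(values=values, model=model, fitness_kind=fitness_kind)


def fraction_better(sample: FitnessSample, reference: float) -> float:
    """Proportion of sampled codes with error strictly below the reference
    (ties count as not better)."""
    return float(np.mean(sample.values < reference))


def pdm(delta_mean: float, delta_code: float, delta_low: float) -> PdmResult:
    """Percentage distance minimization of a code whose error is delta_code,
    relative to the random-code mean delta_mean and best-found delta_low."""
    if not delta_mean > delta_low:
        raise ValueError("pdm undefined: requires delta_mean > delta_low")
    return PdmResult(float(delta_mean), float(delta_code), float(delta_low))


def histogram(
    sample: FitnessSample, bins: int = 30, reference: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray, Optional[int]]:
    """Equal-width histogram of a fitness sample over [min, max].

    Returns (counts, bin_edges, reference_bin) where reference_bin is the
    index of the bin containing the reference value (the canonical code's
    error, say), or None if no reference was given or it lies outside the
    sampled range.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    v = sample.values
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:  # degenerate single-value sample
        hi = lo + 1.0
    counts, edges = np.histogram(v, bins=bins, range=(lo, hi))
    ref_bin = None
    if reference is not None and edges[0] <= reference <= edges[-1]:
        ref_bin = min(int(np.searchsorted(edges, reference, side="right")) - 1, bins - 1)
    return counts, edges, ref_bin


def _sense_property(code: CodeAssignment, scale: PropertyScale) -> np.ndarray:
    """Property value per codon, NaN at the code's stop positions."""
    props = np.full(64, np.nan)
    sense = code.labels != STOP_INDEX
    props[sense] = scale.values[code.labels[sense]]
    return props


def pattern_scores(code: CodeAssignment, scale: Optional[PropertyScale] = None) -> tuple[float, float]:
    """Quantitative proxies for the two regularities of optimized codes.

    pattern1: mean within-group property variance of sense codons grouped
    by (base2, base3) — i.e. varying base 1 — minus the same grouped by
    (base1, base3) — varying base 2.  Negative means amino acids are more
    alike along the first codon position than the second (pattern I).

    pattern2: over sense codon pairs differing only at the second base,
    the mean squared property difference of cross-set pairs (pyrimidine vs
    purine base) minus that of within-set pairs.  Positive means amino
    acids are more alike within second-position pyrimidine/purine sets
    than between them (pattern II).
    """
    scale = scale or PropertyScale.polar_requirement()
    props = _sense_property(code, scale)
    idx = {c: i for i, c in enumerate(CODONS)}

    def mean_group_variance(varying_pos: int) -> float:
        variances = []
        others = [p for p in range(3) if p != varying_pos]
        for b_a in BASES:
            for b_b in BASES:
                group = []
                for b_v in BASES:
                    codon = ["", "", ""]
                    codon[varying_pos] = b_v
                    codon[others[0]], codon[others[1]] = b_a, b_b
                    v = props[idx["".join(codon)]]
                    if np.isfinite(v):
                        group.append(v)
                if len(group) >= 2:
                    variances.append(np.var(group))
        return float(np.mean(variances))

    pattern1 = mean_group_variance(0) - mean_group_variance(1)

    within, across = [], []
    for b1 in BASES:
        for b3 in BASES:
            for b2a in BASES:
                for b2b in BASES:
                    if b2a == b2b:
                        continue
                    va = props[idx[b1 + b2a + b3]]
                    vb = props[idx[b1 + b2b + b3]]
                    if not (np.isfinite(va) and np.isfinite(vb)):
                        continue
                    same_set = (b2a in PYRIMIDINES) == (b2b in PYRIMIDINES)
                    (within if same_set else across).append((va - vb) ** 2)
    pattern2 = float(np.mean(across) - np.mean(within))
    return pattern1, pattern2
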