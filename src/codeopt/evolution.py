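"""Genetic algorithm searching for better-adapted hypothetical codes.

Each individual of the population is a hypothetical code.  Under model 1
the genotype is the permutation assigning the 20 amino acids to the 20
canonical synonym blocks and variation is a swap of two blocks' amino
acids; under model 2 the genotype is the full 61-sense-codon assignment
and variation is a single-codon reassignment mimicking natural codon
reassignments: a random sense codon's amino acid is copied onto a random
single-base sense neighbor, unless that neighbor's amino acid is its only
instance in the code (the move would lose an amino acid, so it is not
applied).

Selection is tournament (best of a random window, default 3% of the
population) with elitism of the single best individual.  Fitness is MS or
tMS, minimized.  Runs stop at a generation cap or when the best fitness
has not improved for a plateau window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .code_model import (
    BlockStructure,
    CodeAssignment,
    canonical_blocks,
)
from .fitness import MistranslationWeights, PopulationEvaluator
from .code_model import PropertyScale
from .tables import N_AA, N_CODONS, SENSE_CODON_INDICES, STOP_INDEX
from .fitness import PAIR_SRC, PAIR_DST

__all__ = [
    "EvolutionConfig",
    "ReplicateTrace",
    "EvolutionTrace",
    "swap_operator",
    "reassignment_operator",
    "tournament_select",
    "evolve",
]

# sense single-base neighbors of each sense codon (codes with canonical
# stops only); ragged, stored padded with -1
def _sense_neighbor_table() -> tuple[np.ndarray, np.ndarray]:
    sense = set(SENSE_CODON_INDICES)
    lists = {i: [] for i in SENSE_CODON_INDICES}
    for s, d in zip(PAIR_SRC, PAIR_DST):
        if s in sense and d in sense:
            lists[int(s)].append(int(d))
    width = max(len(v) for v in lists.values())
    table = np.full((N_CODONS, width), -1, dtype=np.int64)
    counts = np.zeros(N_CODONS, dtype=np.int64)
    for i, v in lists.items():
        table[i, : len(v)] = v
        counts[i] = len(v)
    return table, counts


_SENSE_NEIGHBORS, _SENSE_NEIGHBOR_COUNTS = _sense_neighbor_table()
_SENSE = np.array(SENSE_CODON_INDICES)


@dataclass
class EvolutionConfig:
    """Run parameters of the code-search GA.

    plateau_generations: a run ends early once the best fitness has not
    improved for this many consecutive generations (0 disables).
    """

    model: int = 1
    fitness_kind: str = "ms"  # 'ms' | 'tms'
    population_size: int = 1000
    tournament_fraction: float = 0.03
    generations: int = 0  # 0 → model default (100 for model 1, 300 for model 2)
    replicates: int = 50
    seed: int = 0
    operator_probability: float = 1.0
    plateau_generations: int = 25
    scale: Optional[PropertyScale] = None
    weights: Optional[MistranslationWeights] = None

    def __post_init__(self):
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.fitness_kind.lower() not in ("ms", "tms"):
            raise ValueError("fitness_kind must be 'ms' or 'tms'")
        self.fitness_kind = self.fitness_kind.lower()
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if not (0 < self.tournament_fraction <= 1):
            raise ValueError("tournament_fraction must be in (0, 1]")
        if not (0 <= self.operator_probability <= 1):
            raise ValueError("operator_probability must be in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be positive")
        if self.generations == 0:
            self.generations = 100 if self.model == 1 else 300
        if self.generations < 1:
            raise ValueError("generations must be positive")

    @property
    def tournament_window(self) -> int:
        return max(1, round(self.tournament_fraction * self.population_size))

    def evaluator(self) -> PopulationEvaluator:
        w = None
        if self.fitness_kind == "tms":
            w = self.weights or MistranslationWeights()
        return PopulationEvaluator(scale=self.scale, weights=w)


@dataclass
class ReplicateTrace:
    """Per-generation record of one GA run."""

    best: np.ndarray  # best fitness per generation
    mean: np.ndarray  # population mean fitness per generation
    best_code: CodeAssignment
    best_fitness: float
    spawn_key: tuple


@dataclass
class EvolutionTrace:
    """Aggregate of all replicate runs of one configuration."""

    config: EvolutionConfig
    replicates: list[ReplicateTrace] = field(default_factory=list)

    @property
    def best_finals(self) -> np.ndarray:
        return np.array([r.best_fitness for r in self.replicates])

    @property
    def best_overall(self) -> float:
        return float(self.best_finals.min())

    def mean_curves(self) -> tuple[np.ndarray, np.ndarray]:
        """(best, mean) fitness curves averaged over replicates; runs that
        plateaued early are extended by their final value."""
        length = max(r.best.size for r in self.replicates)

        def pad(a: np.ndarray) -> np.ndarray:
            return np.concatenate([a, np.full(length - a.size, a[-1])])

        best = np.mean([pad(r.best) for r in self.replicates], axis=0)
        mean = np.mean([pad(r.mean) for r in self.replicates], axis=0)
        return best, mean


def swap_operator(code: CodeAssignment, i: int, j: int,
                  blocks: Optional[BlockStructure] = None) -> CodeAssignment:
    """Model-1 variation: exchange the amino acids of sense blocks i and j
    (0-based block indices).  Returns a new code; the input is unchanged."""
    blocks = blocks or canonical_blocks()
    n = len(blocks.sense_blocks)
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"block indices must be in 0..{n - 1}")
    perm = blocks.permutation_of(code).copy()
    perm[i], perm[j] = perm[j], perm[i]
    return blocks.assemble(perm)


def reassignment_operator(code: CodeAssignment, rng: np.random.Generator) -> CodeAssignment:
    """Model-2 variation: pick a random sense codon and copy its amino acid
    onto a random single-base sense neighbor.  If the neighbor's amino acid
    is the sole instance in the code the operator is not applied and the
    input code is returned unchanged."""
    s = int(_SENSE[rng.integers(0, _SENSE.size)])
    k = _SENSE_NEIGHBOR_COUNTS[s]
    if k == 0:  # unreachable under canonical stops; guarded anyway
        return code
    t = int(_SENSE_NEIGHBORS[s, rng.integers(0, k)])
    labels = code.labels
    displaced = labels[t]
    if labels[s] == displaced:
        return code  # synonymous move: nothing changes
    if int(np.sum(labels == displaced)) == 1:
        return code
    new = labels.copy()
    new[t] = labels[s]
    return CodeAssignment(new)


def tournament_select(fitnesses: np.ndarray, window: int, rng: np.random.Generator) -> int:
    """Index of the minimum-fitness individual among `window` members drawn
    uniformly with replacement; ties go to the lowest population index."""
    fitnesses = np.asarray(fitnesses)
    if fitnesses.size == 0:
        raise ValueError("empty population")
    if not (1 <= window <= fitnesses.size):
        raise ValueError("window must be in 1..population size")
    draws = rng.integers(0, fitnesses.size, size=window)
    fv = fitnesses[draws]
    return int(draws[fv == fv.min()].min())


def _tournament_matrix(fitnesses: np.ndarray, n: int, window: int,
                       rng: np.random.Generator) -> np.ndarray:
    """n tournament winners at once (same rule as tournament_select)."""
    draws = rng.integers(0, fitnesses.size, size=(n, window))
    fv = fitnesses[draws]
    winners = np.where(fv == fv.min(axis=1, keepdims=True), draws, fitnesses.size)
    return winners.min(axis=1)


def _init_population(cfg: EvolutionConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.population_size
    if cfg.model == 1:
        return np.array([rng.permutation(N_AA) for _ in range(n)])
    # model 2: uniform surjective assignment of the 61 sense codons,
    # batched rejection sampling
    rows = []
    need = n
    while need > 0:
        batch = rng.integers(0, N_AA, size=(max(need * 3, 64), _SENSE.size))
        ok = (
            (batch[:, :, None] == np.arange(N_AA)[None, None, :]).any(axis=1).all(axis=1)
        )
        good = batch[ok][:need]
        rows.append(good)
        need -= good.shape[0]
    sense_labels = np.concatenate(rows, axis=0)
    pop = np.full((n, N_CODONS), STOP_INDEX, dtype=np.int64)
    pop[:, _SENSE] = sense_labels
    return pop


def _apply_swap(pop: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> None:
    """In-place swap of two distinct blocks for each selected row."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    i = rng.integers(0, N_AA, size=idx.size)
    j = rng.integers(0, N_AA - 1, size=idx.size)
    j = j + (j >= i)
    a = pop[idx, i].copy()
    pop[idx, i] = pop[idx, j]
    pop[idx, j] = a


def _apply_reassignment(pop: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> None:
    """In-place codon reassignment for each selected row, with the
    sole-instance guard."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    s = _SENSE[rng.integers(0, _SENSE.size, size=idx.size)]
    k = _SENSE_NEIGHBOR_COUNTS[s]
    t = _SENSE_NEIGHBORS[s, rng.integers(0, k)]
    donor = pop[idx, s]
    displaced = pop[idx, t]
    inst = (pop[idx] == displaced[:, None]).sum(axis=1)
    ok = (inst > 1) & (donor != displaced)
    rows = idx[ok]
    pop[rows, t[ok]] = donor[ok]


def _run_replicate(cfg: EvolutionConfig, evaluator: PopulationEvaluator,
                   ss: np.random.SeedSequence) -> ReplicateTrace:
    rng = np.random.default_rng(ss)
    pop = _init_population(cfg, rng)
    score = (
        evaluator.permutation_fitness if cfg.model == 1 else evaluator.labels_fitness
    )
    fit = score(pop)
    n = cfg.population_size
    window = cfg.tournament_window
    best_hist, mean_hist = [], []
    stagnant = 0
    for _ in range(cfg.generations):
        best_idx = int(np.flatnonzero(fit == fit.min()).min())
        prev_best = fit[best_idx]
        best_hist.append(float(prev_best))
        mean_hist.append(float(fit.mean()))
        # offspring: tournament winners, then variation; elite kept verbatim
        winners = _tournament_matrix(fit, n - 1, window, rng)
        children = pop[winners].copy()
        mask = (
            np.ones(n - 1, dtype=bool)
            if cfg.operator_probability >= 1.0
            else rng.random(n - 1) < cfg.operator_probability
        )
        if cfg.model == 1:
            _apply_swap(children, mask, rng)
        else:
            _apply_reassignment(children, mask, rng)
        pop = np.concatenate([pop[best_idx][None, :], children], axis=0)
        fit = score(pop)
        if fit.min() < prev_best:
            stagnant = 0
        else:
            stagnant += 1
            if cfg.plateau_generations and stagnant >= cfg.plateau_generations:
                break
    best_idx = int(np.flatnonzero(fit == fit.min()).min())
    best_hist.append(float(fit[best_idx]))
    mean_hist.append(float(fit.mean()))
    if cfg.model == 1:
        best_code = canonical_blocks().assemble(pop[best_idx])
    else:
        best_code = CodeAssignment(pop[best_idx])
    return ReplicateTrace(
        best=np.array(best_hist),
        mean=np.array(mean_hist),
        best_code=best_code,
        best_fitness=float(fit[best_idx]),
        spawn_key=tuple(int(k) for k in ss.spawn_key),
    )


def evolve(config: EvolutionConfig, progress: bool = False) -> EvolutionTrace:
    """Run `config.replicates` independent seeded GA runs and collect their
    traces.  Replicate r uses a child seed derived from the base seed, so
    runs are independent and individually reproducible."""
    evaluator = config.evaluator()
    base = np.random.SeedSequence(config.seed)
    children = base.spawn(config.replicates)
    trace = EvolutionTrace(config=config)
    for r, ss in enumerate(children):
        rep = _run_replicate(config, evaluator, ss)
        trace.replicates.append(rep)
        if progress:
            print(
                f"replicate {r + 1}/{config.replicates}: "
                f"best {rep.best_fitness:.4f} after {rep.best.size - 1} generations"
            )
    return trace
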