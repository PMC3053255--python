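import numpy as np
import pytest
from scipy import stats as sps

from codeopt import (
    CodeAssignment,
    EvolutionConfig,
    canonical_blocks,
    evolve,
    random_reassignment_code,
    reassignment_operator,
    swap_operator,
    tournament_select,
)
from codeopt.tables import SENSE_CODON_INDICES, STOP_INDEX


class TestSwapOperator:
    def test_self_swap_is_identity(self, canon):
        assert swap_operator(canon, 4, 4) == canon

    def test_involution(self, canon):
        assert swap_operator(swap_operator(canon, 2, 17), 2, 17) == canon

    def test_result_is_valid_model1_code(self, canon):
        blocks = canonical_blocks()
        out = swap_operator(canon, 0, 19)
        perm = blocks.permutation_of(out)  # raises if block structure broken
        assert sorted(perm) == list(range(20))
        assert out != canon

    def test_input_unmodified(self, canon):
        before = canon.labels.copy()
        swap_operator(canon, 1, 2)
        assert np.array_equal(canon.labels, before)

    def test_out_of_range_rejected(self, canon):
        with pytest.raises(ValueError):
            swap_operator(canon, 0, 20)


class TestReassignmentOperator:
    def test_success_changes_exactly_one_codon_to_neighbor_value(self):
        rng = np.random.default_rng(21)
        code = random_reassignment_code(rng)
        seen_change = False
        for _ in range(200):
            out = reassignment_operator(code, rng)
            diff = np.flatnonzero(out.labels != code.labels)
            assert diff.size in (0, 1)
            if diff.size == 1:
                seen_change = True
                t = int(diff[0])
                # new value must be carried by a single-base neighbor of t
                from codeopt import codon_neighbors
                from codeopt.tables import CODONS, CODON_INDEX

                nbr_vals = {
                    int(code.labels[CODON_INDEX[m]])
                    for m, _, _ in codon_neighbors(CODONS[t])
                }
                assert int(out.labels[t]) in nbr_vals
                # donor count +1, displaced count -1, still 61 sense codons
                assert out.counts().sum() == 61
            code = out
        assert seen_change

    def test_sole_instance_guard(self):
        # code where amino acids 1..19 each occupy exactly one codon: any
        # move displacing one of them must be refused
        labels = np.full(64, STOP_INDEX, dtype=np.int8)
        sense = list(SENSE_CODON_INDICES)
        labels[sense] = 0
        for aa, pos in enumerate(sense[:20]):
            labels[pos] = aa
        code = CodeAssignment(labels)
        rng = np.random.default_rng(22)
        for _ in range(500):
            out = reassignment_operator(code, rng)
            assert (out.counts() >= 1).all()
            diff = np.flatnonzero(out.labels != code.labels)
            if diff.size == 1:
                # only the abundant amino acid 0 may be displaced
                assert code.labels[diff[0]] == 0


class TestTournamentSelect:
    def test_window_one_is_uniform(self):
        rng = np.random.default_rng(23)
        fit = np.arange(20, dtype=float)
        draws = [tournament_select(fit, 1, rng) for _ in range(10_000)]
        counts = np.bincount(draws, minlength=20)
        assert sps.chisquare(counts).pvalue > 0.01

    def test_full_window_favors_global_best(self):
        rng = np.random.default_rng(24)
        fit = np.array([5.0, 1.0, 3.0, 4.0, 2.0])
        picks = np.array([tournament_select(fit, 5, rng) for _ in range(2000)])
        counts = np.bincount(picks, minlength=5)
        assert counts[1] == counts.max()
        # winner always beats a uniformly drawn individual on average
        assert fit[picks].mean() < fit.mean()

    def test_default_window_three_percent(self):
        cfg = EvolutionConfig(population_size=1000, tournament_fraction=0.03)
        assert cfg.tournament_window == 30

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            tournament_select(np.array([]), 1, np.random.default_rng(0))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"model": 3},
            {"fitness_kind": "rms"},
            {"population_size": 0},
            {"tournament_fraction": 0.0},
            {"tournament_fraction": 1.5},
            {"operator_probability": -0.1},
            {"replicates": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvolutionConfig(**kwargs)

    def test_model_default_generations(self):
        assert EvolutionConfig(model=1).generations == 100
        assert EvolutionConfig(model=2).generations == 300


@pytest.fixture(scope="module")
def small_runs():
    out = {}
    for model in (1, 2):
        cfg = EvolutionConfig(
            model=model, population_size=150, replicates=3, seed=99,
            generations=40, plateau_generations=10,
        )
        out[model] = evolve(cfg)
    return out


class TestEvolve:
    def test_determinism(self):
        cfg = dict(model=1, population_size=100, replicates=2, seed=7,
                   generations=15)
        a = evolve(EvolutionConfig(**cfg))
        b = evolve(EvolutionConfig(**cfg))
        for ra, rb in zip(a.replicates, b.replicates):
            assert np.array_equal(ra.best, rb.best)
            assert np.array_equal(ra.mean, rb.mean)
            assert ra.best_code == rb.best_code

    def test_elitism_monotonic_best(self, small_runs):
        for trace in small_runs.values():
            for rep in trace.replicates:
                assert (np.diff(rep.best) <= 1e-12).all()

    def test_final_codes_satisfy_model_invariants(self, small_runs):
        blocks = canonical_blocks()
        for rep in small_runs[1].replicates:
            perm = blocks.permutation_of(rep.best_code)
            assert sorted(perm) == list(range(20))
        for rep in small_runs[2].replicates:
            assert set(rep.best_code.stop_codons) == {"UAA", "UAG", "UGA"}
            assert (rep.best_code.counts() >= 1).all()

    def test_best_fitness_matches_curve_end(self, small_runs):
        for trace in small_runs.values():
            for rep in trace.replicates:
                assert rep.best_fitness == rep.best[-1]

    def test_model2_converges_at_least_as_low_as_model1(self):
        # the reassignment-code space contains the block-permutation space,
        # so at convergence model 2 should do at least as well (sign test
        # over paired seeded replicates)
        finals = {}
        for model in (1, 2):
            cfg = EvolutionConfig(
                model=model, population_size=300, replicates=20, seed=123,
                generations=200, plateau_generations=15,
            )
            finals[model] = evolve(cfg).best_finals
        wins = int(np.sum(finals[2] < finals[1]))
        assert sps.binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.05
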