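import numpy as np
import pytest

from codeopt import (
    EvolutionConfig,
    MistranslationWeights,
    PropertyScale,
    canonical_code,
    evolve,
    ms,
    sample_random_codes,
    tms,
)


@pytest.fixture(scope="session")
def canon():
    return canonical_code()


@pytest.fixture(scope="session")
def polar():
    return PropertyScale.polar_requirement()


@pytest.fixture(scope="session")
def table1_weights():
    return MistranslationWeights()


ARM_SEED = 20110221  # base seed of the headline experiment runs
N_RANDOM = 10_000
N_REPLICATES = 10


@pytest.fixture(scope="session")
def arm_results(canon):
    """The four experimental arms (model 1/2 x MS/tMS): GA traces, random
    code samples, and the canonical code's score, computed once for the
    whole session."""
    out = {}
    for model in (1, 2):
        for kind in ("ms", "tms"):
            cfg = EvolutionConfig(
                model=model,
                fitness_kind=kind,
                population_size=1000,
                replicates=N_REPLICATES,
                seed=ARM_SEED,
            )
            trace = evolve(cfg)
            rng = np.random.default_rng([ARM_SEED, model, 1 if kind == "tms" else 0])
            sample = sample_random_codes(model, kind, N_RANDOM, rng)
            d_code = ms(canon) if kind == "ms" else tms(canon)
            out[(model, kind)] = {
                "trace": trace,
                "sample": sample,
                "delta_code": d_code,
            }
    return out
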