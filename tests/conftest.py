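import numpy as np
import pytest
from hypothesis import settings

import gendose as g

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Unrelated 400 x 600 cohort with planted effects (h2 ~ 0.25)."""
    cfg = g.unrelated_config(
        n_individuals=400, n_snps=600, n_causal=30,
        target_heritability=0.25, random_seed=11,
    )
    return g.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def family_cohort():
    """600-individual cohort with 200 sib families and 200 singletons."""
    cfg = g.SimulationConfig(
        n_individuals=600, n_snps=3000, n_causal=40,
        n_families=200, n_singletons=200,
        family_size_distribution={1: 0.3, 2: 0.5, 3: 0.2},
        target_heritability=0.3, random_seed=13,
    )
    return g.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_family_cohort():
    """Cohort with families but zero genetic effect on lifespan."""
    cfg = g.SimulationConfig(
        n_individuals=800, n_snps=5000, n_causal=0,
        n_families=250, n_singletons=300,
        family_size_distribution={2: 1.0},
        target_heritability=0.0, random_seed=17,
    )
    return g.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
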