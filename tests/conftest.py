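import pytest

from longimet.simulate import (
    MetabolomeConfig,
    simulate_cohort,
    simulate_genotypes,
    simulate_metabolome,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(12, 6, seed=7)


@pytest.fixture(scope="session")
def small_geno():
    return simulate_genotypes(12, 30, seed=8)


@pytest.fixture(scope="session")
def small_metabolome(small_cohort, small_geno):
    cfg = MetabolomeConfig(n_metabolites=15, n_mqtl=1, missing_rate=0.05)
    return simulate_metabolome(small_cohort, small_geno, cfg, seed=9)
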