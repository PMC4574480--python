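import numpy as np
import pytest

from bagwas.simulate import (
    PhenotypeGroupSpec,
    SimulationConfig,
    simulate_genotypes,
    simulate_phenotype_table,
)


@pytest.fixture(scope="session")
def small_panel():
    """63 cases vs 400 controls, 300 null SNPs, planted risk pair, 2% missing."""
    cfg = SimulationConfig(
        seed=1, n_cases=63, n_controls=400, n_null_snps=300, missing_rate=0.02
    )
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def pheno_table():
    specs = [
        PhenotypeGroupSpec(name="control", n_larvae=20, class_probs=(0.6, 0.25, 0.1, 0.05),
                           length_mean_um=10.0, edu_prob=0.1),
        PhenotypeGroupSpec(name="morphant", n_larvae=20, class_probs=(0.25, 0.2, 0.15, 0.4),
                           length_mean_um=6.0, edu_prob=0.1,
                           severity_probs=(0.1, 0.3, 0.6), ped6_probs=(0.6, 0.3, 0.1)),
    ]
    return simulate_phenotype_table(specs, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
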