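import numpy as np
import pytest

from omicsmeta.simulate import PlantedGene, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with planted effects, shared across tests."""
    cfg = SimConfig(
        seed=11,
        n_samples=400,
        n_genes=80,
        n_modules=40,
        planted=[
            PlantedGene("G0005", gwas_h2=0.06, twas_beta=0.3, rva_h2=0.04),
            PlantedGene("G0012", twas_beta=0.35),
            PlantedGene("G0020", gwas_h2=0.07, rva_h2=0.05, rva_category="missense"),
        ],
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A no-effect cohort for calibration checks."""
    cfg = SimConfig(seed=5, n_samples=300, n_genes=60, n_modules=30)
    return simulate_cohort(cfg)
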