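import numpy as np
import pytest

from regsnp import PlantedEffect, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one planted CNV SNP and one planted methylation SNP."""
    cfg = SimulationConfig(
        n_patients=32,
        n_genes=50,
        n_snps=100,
        planted_cnv_effects=[PlantedEffect("snp00001", "gene0001", 0.8, "qualitative")],
        planted_meth_effects=[PlantedEffect("snp00002", "gene0002", 0.6, "qualitative")],
        seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects: every layer is pure noise."""
    cfg = SimulationConfig(n_patients=32, n_genes=100, n_snps=300, seed=13)
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20150324)
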