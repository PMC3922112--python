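import numpy as np
import pandas as pd
import pytest

from gxeherit import (
    SimConfig,
    assign_environments,
    compute_grm,
    simulate_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300 x 400 cohort with a moderate interaction component, shared
    across tests that only need plausible data."""
    cfg = SimConfig(n_individuals=300, n_snps=400, h2_g=0.2, h2_ge=0.3, seed=11)
    G = simulate_genotypes(cfg)
    env = assign_environments(cfg, "area")
    table, truth = simulate_phenotype(G, env, cfg)
    return cfg, G, env, table, truth


@pytest.fixture(scope="session")
def small_grm(small_cohort):
    _, G, _, _, _ = small_cohort
    return compute_grm(G)


@pytest.fixture()
def toy_genotypes():
    """Hand-sized genotype matrix with known dosages."""
    from gxeherit import GenotypeMatrix

    dos = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, np.nan, 1.0],
            [0.0, 2.0, 1.0],
        ]
    )
    snps = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "snp_id": ["rs1", "rs2", "rs3"],
            "cm": 0.0,
            "pos": [100, 200, 300],
            "a1": ["A", "C", "G"],
            "a2": ["B", "T", "T"],
        }
    )
    return GenotypeMatrix(dos, ["s1", "s2", "s3", "s4"], snps)
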