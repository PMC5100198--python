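import numpy as np
import pytest

from sparsesem import SimConfig, random_network, simulate_genotypes, simulate_phenotypes


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_system():
    """A 3-phenotype, 6-SNP common-variant system with known parameters."""
    cfg = SimConfig(M=3, n_snps=6, n=800, maf_regime="common", seed=42, expected_degree=1.5)
    rng = np.random.default_rng(42)
    Gamma, B, gamma_edges, b_edges = random_network(cfg, rng)
    X, _ = simulate_genotypes(cfg, rng)
    Y = simulate_phenotypes(Gamma, B, X, cfg.noise_sd, rng)
    return {"config": cfg, "Gamma": Gamma, "B": B, "gamma_edges": gamma_edges,
            "b_edges": b_edges, "X": X, "Y": Y}


@pytest.fixture
def gene_system():
    """A 4-phenotype, 3-gene (5 SNPs each) common-variant system."""
    cfg = SimConfig(M=4, n_genes=6, snps_per_gene=4, n=600,
                    maf_regime="common", seed=7)
    rng = np.random.default_rng(7)
    Gamma, B, gamma_edges, b_edges = random_network(cfg, rng)
    X, genes = simulate_genotypes(cfg, rng)
    Y = simulate_phenotypes(Gamma, B, X, cfg.noise_sd, rng)
    return {"config": cfg, "Gamma": Gamma, "B": B, "gamma_edges": gamma_edges,
            "b_edges": b_edges, "X": X, "Y": Y, "genes": genes}
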