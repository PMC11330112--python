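import numpy as np
import pytest

from deeprisk.feature_encoding import build_connectivity
from deeprisk.simulator import (
    ArchitectureSpec,
    SimConfig,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_snps=30, n_genes=8, n_chromosomes=2, ld_block_size=5,
        within_block_rho=0.4, maf_range=(0.1, 0.5), missing_rate=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotypes(small_cfg, 300, seed=21)


@pytest.fixture(scope="session")
def small_genes(small_cfg):
    return simulate_gene_annotation(small_cfg)


@pytest.fixture(scope="session")
def labelled_cohort(small_cfg):
    """Cohort with one strongly additive causal SNP."""
    geno = simulate_genotypes(small_cfg, 600, seed=31)
    arch = ArchitectureSpec(
        n_causal_additive=1, additive_indices=[3], additive_betas=[2.0],
        heritability_like_scale=0.7, prevalence=0.3,
    )
    simulate_phenotype(geno, arch, seed=32)
    return geno


@pytest.fixture(scope="session")
def small_connectivity(small_panel, small_genes):
    return build_connectivity(small_panel.variant_ids, small_panel.variants, small_genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
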