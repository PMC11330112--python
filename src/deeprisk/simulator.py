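"""Synthetic cohorts with LD structure and planted additive + epistatic effects.

Real biobank genotypes and the published discovery GWAS are access-restricted,
so the pipeline is exercised on simulated data.  Genotypes are drawn from a
latent-Gaussian model: within an LD block each haplotype's latent values share
an exchangeable correlation, and each SNP's latent value is thresholded at its
minor-allele frequency, giving Hardy-Weinberg genotypes with tunable
within-block correlation.  This is a controllable stand-in, not a coalescent
model — see the methods note for what it does and does not emulate.

The phenotype follows a liability-threshold model: liability is the sum of
additive allele-count effects, pairwise joint-carrier epistatic effects
(a contribution when *both* loci of a pair carry at least one alternative
allele — the simplest interaction invisible to additive models), optional
covariate effects and Gaussian noise; cases are the samples whose liability
exceeds the (1 - prevalence) quantile of the realized liability distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import (
    MISSING,
    GeneAnnotationTable,
    GenotypeDataset,
    SummaryStatsTable,
    Variant,
)

_ALLELES = ("A", "C")  # unambiguous pair, safe under strand filters


@dataclass
class SimConfig:
    """Layout and population parameters for a simulated panel/cohort.

    SNPs are split evenly across ``n_chromosomes`` autosomes (or per an
    explicit ``chrom_assignment``), spaced ``snp_spacing_bp`` apart, and
    grouped into LD blocks of ``ld_block_size`` adjacent SNPs with latent
    exchangeable correlation ``within_block_rho``.
    """

    n_snps: int = 200
    n_genes: int = 40
    n_samples_panel: int = 500
    n_samples_discovery: int = 2000
    n_samples_cohort: int = 2000
    n_chromosomes: int = 4
    chrom_assignment: dict[int, int] | None = None  # snp index -> chrom
    ld_block_size: int = 10
    within_block_rho: float = 0.4
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    snp_spacing_bp: int = 50_000
    gene_length_bp: int = 30_000
    gene_spacing_bp: int = 220_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ld_block_size < 1 or self.n_snps < 1:
            raise ValueError("n_snps and ld_block_size must be positive")
        if self.n_chromosomes < 1 or self.n_chromosomes > 22:
            raise ValueError("n_chromosomes must be in 1..22")

    # -- deterministic layout --------------------------------------------------

    def chrom_of(self, j: int) -> int:
        if self.chrom_assignment is not None:
            return self.chrom_assignment[j]
        per = -(-self.n_snps // self.n_chromosomes)  # ceil
        return min(j // per + 1, self.n_chromosomes)

    def pos_of(self, j: int) -> int:
        within = self._index_within_chrom(j)
        return 100_000 + within * self.snp_spacing_bp

    def _index_within_chrom(self, j: int) -> int:
        c = self.chrom_of(j)
        return sum(1 for k in range(j) if self.chrom_of(k) == c)

    def variant_list(self) -> list[Variant]:
        return [
            Variant(f"rs{j}", self.chrom_of(j), self.pos_of(j), *_ALLELES)
            for j in range(self.n_snps)
        ]

    def mafs(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.maf_range
        return rng.uniform(lo, hi, size=self.n_snps)


@dataclass
class ArchitectureSpec:
    """Planted genetic architecture on the liability scale.

    ``epistatic_pairs[k]`` contributes ``epistasis_weights[k]`` to liability
    when both member SNPs carry >= 1 alternative allele.
    ``heritability_like_scale`` is the fraction of liability variance explained
    by the genetic (+ covariate) component: noise variance is set from the
    realized genetic variance so that fraction holds in-sample.
    """

    n_causal_additive: int = 0
    additive_indices: list[int] = field(default_factory=list)
    additive_betas: list[float] = field(default_factory=list)
    n_epistatic_pairs: int = 0
    epistatic_pairs: list[tuple[int, int]] = field(default_factory=list)
    epistasis_weights: list[float] = field(default_factory=list)
    heritability_like_scale: float = 0.5
    prevalence: float = 0.2
    covariate_effects: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.additive_indices) != self.n_causal_additive:
            raise ValueError("additive_indices length must equal n_causal_additive")
        if len(self.additive_betas) != self.n_causal_additive:
            raise ValueError("additive_betas length must equal n_causal_additive")
        if len(self.epistatic_pairs) != self.n_epistatic_pairs:
            raise ValueError("epistatic_pairs length must equal n_epistatic_pairs")
        if len(self.epistasis_weights) != self.n_epistatic_pairs:
            raise ValueError("epistasis_weights length must equal n_epistatic_pairs")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.heritability_like_scale <= 1:
            raise ValueError("heritability_like_scale must be in [0, 1]")


def simulate_genotypes(cfg: SimConfig, n: int, seed: int | None = None) -> GenotypeDataset:
    """Draw ``n`` diploid samples from the latent-Gaussian LD-block model.

    Each haplotype's latent vector within a block is ``sqrt(rho)*shared +
    sqrt(1-rho)*private``; an allele is alternative when the latent value falls
    below the normal quantile of the SNP's MAF, so marginal genotype
    frequencies are Hardy-Weinberg at that MAF.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mafs = cfg.mafs(rng)
    thresholds = sps.norm.ppf(mafs)
    geno = np.empty((n, cfg.n_snps), dtype=np.int16)

    blocks = _ld_blocks(cfg)
    for block in blocks:
        m = len(block)
        rho = cfg.within_block_rho
        for hap_alleles in (0, 1):  # two independent haplotypes per sample
            shared = rng.standard_normal((n, 1))
            private = rng.standard_normal((n, m))
            latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * private
            alt = latent < thresholds[block]
            if hap_alleles == 0:
                geno[:, block] = alt.astype(np.int16)
            else:
                geno[:, block] += alt.astype(np.int16)

    if cfg.missing_rate > 0:
        mask = rng.random((n, cfg.n_snps)) < cfg.missing_rate
        geno[mask] = MISSING

    sample_ids = [f"S{seed if seed is not None else cfg.seed}_{i}" for i in range(n)]
    return GenotypeDataset(variants=cfg.variant_list(), sample_ids=sample_ids, alt_counts=geno)


def apply_missingness(geno: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Mask genotype entries MISSING at the given rate, in place.

    Used to decouple the biology from the assay: phenotypes are generated from
    complete genotypes and measurement dropout is layered on afterwards, so
    liability never depends on which entries failed genotyping.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0,1)")
    if rate > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(geno.alt_counts.shape) < rate
        geno.alt_counts[mask] = MISSING
    return geno


def _ld_blocks(cfg: SimConfig) -> list[np.ndarray]:
    """Contiguous same-chromosome index blocks of at most ld_block_size SNPs."""
    blocks: list[np.ndarray] = []
    current: list[int] = []
    for j in range(cfg.n_snps):
        if current and (
            len(current) == cfg.ld_block_size or cfg.chrom_of(j) != cfg.chrom_of(current[-1])
        ):
            blocks.append(np.array(current))
            current = []
        current.append(j)
    if current:
        blocks.append(np.array(current))
    return blocks


def carrier_matrix(geno: GenotypeDataset) -> np.ndarray:
    """Boolean n x m matrix: carries >= 1 alt allele (MISSING counts as non-carrier)."""
    return geno.alt_counts >= 1


def simulate_phenotype(
    geno: GenotypeDataset, arch: ArchitectureSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Liability-threshold case/control phenotype; returns (binary, liability).

    Missing genotypes contribute nothing to liability.  The case threshold is
    the (1 - prevalence) quantile of the *realized* liability values, so the
    case fraction is controlled even at small n.
    """
    rng = np.random.default_rng(seed)
    n, m = geno.alt_counts.shape
    for i, j in arch.epistatic_pairs:
        if not (0 <= i < m and 0 <= j < m):
            raise ValueError(f"epistatic pair ({i},{j}) references a variant outside 0..{m - 1}")
    for i in arch.additive_indices:
        if not 0 <= i < m:
            raise ValueError(f"additive causal index {i} outside 0..{m - 1}")

    counts = np.where(geno.alt_counts == MISSING, 0, geno.alt_counts).astype(float)
    genetic = np.zeros(n)
    if arch.n_causal_additive:
        idx = np.array(arch.additive_indices)
        betas = np.array(arch.additive_betas, dtype=float)
        genetic += counts[:, idx] @ betas
    if arch.n_epistatic_pairs:
        carrier = geno.alt_counts >= 1
        for (i, j), w in zip(arch.epistatic_pairs, arch.epistasis_weights):
            genetic += w * (carrier[:, i] & carrier[:, j])
    if arch.covariate_effects is not None:
        if geno.covariates is None:
            k = len(arch.covariate_effects)
            geno.covariates = rng.standard_normal((n, k))
            geno.covariate_names = [f"cov{i}" for i in range(k)]
        genetic = genetic + geno.covariates @ np.asarray(arch.covariate_effects, dtype=float)

    s = arch.heritability_like_scale
    g_var = float(np.var(genetic))
    if s >= 1 or g_var == 0:
        noise_sd = 0.0 if s >= 1 and g_var > 0 else 1.0
    else:
        noise_sd = np.sqrt(g_var * (1 - s) / s) if s > 0 else max(np.sqrt(g_var), 1.0) * 1e3
    liability = genetic + noise_sd * rng.standard_normal(n)
    threshold = np.quantile(liability, 1 - arch.prevalence)
    y = (liability > threshold).astype(np.int8)
    geno.phenotype = y
    return y, liability


def run_discovery_gwas(geno: GenotypeDataset) -> SummaryStatsTable:
    """Marginal single-variant allelic association scan.

    For each SNP the 2x2 allele-count table (alt/ref x case/control) over
    complete cases yields beta = log odds ratio (Haldane 0.5 correction when a
    cell is empty) and a 1-df Pearson chi-square p-value.  Monomorphic or
    all-missing SNPs are reported as (beta=0, p=1).
    """
    if geno.phenotype is None:
        raise ValueError("discovery GWAS needs a phenotype")
    y = geno.phenotype.astype(bool)
    counts = geno.alt_counts
    rows = []
    for j, v in enumerate(geno.variants):
        col = counts[:, j]
        obs = col != MISSING
        beta, p = _allelic_test(col[obs & y], col[obs & ~y])
        rows.append(
            {
                "id": v.id, "chrom": v.chrom, "pos": v.pos,
                "ref_allele": v.ref_allele, "alt_allele": v.alt_allele,
                "beta": beta, "p_value": p,
            }
        )
    df = pd.DataFrame(rows).set_index("id")
    return SummaryStatsTable(df)


def _allelic_test(case_counts: np.ndarray, control_counts: np.ndarray) -> tuple[float, float]:
    n_case, n_ctrl = len(case_counts), len(control_counts)
    if n_case == 0 or n_ctrl == 0:
        return 0.0, 1.0
    a1 = float(case_counts.sum())          # alt alleles in cases
    a0 = 2.0 * n_case - a1
    b1 = float(control_counts.sum())       # alt alleles in controls
    b0 = 2.0 * n_ctrl - b1
    if (a1 + b1) == 0 or (a0 + b0) == 0:
        return 0.0, 1.0  # monomorphic
    table = np.array([[a1, a0], [b1, b0]])
    if 0.0 in table:
        beta = float(np.log(((a1 + 0.5) * (b0 + 0.5)) / ((a0 + 0.5) * (b1 + 0.5))))
    else:
        beta = float(np.log((a1 * b0) / (a0 * b1)))
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return beta, float(max(p, np.nextafter(0, 1)))


def simulate_gene_annotation(cfg: SimConfig) -> GeneAnnotationTable:
    """Deterministic non-overlapping gene intervals per chromosome.

    Genes tile the front of each chromosome's SNP span; with the default
    layout the last SNPs on a chromosome lie beyond 250 kb of every gene, so
    the nearest-gene fallback path is always exercised.
    """
    per_chrom: dict[int, int] = {}
    for j in range(cfg.n_snps):
        per_chrom[cfg.chrom_of(j)] = per_chrom.get(cfg.chrom_of(j), 0) + 1
    chroms = sorted(per_chrom)
    base = cfg.n_genes // len(chroms)
    extra = cfg.n_genes % len(chroms)
    rows = []
    for k, c in enumerate(chroms):
        n_genes_c = base + (1 if k < extra else 0)
        for g in range(n_genes_c):
            start = 150_000 + g * cfg.gene_spacing_bp
            rows.append(
                {
                    "gene_id": f"GENE{c}_{g}", "chrom": c,
                    "start": start, "end": start + cfg.gene_length_bp,
                }
            )
    return GeneAnnotationTable(pd.DataFrame(rows))
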