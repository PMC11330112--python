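"""Planted-architecture benchmark cohorts used by the test-bench and examples.

Three named benchmarks define the synthetic study conditions under which the
pipeline's claims are exercised:

* ``epistatic_benchmark`` — 200 SNPs, five joint-carrier epistatic pairs with
  no planted additive effects, cohort n=4000 at prevalence 0.2.  Each pair
  lies on one chromosome in two different LD blocks (and hence different
  genes), the interaction pattern the per-chromosome BiLSTM can represent but
  a linear score cannot.
* ``additive_benchmark`` — same genome layout with 20 purely additive causal
  SNPs, the regime where linear baselines are near-optimal.
* ``robustness_benchmark`` — 100 SNPs, all causal with linearly decaying
  effects, so removing the top GWAS hits strips signal in a graded, monotone
  way while weaker loci remain selectable at every removal level.

All sampling is deterministic in the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_io import GenotypeDataset, SummaryStatsTable, GeneAnnotationTable
from .pipeline import PipelineConfig, fit_score_pipeline
from .risk_analysis import auc
from .risk_model import ModelConfig
from .simulator import (
    ArchitectureSpec,
    SimConfig,
    apply_missingness,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotype,
    run_discovery_gwas,
)
from .snp_selection import SelectionParams, stratified_split


@dataclass
class Benchmark:
    cfg: SimConfig
    arch: ArchitectureSpec
    cohort: GenotypeDataset
    panel: GenotypeDataset
    stats: SummaryStatsTable
    genes: GeneAnnotationTable


#: Epistatic pairs as (chromosome-local offsets); each pair spans two LD blocks.
_EPI_LAYOUT = [(0, 5, 25), (1, 5, 25), (2, 5, 25), (3, 5, 25), (0, 15, 45)]

#: Training configuration used on the benchmark cohorts (documented in the
#: methods note): a slightly higher learning rate than the library default
#: speeds convergence of the small network within the epoch budget.
BENCH_MODEL_CFG = ModelConfig(learning_rate=3e-3, max_epochs=40, early_stop_patience=6)

#: Lenient selection used on the benchmarks: the epistatic signal is marginal
#: only through carrier-frequency leakage, so a permissive p threshold keeps
#: the interacting loci in play for every method alike.
BENCH_SELECTION = SelectionParams(5e-3, None)

#: Selection used in the SNP-removal experiment: after the strongest GWAS hits
#: are deleted the surviving signal is weak, so the experiment keeps a
#: permissive threshold to have SNPs left to score at every removal level.
ROBUST_SELECTION = SelectionParams(0.05, None)


def _build(cfg: SimConfig, arch: ArchitectureSpec, seed: int) -> Benchmark:
    """Panel + discovery GWAS + labelled cohort under one architecture.

    Phenotypes are generated from complete genotypes; assay missingness is
    masked in afterwards, so liability never depends on genotyping failures.
    """
    from dataclasses import replace

    complete = replace(cfg, missing_rate=0.0)
    panel = simulate_genotypes(cfg, cfg.n_samples_panel, seed=seed * 11 + 1)
    discovery = simulate_genotypes(complete, cfg.n_samples_discovery, seed=seed * 11 + 2)
    simulate_phenotype(discovery, arch, seed=seed * 11 + 3)
    apply_missingness(discovery, cfg.missing_rate, seed=seed * 11 + 4)
    stats = run_discovery_gwas(discovery)
    cohort = simulate_genotypes(complete, cfg.n_samples_cohort, seed=seed * 11 + 5)
    simulate_phenotype(cohort, arch, seed=seed * 11 + 6)
    apply_missingness(cohort, cfg.missing_rate, seed=seed * 11 + 7)
    genes = simulate_gene_annotation(cfg)
    return Benchmark(cfg=cfg, arch=arch, cohort=cohort, panel=panel, stats=stats, genes=genes)


def epistatic_benchmark(seed: int = 0, n_cohort: int = 4000) -> Benchmark:
    """Pure joint-carrier epistasis: five pairs, zero planted additive effects."""
    cfg = SimConfig(
        n_snps=200, n_genes=40, n_chromosomes=4,
        n_samples_panel=500, n_samples_discovery=2000, n_samples_cohort=n_cohort,
        ld_block_size=10, within_block_rho=0.3, maf_range=(0.2, 0.5),
        missing_rate=0.02, seed=seed,
    )
    per = 50  # SNPs per chromosome
    pairs = [(c * per + a, c * per + b) for c, a, b in _EPI_LAYOUT]
    arch = ArchitectureSpec(
        n_epistatic_pairs=5,
        epistatic_pairs=pairs,
        epistasis_weights=[2.0] * 5,
        heritability_like_scale=0.8,
        prevalence=0.2,
    )
    return _build(cfg, arch, seed)


def additive_benchmark(seed: int = 0, n_cohort: int = 4000) -> Benchmark:
    """Purely additive architecture: 20 causal SNPs, one per LD block."""
    cfg = SimConfig(
        n_snps=200, n_genes=40, n_chromosomes=4,
        n_samples_panel=500, n_samples_discovery=2000, n_samples_cohort=n_cohort,
        ld_block_size=10, within_block_rho=0.3, maf_range=(0.2, 0.5),
        missing_rate=0.02, seed=seed,
    )
    causal = list(range(0, 200, 10))  # first SNP of every block
    arch = ArchitectureSpec(
        n_causal_additive=20,
        additive_indices=causal,
        additive_betas=[0.35] * 20,
        heritability_like_scale=0.5,
        prevalence=0.2,
    )
    return _build(cfg, arch, seed)


def robustness_benchmark(seed: int = 0, n_cohort: int = 2000) -> Benchmark:
    """Graded additive signal: betas decay linearly across all 100 SNPs."""
    cfg = SimConfig(
        n_snps=100, n_genes=20, n_chromosomes=4,
        n_samples_panel=500, n_samples_discovery=3000, n_samples_cohort=n_cohort,
        ld_block_size=10, within_block_rho=0.2, maf_range=(0.2, 0.5),
        missing_rate=0.02, seed=seed,
    )
    betas = [0.4 * (1.0 - i / 100.0) for i in range(100)]
    arch = ArchitectureSpec(
        n_causal_additive=100,
        additive_indices=list(range(100)),
        additive_betas=betas,
        heritability_like_scale=0.6,
        prevalence=0.2,
    )
    return _build(cfg, arch, seed)


def evaluate_methods(
    bench: Benchmark,
    methods: tuple[str, ...] = ("deeprisk", "pt", "lasso"),
    variants: tuple[str, ...] = ("full",),
    seed: int = 0,
    test_fraction: float = 0.3,
    model_cfg: ModelConfig | None = None,
    selection: SelectionParams | None = None,
) -> dict[str, float]:
    """Train every requested method on a fixed stratified split; return test AUCs.

    The deep model is evaluated once per requested variant (keys
    ``deeprisk``, ``deeprisk:no_partial_layer``, ...).
    """
    from dataclasses import replace

    mcfg = model_cfg or BENCH_MODEL_CFG
    sel = selection or BENCH_SELECTION
    tr_idx, te_idx = stratified_split(bench.cohort.phenotype, test_fraction, seed)
    tr = bench.cohort.subset_samples(tr_idx)
    te = bench.cohort.subset_samples(te_idx)
    out: dict[str, float] = {}
    for method in methods:
        if method == "deeprisk":
            for variant in variants:
                cfg = PipelineConfig(
                    method="deeprisk", selection=sel, genes=bench.genes,
                    model_cfg=replace(mcfg, variant=variant),
                )
                scores = fit_score_pipeline(tr, te, bench.stats, bench.panel, cfg, seed=seed)
                key = "deeprisk" if variant == "full" else f"deeprisk:{variant}"
                out[key] = auc(scores, te.phenotype)
        else:
            cfg = PipelineConfig(method=method, selection=sel, genes=bench.genes)
            scores = fit_score_pipeline(tr, te, bench.stats, bench.panel, cfg, seed=seed)
            out[method] = auc(scores, te.phenotype)
    return out
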