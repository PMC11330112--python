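"""Score-based risk stratification and evaluation.

Implements the odds-ratio analysis of top-score groups, the largest population
fraction at k-fold increased risk, 100-bin percentile prevalence curves,
rank-based AUC, stratified cross-validation of whole pipelines, the risk-SNP
subgroup analysis, and the top-SNP removal robustness experiment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .data_io import GenotypeDataset, SummaryStatsTable

logger = logging.getLogger(__name__)

RISK_SNP_P = 5e-8


@dataclass
class ContingencySummary:
    """Top-group vs remainder 2x2 counts: T=TD+TE (top), R=RD+RE (rest)."""

    T: int
    TD: int
    TE: int
    R: int
    RD: int
    RE: int

    def __post_init__(self) -> None:
        assert self.TD + self.TE == self.T and self.RD + self.RE == self.R


@dataclass
class StratificationReport:
    or_by_cutoff: dict[float, float]
    proportion_at_fold: dict[float, float]
    prevalence_bins: np.ndarray
    median_case_percentile: float
    median_control_percentile: float
    auc: float
    or_flags: dict[float, bool] = field(default_factory=dict)  # cutoff -> infinite OR


def _check_scores_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite scores")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def _descending_order(scores: np.ndarray) -> np.ndarray:
    """Stable descending sort: ties keep original sample order."""
    return np.argsort(-scores, kind="stable")


def odds_ratio(
    scores: np.ndarray, labels: np.ndarray, top_fraction: float
) -> tuple[float, ContingencySummary]:
    """OR of the top score group versus the remainder: (TD*RE)/(TE*RD).

    The top group holds the ceil(top_fraction * n) highest-scoring samples
    (score ties broken by stable sample order).  A zero TE or RD cell gives
    OR = +inf — no continuity correction is applied silently.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0,1)")
    n = len(scores)
    k = math.ceil(top_fraction * n)
    order = _descending_order(scores)
    n_ties = n - len(np.unique(scores))
    if n_ties:
        logger.debug("odds_ratio: %d tied scores broken by sample order", n_ties)
    top = np.zeros(n, dtype=bool)
    top[order[:k]] = True
    TD = int(labels[top].sum())
    TE = k - TD
    RD = int(labels[~top].sum())
    RE = (n - k) - RD
    summary = ContingencySummary(T=k, TD=TD, TE=TE, R=n - k, RD=RD, RE=RE)
    if TE == 0 or RD == 0:
        return float("inf"), summary
    return (TD * RE) / (TE * RD), summary


def proportion_at_fold_risk(scores: np.ndarray, labels: np.ndarray, fold: float) -> float:
    """Largest population fraction whose top-score group has OR >= fold.

    Sweeps every top-k cutoff (k = 1 .. n-1) and returns the largest k/n whose
    odds ratio against the remainder reaches ``fold``; 0.0 if none does.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if fold < 1:
        raise ValueError("fold must be >= 1")
    n = len(scores)
    order = _descending_order(scores)
    y_sorted = labels[order]
    td = np.cumsum(y_sorted)[:-1].astype(float)          # k = 1..n-1
    ks = np.arange(1, n, dtype=float)
    te = ks - td
    total_d = labels.sum()
    rd = total_d - td
    re = (n - ks) - rd
    with np.errstate(divide="ignore", invalid="ignore"):
        ors = np.where((te == 0) | (rd == 0), np.inf, (td * re) / (te * rd))
    hits = np.flatnonzero(ors >= fold)
    if hits.size == 0:
        return 0.0
    return float(ks[hits[-1]] / n)


def percentile_prevalence(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 100
) -> tuple[np.ndarray, float, float]:
    """Disease prevalence per score-percentile bin, plus median case/control percentile.

    Percentiles are average-rank based (ties share a percentile); bin b covers
    percentiles (b, b+1].  Returns (prevalence vector, median case percentile,
    median control percentile).
    """
    scores, labels = _check_scores_labels(scores, labels)
    n = len(scores)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} samples for {n_bins} bins; use fewer bins")
    pct = rankdata(scores, method="average") / n * 100.0
    bins = np.clip(np.ceil(pct).astype(int) - 1, 0, n_bins - 1)
    prevalence = np.zeros(n_bins)
    for b in range(n_bins):
        members = bins == b
        tot = int(members.sum())
        prevalence[b] = labels[members].sum() / tot if tot else 0.0
    med_case = float(np.median(pct[labels == 1]))
    med_ctrl = float(np.median(pct[labels == 0]))
    return prevalence, med_case, med_ctrl


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction: P(case score > control score) + P(tie)/2."""
    scores, labels = _check_scores_labels(scores, labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def stratify(
    scores: np.ndarray,
    labels: np.ndarray,
    or_cutoffs: tuple[float, ...] = (0.01, 0.05, 0.2),
    folds: tuple[float, ...] = (3.0, 4.0, 5.0),
    n_bins: int = 100,
) -> StratificationReport:
    """Full stratification report: ORs, fold-risk proportions, percentile curve, AUC."""
    ors: dict[float, float] = {}
    flags: dict[float, bool] = {}
    for c in or_cutoffs:
        orv, _ = odds_ratio(scores, labels, c)
        ors[c] = orv
        flags[c] = math.isinf(orv)
    props = {f: proportion_at_fold_risk(scores, labels, f) for f in folds}
    prev, med_case, med_ctrl = percentile_prevalence(scores, labels, n_bins)
    return StratificationReport(
        or_by_cutoff=ors,
        proportion_at_fold=props,
        prevalence_bins=prev,
        median_case_percentile=med_case,
        median_control_percentile=med_ctrl,
        auc=auc(scores, labels),
        or_flags=flags,
    )


def stratified_fold_indices(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified k-fold partition of sample indices."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, sample in enumerate(idx):
            folds[i % k].append(int(sample))
    return [np.sort(np.array(f)) for f in folds]


def cross_validate(
    geno: GenotypeDataset,
    stats: SummaryStatsTable,
    panel: GenotypeDataset,
    pipeline_cfg,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Stratified k-fold cross-validation of a scoring pipeline.

    SNP selection (including any grid search) and model training run inside
    each training fold; the held-out fold is only ever scored.  Returns
    (per-fold AUCs, mean AUC).
    """
    from .pipeline import fit_score_pipeline  # local import; pipeline depends on this module

    if geno.phenotype is None:
        raise ValueError("cross-validation needs a labelled cohort")
    y = geno.phenotype
    n_case = int(y.sum())
    n_ctrl = len(y) - n_case
    if n_case < k or n_ctrl < k:
        raise ValueError(f"need at least {k} cases and {k} controls for {k}-fold CV")
    folds = stratified_fold_indices(y, k, seed)
    all_idx = np.arange(len(y))
    aucs = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        tr = geno.subset_samples(train_idx)
        te = geno.subset_samples(test_idx)
        test_scores = fit_score_pipeline(tr, te, stats, panel, pipeline_cfg, seed=seed + fi)
        aucs.append(auc(test_scores, te.phenotype))
    return aucs, float(np.mean(aucs))


def risk_snp_counts(geno: GenotypeDataset, stats: SummaryStatsTable) -> np.ndarray:
    """Per-individual count of risk SNPs carried.

    A risk SNP has GWAS p < 5e-8 and beta > 0; an individual carries it when
    holding at least one alternative allele there (missing = not carried).
    """
    tab = stats.table
    risk_ids = tab.index[(tab["p_value"] < RISK_SNP_P) & (tab["beta"] > 0)]
    index = geno.variant_index()
    cols = [index[i] for i in risk_ids if i in index]
    if not cols:
        return np.zeros(geno.n_samples, dtype=int)
    return (geno.alt_counts[:, cols] >= 1).sum(axis=1).astype(int)


def risk_snp_subgroup_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    geno: GenotypeDataset,
    stats: SummaryStatsTable,
    cutoffs: list[int],
) -> tuple[dict[int, float], int]:
    """AUC within subgroups of individuals carrying few risk SNPs.

    For each cutoff, the subgroup holds individuals whose risk-SNP count is
    <= cutoff; a one-class subgroup reports NaN.  Also returns the count
    threshold corresponding to the lowest 1% of individuals.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    counts = risk_snp_counts(geno, stats)
    one_pct_threshold = int(np.quantile(counts, 0.01, method="lower"))
    out: dict[int, float] = {}
    for cutoff in cutoffs:
        members = counts <= cutoff
        sub_y = labels[members]
        if members.sum() == 0 or sub_y.min() == sub_y.max():
            out[cutoff] = float("nan")
            logger.info("subgroup cutoff %d: single class, AUC undefined", cutoff)
            continue
        out[cutoff] = auc(scores[members], sub_y)
    return out, one_pct_threshold


def snp_removal_robustness(
    geno: GenotypeDataset,
    stats: SummaryStatsTable,
    panel: GenotypeDataset,
    pipeline_cfg,
    removals: tuple[int, ...] = (10, 20, 50),
    seed: int = 0,
    test_fraction: float = 0.3,
) -> dict[int, float]:
    """Rerun selection + training + scoring after dropping the top-k GWAS SNPs.

    For each removal level k (0 is always included) the k smallest-p variants
    are removed from the summary statistics before selection; the pipeline is
    refit on a fixed stratified train split and the AUC measured on the fixed
    test split.  Seeds are held fixed across levels.
    """
    from .data_io import SummaryStatsTable as SST
    from .pipeline import fit_score_pipeline
    from .snp_selection import stratified_split

    if geno.phenotype is None:
        raise ValueError("robustness experiment needs a labelled cohort")
    levels = sorted(set((0,) + tuple(removals)))
    if levels[-1] > len(stats.table):
        raise ValueError(f"cannot remove {levels[-1]} of {len(stats.table)} SNPs")
    tr_idx, te_idx = stratified_split(geno.phenotype, test_fraction, seed)
    tr = geno.subset_samples(tr_idx)
    te = geno.subset_samples(te_idx)
    results: dict[int, float] = {}
    order = stats.table.sort_values(["p_value", "chrom", "pos"]).index
    for k in levels:
        kept = stats.table.drop(index=order[:k])
        reduced = SST(kept)
        test_scores = fit_score_pipeline(tr, te, reduced, panel, pipeline_cfg, seed=seed)
        results[k] = auc(test_scores, te.phenotype)
    return results
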