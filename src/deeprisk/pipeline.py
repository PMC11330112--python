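"""End-to-end scoring pipelines: selection -> encoding -> model -> scores.

A :class:`PipelineConfig` names the scoring method (the deep model or one of
the baselines), the SNP-selection parameters (a fixed pair or the full grid),
and — for the deep model — the gene annotation and training configuration.
:func:`fit_score_pipeline` is the single entry point used by cross-validation,
the robustness experiment and the command-line interface, so every consumer
gets identical leakage-free semantics: selection and training see only the
training cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .baselines import lasso_fit, prs_pt
from .data_io import GeneAnnotationTable, GenotypeDataset, SummaryStatsTable
from .feature_encoding import build_connectivity, encode
from .risk_analysis import auc
from .risk_model import ModelConfig, build_model, predict_scores, train
from .snp_selection import (
    SelectionParams,
    SelectionResult,
    grid_search,
    ld_clump,
)

METHODS = ("deeprisk", "pt", "lasso")


@dataclass
class PipelineConfig:
    method: str = "deeprisk"
    selection: SelectionParams = field(default_factory=lambda: SelectionParams(5e-3, None))
    grid: Sequence[SelectionParams] | None = None  # when set, grid search picks the params
    genes: GeneAnnotationTable | None = None
    model_cfg: ModelConfig = field(default_factory=ModelConfig)
    use_covariates: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


def _fit_and_score(
    selection: SelectionResult,
    train_ds: GenotypeDataset,
    test_ds: GenotypeDataset,
    stats: SummaryStatsTable,
    cfg: PipelineConfig,
    seed: int,
) -> np.ndarray:
    """Fit cfg.method on train_ds for a fixed SNP selection; score test_ds."""
    if cfg.method == "pt":
        return prs_pt(test_ds, stats, selection).scores

    cov_tr = train_ds.covariates if cfg.use_covariates else None
    cov_te = test_ds.covariates if cfg.use_covariates else None

    if cfg.method == "lasso":
        Xtr = encode(train_ds, selection, "additive").tensor[:, :, 0]
        Xte = encode(test_ds, selection, "additive").tensor[:, :, 0]
        res = lasso_fit(Xtr, train_ds.phenotype, cov_tr, seed=seed)
        return res.predict(Xte, cov_te)

    if cfg.genes is None:
        raise ValueError("the deep model needs a gene annotation")
    conn = build_connectivity(selection, train_ds.variants, cfg.genes)
    mcfg = replace(
        cfg.model_cfg,
        seed=seed,
        covariate_dim=(cov_tr.shape[1] if cov_tr is not None else 0),
    )
    mode = mcfg.encoding_mode
    Xtr = encode(train_ds, conn.snp_ids, mode)
    Xte = encode(test_ds, conn.snp_ids, mode)
    model = build_model(conn, mcfg)
    train(model, Xtr, train_ds.phenotype, cov_tr, mcfg)
    return predict_scores(model, Xte, cov_te)


def fit_score_pipeline(
    train_ds: GenotypeDataset,
    test_ds: GenotypeDataset,
    stats: SummaryStatsTable,
    panel: GenotypeDataset,
    cfg: PipelineConfig,
    seed: int = 0,
) -> np.ndarray:
    """Select SNPs (fixed params or grid search) on the training cohort, fit, score test."""
    if train_ds.phenotype is None:
        raise ValueError("training cohort must be labelled")
    if cfg.grid is not None:

        def train_fn(selection, tr, va):
            scores = _fit_and_score(selection, tr, va, stats, cfg, seed)
            return auc(scores, va.phenotype)

        best, _ = grid_search(stats, panel, train_ds, list(cfg.grid), train_fn, seed=seed)
        selection = ld_clump(stats, panel, best)
    else:
        selection = ld_clump(stats, panel, cfg.selection)
    return _fit_and_score(selection, train_ds, test_ds, stats, cfg, seed)
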