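"""Comparison methods: pruning-and-thresholding PRS and a lasso classifier.

Both consume the traditional additive alt-count representation — they are the
linear comparators against which the deep score is judged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_io import MISSING, GenotypeDataset, SummaryStatsTable
from .snp_selection import SelectionResult
from .risk_analysis import auc as _auc

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3, 2, 10))


@dataclass
class PRSResult:
    scores: np.ndarray
    selected_ids: list[str]
    params: object = None


def prs_pt(
    geno: GenotypeDataset, stats: SummaryStatsTable, selected: SelectionResult | list[str]
) -> PRSResult:
    """Classical weighted-sum PRS over the pruned/thresholded SNP set.

    score_i = sum_j beta_j * altcount_ij; missing genotypes contribute 0.
    """
    ids = selected.selected_variant_ids if isinstance(selected, SelectionResult) else list(selected)
    index = geno.variant_index()
    usable = [i for i in ids if i in index and i in stats.table.index]
    if not usable:
        raise ValueError("no overlap between selected SNPs and genotyped SNPs with betas")
    cols = [index[i] for i in usable]
    betas = stats.table.loc[usable, "beta"].to_numpy(float)
    counts = geno.alt_counts[:, cols].astype(float)
    counts[counts == MISSING] = 0.0
    scores = counts @ betas
    params = selected.params if isinstance(selected, SelectionResult) else None
    return PRSResult(scores=scores, selected_ids=usable, params=params)


@dataclass
class LassoResult:
    scores: np.ndarray              # P(case) on the fitting data
    nonzero: list[tuple[int, float]]  # (feature index, coefficient)
    best_lambda: float
    model: LogisticRegression = field(repr=False, default=None)
    _n_genotype_features: int = 0

    def predict(self, X: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        A = _assemble(X, covariates)
        return self.model.predict_proba(A)[:, 1]


def _assemble(X: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:  # accept encoded tensors by flattening
        X = X.reshape(X.shape[0], -1)
    if covariates is None:
        return X
    cov = np.asarray(covariates, dtype=float)
    sd = cov.std(axis=0)
    cov = (cov - cov.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    return np.concatenate([X, cov], axis=1)


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> LassoResult:
    """L1-penalized logistic classifier with lambda chosen by cross-validated AUC.

    ``lambda_grid`` holds penalty strengths (sklearn's C = 1/lambda).
    Covariates are standardized and appended to the genotype features.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate phenotype: one class only")
    A = _assemble(X, covariates)
    n_geno = A.shape[1] if covariates is None else A.shape[1] - covariates.shape[1]

    best_lam, best_cv = None, -np.inf
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(A, y))
    for lam in lambda_grid:
        aucs = []
        for tr, te in splits:
            m = _fit_one(A[tr], y[tr], lam, seed)
            p = m.predict_proba(A[te])[:, 1]
            aucs.append(_auc(p, y[te]))
        cv = float(np.mean(aucs))
        if cv > best_cv:
            best_cv, best_lam = cv, lam

    model = _fit_one(A, y, best_lam, seed)
    coefs = model.coef_.ravel()
    nonzero = [(int(j), float(c)) for j, c in enumerate(coefs) if c != 0.0]
    scores = model.predict_proba(A)[:, 1]
    return LassoResult(scores=scores, nonzero=nonzero, best_lambda=best_lam,
                       model=model, _n_genotype_features=n_geno)


def _fit_one(A: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=2000,
        random_state=seed,
    ).fit(A, y)
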