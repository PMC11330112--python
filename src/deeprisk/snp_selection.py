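"""P-value thresholding and LD-driven clumping against a reference panel.

The selection grid crosses four p-value thresholds (5e-3 .. 5e-6) with five
r-squared thresholds (0.2, 0.4, 0.6, 0.8 and none), giving 20 candidate SNP
sets; the pair of parameters that scores best on held-out training data is
carried to the test set.

Clumping is greedy: SNPs passing the p threshold are visited in ascending
p-value order (ties by (chrom, pos) then id); each unassigned SNP becomes an
index SNP and absorbs every unassigned SNP on the same chromosome within the
window whose genotypic r-squared with it reaches the threshold.  The window is
a radius: |pos_index - pos_other| <= window_bp.  An r-squared threshold of
``None`` disables clumping entirely (pure p-thresholding, no window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeDataset, SummaryStatsTable

logger = logging.getLogger(__name__)

P_GRID = (5e-3, 5e-4, 5e-5, 5e-6)
R2_GRID = (0.2, 0.4, 0.6, 0.8, None)


class NoSNPsSelectedError(ValueError):
    """Raised when a parameter pair leaves the selected SNP set empty."""


class MonomorphicVariantError(ValueError):
    """r-squared is undefined for a variant with no variation among complete cases."""


@dataclass(frozen=True)
class SelectionParams:
    """One point of the selection grid."""

    p_threshold: float
    r2_threshold: float | None = None
    window_bp: int = 250_000

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if self.r2_threshold is not None and not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0,1] or None")
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")

    def label(self) -> str:
        r2 = "-" if self.r2_threshold is None else f"{self.r2_threshold:g}"
        return f"p<={self.p_threshold:g}, r2<{r2}"


@dataclass
class SelectionResult:
    """Index SNPs chosen by one parameter pair, ordered by (chrom, pos)."""

    selected_variant_ids: list[str]
    params: SelectionParams
    clumps: dict[str, list[str]] = field(default_factory=dict)  # index SNP -> absorbed members


def default_grid(window_bp: int = 250_000) -> list[SelectionParams]:
    """The full 4 x 5 parameter grid (20 candidates)."""
    return [SelectionParams(p, r2, window_bp) for p in P_GRID for r2 in R2_GRID]


def compute_r2(panel: GenotypeDataset, i: int, j: int) -> float:
    """Genotypic r²: squared Pearson correlation of alt-counts over complete cases.

    Raises :class:`MonomorphicVariantError` when either column is constant
    among complete cases (callers treat that as r² = 0).
    """
    a = panel.alt_counts[:, i]
    b = panel.alt_counts[:, j]
    obs = (a != MISSING) & (b != MISSING)
    if obs.sum() < 2:
        raise MonomorphicVariantError(f"fewer than 2 complete cases for variants {i},{j}")
    x = a[obs].astype(float)
    y = b[obs].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise MonomorphicVariantError(f"variant {i if sx == 0 else j} monomorphic among complete cases")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def _r2_or_zero(panel: GenotypeDataset, i: int, j: int) -> float:
    try:
        return compute_r2(panel, i, j)
    except MonomorphicVariantError:
        return 0.0


def ld_clump(
    stats: SummaryStatsTable,
    panel: GenotypeDataset,
    params: SelectionParams,
) -> SelectionResult:
    """Greedy LD clumping of summary statistics against a reference panel.

    Only SNPs present in both the summary stats and the panel are considered.
    Output index SNPs are ordered by (chrom, pos).
    """
    panel_idx = panel.variant_index()
    cand = stats.table[stats.table["p_value"] <= params.p_threshold]
    cand = cand[cand.index.isin(panel_idx)]
    if cand.empty:
        raise NoSNPsSelectedError(f"no SNPs selected at {params.label()}")

    if params.r2_threshold is None:
        order = cand.sort_values(["chrom", "pos"]).index.tolist()
        return SelectionResult(order, params, {vid: [] for vid in order})

    # ascending p, ties by (chrom, pos) then id
    visit = cand.assign(_id=cand.index).sort_values(
        ["p_value", "chrom", "pos", "_id"]
    ).index.tolist()
    pos = {vid: int(stats.table.at[vid, "pos"]) for vid in visit}
    chrom = {vid: int(stats.table.at[vid, "chrom"]) for vid in visit}
    assigned: set[str] = set()
    clumps: dict[str, list[str]] = {}
    for vid in visit:
        if vid in assigned:
            continue
        assigned.add(vid)
        members: list[str] = []
        for other in visit:
            if other in assigned or chrom[other] != chrom[vid]:
                continue
            if abs(pos[other] - pos[vid]) > params.window_bp:
                continue
            if _r2_or_zero(panel, panel_idx[vid], panel_idx[other]) >= params.r2_threshold:
                assigned.add(other)
                members.append(other)
        clumps[vid] = members

    index_snps = sorted(clumps, key=lambda v: (chrom[v], pos[v], v))
    return SelectionResult(index_snps, params, clumps)


def grid_search(
    stats: SummaryStatsTable,
    panel: GenotypeDataset,
    cohort_train: GenotypeDataset,
    grid: Sequence[SelectionParams],
    train_fn: Callable[[SelectionResult, GenotypeDataset, GenotypeDataset], float],
    *,
    seed: int = 0,
    val_fraction: float = 0.2,
    select_on_train: bool = False,
) -> tuple[SelectionParams, pd.DataFrame]:
    """Pick the grid point whose trained candidate scores best.

    ``train_fn(selection, train_split, val_split) -> AUC`` trains one candidate
    and returns the metric on ``val_split``.  By default the training cohort is
    split into a stratified 80/20 internal train/validation split so the grid
    is not chosen by in-sample fit; ``select_on_train=True`` instead evaluates
    on the full training cohort itself (train == val), the looser protocol.
    Parameter pairs selecting zero SNPs are recorded with metric NaN and
    excluded from the argmax.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if cohort_train.phenotype is None:
        raise ValueError("grid search needs a labelled training cohort")

    if select_on_train:
        tr = va = cohort_train
    else:
        tr_idx, va_idx = stratified_split(cohort_train.phenotype, val_fraction, seed)
        tr, va = cohort_train.subset_samples(tr_idx), cohort_train.subset_samples(va_idx)

    rows = []
    for params in grid:
        try:
            selection = ld_clump(stats, panel, params)
            metric = float(train_fn(selection, tr, va))
            n_sel = len(selection.selected_variant_ids)
        except NoSNPsSelectedError:
            metric, n_sel = float("nan"), 0
        rows.append(
            {
                "p_threshold": params.p_threshold,
                "r2_threshold": np.nan if params.r2_threshold is None else params.r2_threshold,
                "window_bp": params.window_bp,
                "n_snps": n_sel,
                "metric": metric,
            }
        )
    table = pd.DataFrame(rows)
    if table["metric"].isna().all():
        raise NoSNPsSelectedError("every grid point selected zero SNPs")
    best = int(table["metric"].idxmax())  # NaNs excluded by idxmax
    return grid[best], table


def stratified_split(
    y: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified two-way split; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    test: list[np.ndarray] = []
    train: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, int(round(test_fraction * len(idx))))
        test.append(idx[:k])
        train.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))
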