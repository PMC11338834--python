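"""Module scoring and downstream statistics.

Covers per-cell module scores (mean normalized expression of member genes),
hypergeometric covariate enrichment of high-scoring cells, sample-aggregated
module-module correlation networks, assignment of differentially expressed
genes (DEGs) to their closest module with hypergeometric enrichment, and
Gaussian contour smoothing of per-cell values on a 2D embedding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

from .graphs import ModuleSet, _module_sort_key
from .io import ExpressionMatrix

logger = logging.getLogger("scdemon")

__all__ = [
    "ModuleScores",
    "score_modules",
    "enrich_covariate",
    "module_module_network",
    "assign_degs_to_modules",
    "smooth_contour",
]


@dataclass
class ModuleScores:
    """Per-cell module activity: cells x modules table."""

    scores: pd.DataFrame  # index = cell ids, columns = module ids

    def aggregate(self, cell_meta: pd.DataFrame, group_keys: list[str]) -> pd.DataFrame:
        """Mean score per group (e.g. subtype x sample, or sample alone)."""
        meta = cell_meta.loc[self.scores.index, group_keys]
        return self.scores.groupby([meta[k] for k in group_keys], observed=True).mean()


def score_modules(
    X: ExpressionMatrix, modules: ModuleSet, background_correct: bool = False
) -> ModuleScores:
    """Mean normalized expression of each module's member genes per cell.

    Module genes missing from ``X`` are dropped with a warning; a module
    with no genes present yields a NaN column.  With
    ``background_correct=True`` the mean expression over all genes is
    subtracted from every module score.
    """
    gene_pos = {gname: i for i, gname in enumerate(X.gene_ids)}
    cols = {}
    mod_ids = sorted(modules.modules, key=_module_sort_key)
    for mid in mod_ids:
        idx = [gene_pos[gname] for gname in modules.modules[mid] if gname in gene_pos]
        n_missing = len(modules.modules[mid]) - len(idx)
        if n_missing:
            warnings.warn(f"{mid}: {n_missing} member genes absent from the matrix")
        if not idx:
            cols[mid] = np.full(X.n_cells, np.nan)
            continue
        cols[mid] = np.asarray(X.values[:, idx].mean(axis=1)).ravel()
    scores = pd.DataFrame(cols, index=pd.Index(X.cell_ids, name="cell_id"))
    if background_correct:
        bg = np.asarray(X.values.mean(axis=1)).ravel()
        scores = scores.sub(bg, axis=0)
    return ModuleScores(scores=scores)


def enrich_covariate(
    scores: ModuleScores,
    covariate: pd.Series,
    sd_mult: float = 1.0,
    p_thresh: float = 0.001,
) -> pd.DataFrame:
    """Hypergeometric enrichment of high-scoring cells in covariate levels.

    Cells with module score above mean + ``sd_mult`` s.d. (over all cells)
    are the "high" set; for every covariate level the upper-tail
    hypergeometric probability of the observed high/level overlap is
    computed.  Rows with p below ``p_thresh`` are flagged enriched.
    """
    cov = covariate.reindex(scores.scores.index)
    if cov.isna().any():
        raise ValueError("covariate must be defined for every scored cell")
    n_total = len(cov)
    rows = []
    for mid in scores.scores.columns:
        s = scores.scores[mid].to_numpy()
        if np.isnan(s).all():
            continue
        high = s > (np.nanmean(s) + sd_mult * np.nanstd(s))
        n_high = int(high.sum())
        for level, level_mask in ((lv, (cov == lv).to_numpy()) for lv in cov.unique()):
            n_level = int(level_mask.sum())
            if n_level == 0:
                continue
            overlap = int((high & level_mask).sum())
            expected = n_high * n_level / n_total
            pval = hypergeom.sf(overlap - 1, n_total, n_level, n_high)
            rows.append(
                (mid, covariate.name or "covariate", level, overlap, expected,
                 pval, "high" if overlap >= expected else "low")
            )
    table = pd.DataFrame(
        rows,
        columns=["module", "covariate", "level", "overlap", "expected", "p", "direction"],
    )
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table["enriched"] = table["p"] < p_thresh
    else:
        table["p_adj"] = []
        table["enriched"] = []
    return table


def module_module_network(
    scores: ModuleScores,
    cell_meta: pd.DataFrame,
    group_keys: list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Module co-activity network on aggregated, logged scores.

    Scores are averaged per group (e.g. subtype x sample), shifted to
    positivity and logged as ``log(score - min + 1)``, Pearson-correlated per
    module pair with a one-sided (positive) test, and Benjamini-Hochberg
    adjusted; edges with adjusted p below ``alpha`` are kept.
    """
    agg = scores.aggregate(cell_meta, group_keys)
    if len(agg) < 3:
        raise ValueError("need at least 3 aggregation groups for correlations")
    logged = np.log(agg - agg.min().min() + 1.0)
    keep_cols = [c for c in logged.columns if logged[c].std() > 0]
    dropped = set(logged.columns) - set(keep_cols)
    if dropped:
        logger.warning("excluding constant aggregated modules: %s", sorted(dropped))
    rows = []
    for i, a in enumerate(keep_cols):
        for b in keep_cols[i + 1 :]:
            r, p = pearsonr(logged[a], logged[b], alternative="greater")
            rows.append((a, b, r, p))
    table = pd.DataFrame(rows, columns=["module_i", "module_j", "r", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table[table["p_adj"] < alpha].reset_index(drop=True)
    return table


def assign_degs_to_modules(
    deg_table: pd.DataFrame,
    X: ExpressionMatrix,
    modules: ModuleSet,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign tested genes to their closest module, then test DEG enrichment.

    Each tested gene is assigned to the module whose average member
    expression profile across cells it correlates with most.  Per module x
    category (up / down / ns) a hypergeometric test compares the number of
    category genes assigned to the module against the totals; p-values are
    Benjamini-Hochberg adjusted.  Returns (assignment series, enrichment
    table).  ``deg_table`` needs columns ``gene_id`` and ``category``.
    """
    if not {"gene_id", "category"} <= set(deg_table.columns):
        raise ValueError("deg_table requires columns gene_id and category")
    gene_pos = {gname: i for i, gname in enumerate(X.gene_ids)}
    tested = [gname for gname in deg_table["gene_id"] if gname in gene_pos]
    mod_ids = sorted(modules.modules, key=_module_sort_key)
    # module average-expression profiles across cells
    profiles = np.column_stack(
        [
            np.asarray(
                X.values[:, [gene_pos[gname] for gname in modules.modules[mid] if gname in gene_pos]]
                .mean(axis=1)
            ).ravel()
            for mid in mod_ids
        ]
    )
    prof_c = profiles - profiles.mean(axis=0)
    prof_norm = np.linalg.norm(prof_c, axis=0)
    expr = np.asarray(X.values[:, [gene_pos[gname] for gname in tested]].todense())
    expr_c = expr - expr.mean(axis=0)
    expr_norm = np.linalg.norm(expr_c, axis=0)
    valid = expr_norm > 0
    if (~valid).any():
        logger.warning("%d zero-variance genes left unassigned", int((~valid).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (expr_c.T @ prof_c) / np.outer(
            np.maximum(expr_norm, 1e-300), np.maximum(prof_norm, 1e-300)
        )
    best = np.argmax(corr, axis=1)
    assignment = pd.Series(
        [mod_ids[b] if ok else np.nan for b, ok in zip(best, valid)],
        index=pd.Index(tested, name="gene_id"),
        name="module",
    )
    cat = deg_table.set_index("gene_id")["category"].reindex(tested)
    assigned = assignment.dropna()
    n_tested = len(assigned)
    rows = []
    for mid in mod_ids:
        in_mod = assigned == mid
        n_mod = int(in_mod.sum())
        for level in sorted(cat.dropna().unique()):
            n_cat = int((cat.loc[assigned.index] == level).sum())
            overlap = int((in_mod & (cat.loc[assigned.index] == level)).sum())
            pval = hypergeom.sf(overlap - 1, n_tested, n_cat, n_mod)
            rows.append((mid, "deg_category", level, overlap, n_mod * n_cat / max(n_tested, 1), pval))
    table = pd.DataFrame(
        rows, columns=["module", "covariate", "level", "overlap", "expected", "p"]
    )
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return assignment, table


def gaussian_kernel(size: int = 25, sigma: float = 1.0) -> np.ndarray:
    half = size // 2
    ax = np.arange(-half, half + 1)
    k = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    return k / k.sum()


def smooth_contour(
    coords: np.ndarray,
    values: np.ndarray,
    grid: int = 500,
    kernel: int = 25,
    sigma: float = 1.0,
) -> dict:
    """Smooth per-cell values on a 2D embedding grid for contour plotting.

    Values are averaged per occupied grid cell on a ``grid x grid`` raster
    over the coordinate bounding box, then convolved with a normalized 2D
    Gaussian kernel.  Returns the surface, the grid edges, and contour
    levels at 0.1-0.8 of the surface maximum.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (np.all(np.isfinite(coords)) and np.all(np.isfinite(values))):
        raise ValueError("coords and values must be finite")
    x_edges = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid + 1)
    y_edges = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid + 1)
    xi = np.clip(np.digitize(coords[:, 0], x_edges) - 1, 0, grid - 1)
    yi = np.clip(np.digitize(coords[:, 1], y_edges) - 1, 0, grid - 1)
    flat = xi * grid + yi
    counts = np.bincount(flat, minlength=grid * grid).astype(float)
    sums = np.bincount(flat, weights=values, minlength=grid * grid)
    with np.errstate(invalid="ignore"):
        binned = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    binned = binned.reshape(grid, grid)
    k = gaussian_kernel(kernel, sigma)
    surface = scipy.signal.convolve2d(binned, k, mode="same", boundary="fill")
    peak = surface.max()
    levels = np.arange(0.1, 0.81, 0.1) * peak
    return {
        "surface": surface,
        "x_edges": x_edges,
        "y_edges": y_edges,
        "levels": levels,
        "occupied": counts.reshape(grid, grid) > 0,
    }
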