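"""Sparsity calibration of decorrelated correlations via 2D binning + splines.

Correlation estimates between sparsely expressed gene pairs are inflated
relative to dense pairs.  To correct this, every gene pair is binned by the
two genes' sparsities (expressed fraction, log10 scale), the per-bin mean and
s.d. of the decorrelated correlations are computed, both statistics are
smoothed with bivariate splines weighted by the log number of pairs per bin,
and the correlation matrix is z-scored against the smoothed surfaces.
Z-scores are averaged over bootstraps of experimental batches to stabilize
edges against batch-driven artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LSQBivariateSpline, SmoothBivariateSpline

from .decorrelation import DecorrelatedCorrelation, compute_svd, decorrelated_covariance
from .io import ExpressionMatrix, GeneSparsity, compute_sparsity

logger = logging.getLogger("scdemon")

__all__ = [
    "SparsityBinModel",
    "ZScoreMatrix",
    "fit_sparsity_bins",
    "zscore_correlations",
    "bootstrap_zscores",
    "zscore_pipeline_single",
]

SD_FLOOR = 1e-4  # guards divisions in near-empty bins
N_BINS = 20


@dataclass
class SparsityBinModel:
    """Binned + spline-smoothed mean/s.d. of correlations vs pair sparsity.

    ``constant=True`` marks the fallback model (fewer than 4 populated bins
    per axis): both surfaces are flat at the global mean/s.d.
    """

    bin_edges: np.ndarray
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    bin_count: np.ndarray
    sd_floor: float = SD_FLOOR
    constant: bool = False
    global_mean: float = 0.0
    global_sd: float = 1.0
    _mean_spline: object = field(default=None, repr=False)
    _sd_spline: object = field(default=None, repr=False)

    def surfaces(self, log10_sparsity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate smoothed mean and s.d. at every pair (s_i, s_j).

        Returns two symmetric g x g matrices.
        """
        s = np.asarray(log10_sparsity, dtype=float)
        if self.constant:
            g = len(s)
            mu = np.full((g, g), self.global_mean)
            sd = np.full((g, g), max(self.global_sd, self.sd_floor))
            return mu, sd
        # grid-evaluate on sorted unique sparsities, then scatter back
        uniq, inv = np.unique(s, return_inverse=True)
        mu_u = self._mean_spline(uniq, uniq, grid=True)
        sd_u = self._sd_spline(uniq, uniq, grid=True)
        mu = mu_u[np.ix_(inv, inv)]
        sd = sd_u[np.ix_(inv, inv)]
        mu = 0.5 * (mu + mu.T)
        sd = 0.5 * (sd + sd.T)
        return mu, np.maximum(sd, self.sd_floor)


@dataclass
class ZScoreMatrix:
    """Symmetric matrix of sparsity-calibrated correlation z-scores."""

    z: np.ndarray
    gene_ids: np.ndarray
    provenance: dict = field(default_factory=dict)
    n_contrib: np.ndarray = None  # bootstraps contributing per entry

    def edge_table(self, z_floor: float = 0.0):
        """Long-format (gene_i, gene_j, z) table of entries above ``z_floor``."""
        import pandas as pd

        iu = np.triu_indices_from(self.z, k=1)
        keep = self.z[iu] > z_floor
        return pd.DataFrame(
            {
                "gene_i": self.gene_ids[iu[0][keep]],
                "gene_j": self.gene_ids[iu[1][keep]],
                "z": self.z[iu][keep],
            }
        )


def _pair_bin_stats(corr: np.ndarray, bin_idx: np.ndarray, n_bins: int):
    """Mean/sd/count of off-diagonal correlations per unordered sparsity-bin pair."""
    iu = np.triu_indices_from(corr, k=1)
    r = corr[iu]
    bi, bj = bin_idx[iu[0]], bin_idx[iu[1]]
    lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
    flat = lo * n_bins + hi
    count = np.bincount(flat, minlength=n_bins * n_bins).astype(float)
    s1 = np.bincount(flat, weights=r, minlength=n_bins * n_bins)
    s2 = np.bincount(flat, weights=r * r, minlength=n_bins * n_bins)
    count = count.reshape(n_bins, n_bins)
    s1 = s1.reshape(n_bins, n_bins)
    s2 = s2.reshape(n_bins, n_bins)
    # mirror to a symmetric table (upper triangle holds all unordered pairs)
    count = count + np.triu(count, 1).T
    s1 = s1 + np.triu(s1, 1).T
    s2 = s2 + np.triu(s2, 1).T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 1, s2 / np.maximum(count, 1) - mean**2, np.nan)
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean, sd, count


def fit_sparsity_bins(
    corr: DecorrelatedCorrelation | np.ndarray,
    sp: GeneSparsity,
    n_bins: int = N_BINS,
) -> SparsityBinModel:
    """Bin pair correlations by (log10 s_i, log10 s_j) and smooth mean/s.d.

    Equal-width bins on the observed log10-sparsity range; spline fits are
    weighted by log(1 + pair count) and skip empty bins.  With fewer than 4
    populated bins per axis the model falls back to flat global surfaces.
    """
    C = corr.corr if isinstance(corr, DecorrelatedCorrelation) else np.asarray(corr)
    ls = np.asarray(sp.log10_sparsity, dtype=float)
    if not np.all(np.isfinite(ls)):
        raise ValueError("all genes must have fraction_expressed > 0 (filter first)")
    lo, hi = ls.min(), ls.max()
    if hi - lo < 1e-12:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_idx = np.clip(np.digitize(ls, edges) - 1, 0, n_bins - 1)
    mean, sd, count = _pair_bin_stats(C, bin_idx, n_bins)

    iu = np.triu_indices_from(C, k=1)
    vals = C[iu]
    g_mean, g_sd = float(vals.mean()), float(vals.std())

    populated = count > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    px, py = np.nonzero(populated)
    n_x = len(np.unique(px))
    n_y = len(np.unique(py))
    model = SparsityBinModel(
        bin_edges=edges,
        bin_mean=mean,
        bin_sd=sd,
        bin_count=count,
        global_mean=g_mean,
        global_sd=g_sd,
    )
    if n_x < 4 or n_y < 4:
        logger.warning(
            "only %dx%d populated sparsity bins; using flat global calibration", n_x, n_y
        )
        model.constant = True
        return model
    model._mean_spline = _fit_surface(centers, px, py, mean, count)
    # s.d. needs >= 2 pairs per bin; smoothed on the raw scale
    sx, sy = np.nonzero(count > 1)
    model._sd_spline = _fit_surface(centers, sx, sy, sd, count)
    return model


def _fit_surface(centers, px, py, values, count):
    """Weighted least-squares bivariate spline of a binned statistic.

    Interior knots sit at every other bin center, which leaves enough
    flexibility to track the sparsity-dependent surface while the
    log(1 + count) weights pool information across neighbouring bins.  If
    the knot placement is infeasible for the populated cells (Schoenberg-
    Whitney violation on sparsely populated grids) the knot set degrades
    until the fit succeeds.
    """
    w = np.log1p(count[px, py])
    x, y = centers[px], centers[py]
    kx = min(3, len(np.unique(x)) - 1)
    ky = min(3, len(np.unique(y)) - 1)
    for step in (2, 4, 8):
        knots = centers[2:-2:step]
        if len(knots) == 0:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                return LSQBivariateSpline(x, y, values[px, py], knots, knots, w=w, kx=kx, ky=ky)
        except Exception:  # infeasible knots; coarsen
            continue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return SmoothBivariateSpline(x, y, values[px, py], w=w, kx=kx, ky=ky)


def zscore_correlations(
    corr: DecorrelatedCorrelation,
    model: SparsityBinModel,
    sp: GeneSparsity,
) -> ZScoreMatrix:
    """z[i, j] = (corr[i, j] - mu(s_i, s_j)) / max(sigma(s_i, s_j), floor)."""
    C = corr.corr
    if len(sp.fraction_expressed) != C.shape[0]:
        raise ValueError("sparsity vector does not match the correlation gene set")
    mu, sd = model.surfaces(sp.log10_sparsity)
    z = (C - mu) / sd
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, 0.0)
    return ZScoreMatrix(z=z, gene_ids=corr.gene_ids, provenance={"p": corr.p})


def zscore_pipeline_single(
    X: ExpressionMatrix,
    p: float,
    k: int,
    seed: int = 0,
    n_bins: int = N_BINS,
    svd=None,
) -> ZScoreMatrix:
    """Single-pass SVD -> decorrelated correlation -> sparsity z-score."""
    sp_ = compute_sparsity(X)
    expressed = sp_.fraction_expressed > 0
    Xe = X.subset_genes(expressed) if not expressed.all() else X
    spe = GeneSparsity(sp_.fraction_expressed[expressed])
    if svd is None:
        svd = compute_svd(Xe, k=min(k, min(Xe.values.shape)), seed=seed)
    corr = decorrelated_covariance(svd, p=p, n=Xe.n_cells, g=Xe.n_genes, gene_ids=Xe.gene_ids)
    model = fit_sparsity_bins(corr, spe, n_bins=n_bins)
    zs = zscore_correlations(corr, model, spe)
    if expressed.all():
        zs.provenance.update({"k": svd.k, "seed": seed})
        return zs
    # scatter back into the full gene universe; unexpressed genes get z = 0
    g = X.n_genes
    z_full = np.zeros((g, g))
    idx = np.flatnonzero(expressed)
    z_full[np.ix_(idx, idx)] = zs.z
    return ZScoreMatrix(
        z=z_full, gene_ids=X.gene_ids, provenance={"p": p, "k": svd.k, "seed": seed}
    )


def _draw_batch_subsets(batches, n_boot, batch_fraction, rng):
    n_take = int(np.ceil(batch_fraction * len(batches)))
    n_take = max(1, min(n_take, len(batches)))
    return [rng.choice(batches, size=n_take, replace=False) for _ in range(n_boot)]


def bootstrap_zscores(
    X: ExpressionMatrix,
    p: float | list[float],
    k: int,
    n_boot: int = 10,
    batch_fraction: float = 0.9,
    seed: int = 0,
    n_bins: int = N_BINS,
) -> ZScoreMatrix | dict[float, ZScoreMatrix]:
    """Bootstrap-averaged z-scores over resampled batches.

    Each bootstrap draws ``ceil(batch_fraction * B)`` batches without
    replacement, reruns SVD -> decorrelated correlation -> calibration -> z
    on those cells, and the ``n_boot`` z-matrices are averaged elementwise.
    Genes unexpressed in a bootstrap's cell subset contribute nothing for
    that bootstrap; their averages renormalize by the number of contributing
    bootstraps.  ``p`` may be a single power or a list (the per-bootstrap SVD
    is shared across powers); a dict keyed by power is returned for a list.

    The gene sparsity filter is applied once, on the full dataset, before
    calling this function - not per bootstrap.
    """
    powers = [p] if np.isscalar(p) else list(p)
    batches = X.batches
    if len(batches) < 2:
        raise ValueError("bootstrap over batches requires at least 2 batches")
    rng = np.random.default_rng(seed)
    subsets = _draw_batch_subsets(batches, n_boot, batch_fraction, rng)
    g = X.n_genes
    z_sum = {pw: np.zeros((g, g)) for pw in powers}
    contrib = np.zeros((g, g))
    batch_col = X.cell_meta["batch_id"].astype(str).to_numpy()

    for b, chosen in enumerate(subsets):
        mask = np.isin(batch_col, chosen)
        for attempt in range(10):
            if mask.sum() >= 2:
                break
            chosen = rng.choice(batches, size=len(chosen), replace=False)
            mask = np.isin(batch_col, chosen)
        else:
            raise ValueError("could not draw a bootstrap subset with >= 2 cells")
        sub = X.subset_cells(mask)
        sp_ = compute_sparsity(sub)
        expressed = sp_.fraction_expressed > 0
        idx = np.flatnonzero(expressed)
        sube = sub.subset_genes(expressed) if not expressed.all() else sub
        spe = GeneSparsity(sp_.fraction_expressed[expressed])
        k_b = min(k, min(sube.values.shape) - 1)
        svd = compute_svd(sube, k=k_b, seed=seed + 1000 * b)
        for pw in powers:
            corr = decorrelated_covariance(
                svd, p=pw, n=sube.n_cells, g=sube.n_genes, gene_ids=sube.gene_ids
            )
            model = fit_sparsity_bins(corr, spe, n_bins=n_bins)
            zs = zscore_correlations(corr, model, spe)
            z_sum[pw][np.ix_(idx, idx)] += zs.z
        contrib[np.ix_(idx, idx)] += 1.0
        logger.debug("bootstrap %d: %d cells, %d genes", b, sube.n_cells, len(idx))

    np.fill_diagonal(contrib, 0.0)
    out = {}
    for pw in powers:
        with np.errstate(invalid="ignore", divide="ignore"):
            z_avg = np.where(contrib > 0, z_sum[pw] / np.maximum(contrib, 1.0), 0.0)
        np.fill_diagonal(z_avg, 0.0)
        out[pw] = ZScoreMatrix(
            z=z_avg,
            gene_ids=X.gene_ids,
            provenance={"p": pw, "n_boot": n_boot, "seed": seed, "k": k},
            n_contrib=contrib,
        )
    return out[powers[0]] if np.isscalar(p) else out
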