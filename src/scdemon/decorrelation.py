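"""ZCA sample-decorrelation of gene-gene covariance via the truncated SVD.

The whitening (ZCA) transform ``W = C^{-1/2}`` applied on the cell side of a
cells x genes matrix X removes sample-sample correlation, which suppresses
the dominance of abundant cell types in the gene-gene covariance.  Forming
the n x n cell covariance is intractable at atlas scale, but with the
(non-centred) truncated SVD ``X = U S V^T`` the covariance of the whitened
data reduces analytically to

    C_ZCA = g * V S^p V^T / n

with ``p = 0`` the fully decorrelated case and ``p = 2`` recovering the raw
non-centred covariance ``g * X^T X / n``.  Intermediate powers tune the
contribution of the dominant singular components, which otherwise drop out
of the decorrelated matrix together with the largest identity programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

logger = logging.getLogger("scdemon")

__all__ = [
    "SVDFactorization",
    "DecorrelatedCorrelation",
    "compute_svd",
    "decorrelated_covariance",
    "select_k",
]

DEFAULT_K = 100  # component count used for the published-data preset

EPS_DIAG = 1e-12  # diagonal floor when rescaling covariance to correlation


@dataclass
class SVDFactorization:
    """Truncated non-centred SVD ``X ~ U diag(S) V^T``."""

    U: np.ndarray  # n x k, orthonormal columns
    S: np.ndarray  # length k, descending, >= 0
    V: np.ndarray  # g x k, orthonormal columns
    k: int
    centered: bool = False

    def __post_init__(self):
        if self.centered:
            raise ValueError("the analytic reduction requires a non-centred SVD")
        order = np.argsort(self.S)[::-1]
        if not np.array_equal(order, np.arange(len(self.S))):
            self.S = self.S[order]
            self.U = self.U[:, order]
            self.V = self.V[:, order]


@dataclass
class DecorrelatedCorrelation:
    """Decorrelated gene-gene covariance/correlation at eigenvalue power p."""

    p: float
    cov: np.ndarray  # g x g symmetric
    corr: np.ndarray  # g x g, unit diagonal, clipped to [-1, 1]
    gene_ids: np.ndarray
    valid: np.ndarray = None  # genes with positive diagonal (rescalable)

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(self.cov.shape[0], dtype=bool)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|loading| V entry positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def compute_svd(X, k: int, seed: int = 0) -> SVDFactorization:
    """Truncated non-centred SVD of the expression matrix.

    Uses a randomized solver; deterministic for a fixed ``seed``.  Accepts an
    :class:`~scdemon.io.ExpressionMatrix` or a raw (sparse) array.
    """
    values = getattr(X, "values", X)
    n, g = values.shape
    if k > min(n, g):
        raise ValueError(f"k={k} exceeds min(n, g)={min(n, g)}")
    U, S, Vt = randomized_svd(
        values, n_components=k, n_iter=7, random_state=int(seed)
    )
    U, V = _fix_signs(U, Vt.T)
    return SVDFactorization(U=U, S=S, V=V, k=k)


def decorrelated_covariance(
    svd: SVDFactorization, p: float, n: int, g: int, gene_ids=None
) -> DecorrelatedCorrelation:
    """Form ``C_ZCA = g * V S^p V^T / n`` and rescale to unit diagonal.

    Genes whose diagonal entry is ~0 (below ``EPS_DIAG``) cannot be rescaled;
    they are flagged in ``valid`` and their correlation rows zeroed.
    """
    if p < 0:
        raise ValueError("eigenvalue power p must be >= 0")
    V, S = svd.V, svd.S
    with np.errstate(divide="ignore"):
        sp_pow = np.where(S > 0, S**p, 0.0 if p > 0 else 1.0)
    cov = (g / n) * ((V * sp_pow) @ V.T)
    cov = 0.5 * (cov + cov.T)
    d = np.diag(cov).copy()
    valid = d > EPS_DIAG
    scale = 1.0 / np.sqrt(np.maximum(d, EPS_DIAG))
    corr = cov * scale[:, None] * scale[None, :]
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    if not valid.all():
        corr[~valid, :] = 0.0
        corr[:, ~valid] = 0.0
        logger.warning("%d genes have ~zero decorrelated variance", int((~valid).sum()))
    if gene_ids is None:
        gene_ids = np.arange(cov.shape[0])
    return DecorrelatedCorrelation(p=p, cov=cov, corr=corr, gene_ids=np.asarray(gene_ids, dtype=object), valid=valid)


def whiten_explicit(values, k: int, seed: int = 0) -> np.ndarray:
    """Brute-force ZCA on the cell side: ``X_zca = g^{1/2} U S^{-1} U^T X``.

    Reference pipeline retained for validation; materializes dense arrays and
    is only usable on small matrices.
    """
    values = getattr(values, "values", values)
    n, g = values.shape
    svd = compute_svd(values, k=k, seed=seed)
    dense = values.toarray() if sp.issparse(values) else np.asarray(values)
    Sinv = np.where(svd.S > 0, 1.0 / svd.S, 0.0)
    return np.sqrt(g) * (svd.U * Sinv) @ (svd.U.T @ dense)


def _half_split_edges(X, k: int, z_cut: float, seed: int, p: float = 0.0):
    """Edge sets from z-scored graphs on two batch half-splits (helper for select_k)."""
    from .zscore import zscore_pipeline_single

    rng = np.random.default_rng(seed)
    batches = X.batches
    perm = rng.permutation(len(batches))
    halves = [set(batches[perm[: len(batches) // 2]]), set(batches[perm[len(batches) // 2 :]])]
    edge_sets = []
    for half in halves:
        mask = X.cell_meta["batch_id"].astype(str).isin(half).to_numpy()
        sub = X.subset_cells(mask)
        z = zscore_pipeline_single(sub, p=p, k=min(k, min(sub.values.shape) - 1), seed=seed)
        iu = np.triu_indices_from(z.z, k=1)
        hits = z.z[iu] > z_cut
        edge_sets.append(set(zip(iu[0][hits].tolist(), iu[1][hits].tolist())))
    return edge_sets


def select_k(X, k_grid, seed: int = 0, z_cut: float = 4.5) -> int:
    """Grid-search the SVD component count by edge-set stability.

    For each candidate ``k``, the batches are split into two halves, the
    z-scored graph is thresholded on each half, and the Jaccard similarity
    of the two edge sets is recorded; the most stable ``k`` wins.  With
    fewer than 2 batches no split exists and the default ``k = 100`` (capped
    at ``min(n, g) - 1``) is returned with a warning.
    """
    k_grid = list(k_grid)
    cap = min(X.values.shape) - 1
    if len(k_grid) == 1:
        return int(k_grid[0])
    if len(X.batches) < 2:
        logger.warning("fewer than 2 batches; falling back to default k")
        return min(DEFAULT_K, cap)
    bad = [k for k in k_grid if k > min(X.values.shape)]
    if bad:
        raise ValueError(f"k values {bad} exceed min(n, g)={min(X.values.shape)}")
    best_k, best_j = k_grid[0], -1.0
    for k in k_grid:
        a, b = _half_split_edges(X, k=k, z_cut=z_cut, seed=seed)
        union = len(a | b)
        jac = (len(a & b) / union) if union else 0.0
        logger.info("select_k: k=%d stability Jaccard=%.3f", k, jac)
        if jac > best_j:
            best_k, best_j = k, jac
    return int(best_k)
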