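"""Preprocessing: filtering, normalisation, HVG selection, per-batch scaling, PCA.

All stages operate on :class:`anndata.AnnData` and delegate the standard
steps to scanpy.  The pipeline order is fixed:

    filter_cells_genes -> normalize_log -> select_hvgs -> scale_per_batch -> pca_embed

Gene filtering runs after cell filtering and can re-lower some cells' gene
count below the cell threshold; filtering is deliberately not re-applied.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp

__all__ = [
    "filter_cells_genes",
    "normalize_log",
    "select_hvgs",
    "scale_per_batch",
    "pca_embed",
    "preprocess",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def filter_cells_genes(
    adata: ad.AnnData, min_genes: int = 10, min_cells: int = 3
) -> ad.AnnData:
    """Drop low-quality cells (< ``min_genes`` expressed genes), then genes
    expressed in fewer than ``min_cells`` cells.  Batch and cell-type labels
    are subset along with the matrix."""
    if min_genes < 0 or min_cells < 0:
        raise ValueError("min_genes and min_cells must be non-negative")
    out = adata.copy()
    sc.pp.filter_cells(out, min_genes=min_genes)
    if out.n_obs == 0:
        raise ValueError("empty-after-filter: all cells removed")
    sc.pp.filter_genes(out, min_cells=min_cells)
    if out.n_vars == 0:
        raise ValueError("empty-after-filter: all genes removed")
    return out


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalise each cell to ``target_sum`` total counts and
    apply log1p.  Fails on zero-total cells, naming the first offender."""
    totals = np.ravel(_dense(adata.X).sum(axis=1))
    if (totals <= 0).any():
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(
            f"cell {adata.obs_names[bad]!r} (index {bad}) has zero total counts"
        )
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    out.uns["normalized"] = True
    out.uns["target_sum"] = float(target_sum)
    return out


def select_hvgs(
    adata: ad.AnnData,
    n_hvg: int,
    batch_key: str | None = "batch",
) -> ad.AnnData:
    """Keep the ``n_hvg`` most highly variable genes.

    Uses the mean-binned normalised-dispersion criterion.  With ``batch_key``
    set, dispersions are computed within each batch and genes are ranked by
    the number of batches selecting them, ties broken by median normalised
    dispersion; pass ``batch_key=None`` for a joint ranking.
    """
    if not 1 <= n_hvg <= adata.n_vars:
        raise ValueError(f"n_hvg must be in [1, {adata.n_vars}], got {n_hvg}")
    out = adata.copy()
    key = batch_key if (batch_key is not None and batch_key in out.obs) else None
    sc.pp.highly_variable_genes(
        out, n_top_genes=n_hvg, flavor="seurat", batch_key=key
    )
    out = out[:, out.var["highly_variable"].to_numpy()].copy()
    out.uns["n_hvg"] = int(n_hvg)
    return out


def scale_per_batch(
    adata: ad.AnnData, max_value: float = 10.0, batch_key: str = "batch"
) -> ad.AnnData:
    """Z-score each gene within each batch and truncate to ±``max_value``.

    Zero-variance genes become 0 within the affected batch.  A single-cell
    batch has no defined variance: the gene is centred only (divisor 1) and a
    warning is raised.
    """
    out = adata.copy()
    X = _dense(out.X).astype(np.float64)
    batches = np.asarray(out.obs[batch_key])
    for b in np.unique(batches):
        rows = np.flatnonzero(batches == b)
        sub = X[rows]
        mu = sub.mean(axis=0)
        if len(rows) == 1:
            warnings.warn(
                f"batch {b!r} has a single cell; variance undefined, scaling by 1"
            )
            sd = np.ones(sub.shape[1])
        else:
            sd = sub.std(axis=0)
            sd[sd == 0] = 1.0
        X[rows] = (sub - mu) / sd
    np.clip(X, -max_value, max_value, out=X)
    out.X = X
    out.uns["scaled"] = {"max_value": float(max_value), "per_batch": True}
    return out


def pca_embed(
    adata: ad.AnnData, n_pca: int = 100, seed: int = 0, key: str = "X_pca"
) -> np.ndarray:
    """Project onto the first ``n_pca`` principal components.

    Uses a seeded randomized SVD; the result is stored in ``obsm[key]`` and
    returned.  Determinism given the seed is guaranteed, exactness is not.
    """
    max_admissible = min(adata.n_obs - 1, adata.n_vars)
    if n_pca > max_admissible:
        raise ValueError(
            f"n_pca={n_pca} too large; the admissible maximum is {max_admissible}"
        )
    sc.tl.pca(adata, n_comps=n_pca, svd_solver="randomized", random_state=seed)
    coords = np.asarray(adata.obsm["X_pca"], dtype=np.float64)
    adata.obsm[key] = coords
    return coords


def preprocess(
    adata: ad.AnnData,
    *,
    min_genes: int = 10,
    min_cells: int = 3,
    target_sum: float = 1e4,
    n_hvg: int = 1000,
    max_value: float = 10.0,
    n_pca: int = 100,
    batch_key: str = "batch",
    hvg_per_batch: bool = True,
    skip_norm: bool = False,
    seed: int = 0,
) -> ad.AnnData:
    """Run the full preprocessing chain; ``skip_norm=True`` trusts the input
    as already normalised (for inputs shipped log-normalised) and bypasses
    filtering and normalisation."""
    if skip_norm:
        step = adata.copy()
        step.uns["normalized"] = True
    else:
        step = filter_cells_genes(adata, min_genes=min_genes, min_cells=min_cells)
        step = normalize_log(step, target_sum=target_sum)
    n_hvg_eff = min(n_hvg, step.n_vars)
    step = select_hvgs(step, n_hvg_eff, batch_key=batch_key if hvg_per_batch else None)
    step.layers["hvg_lognorm"] = _dense(step.X).copy()
    step = scale_per_batch(step, max_value=max_value, batch_key=batch_key)
    n_pca_eff = min(n_pca, step.n_obs - 1, step.n_vars)
    pca_embed(step, n_pca=n_pca_eff, seed=seed)
    return step
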