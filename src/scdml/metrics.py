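"""Integration-quality metrics.

Six scores quantify how well an embedding separates cell types while mixing
batches:

* ARI, NMI — chance-adjusted and information-theoretic agreement between a
  clustering and the true cell-type partition (sklearn implementations,
  arithmetic-mean NMI normalisation).
* ASW_celltype / ASW_batch — mean silhouette width against cell-type labels
  (higher = purer types) or batch labels (lower = better mixing).  Raw
  silhouette lives in [-1, 1]; the conventional (s + 1) / 2 rescaling to
  [0, 1] is reported alongside it.
* iLISI — mean inverse Simpson's index of batch composition in
  perplexity-calibrated Gaussian neighbourhoods; approaches the number of
  batches under perfect mixing and 1 under complete separation.
* BatchKL — mean KL divergence between the local (k-nearest-neighbour) batch
  proportions of bootstrap-sampled cells and the global proportions; 0 under
  perfect mixing.

All distances are Euclidean in the supplied embedding.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
from sklearn.metrics import (
    adjusted_rand_score,
    normalized_mutual_info_score,
    silhouette_samples,
)
from sklearn.neighbors import NearestNeighbors

__all__ = ["ari", "nmi", "asw", "ilisi", "batchkl", "evaluate", "Silhouette"]


def _check_lengths(a, b):
    a, b = np.asarray(a), np.asarray(b)
    if len(a) != len(b):
        raise ValueError(f"label lengths differ: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least two cells")
    return a, b


def ari(truth, pred) -> float:
    """Adjusted Rand index between two partitions (label-name invariant)."""
    truth, pred = _check_lengths(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def nmi(truth, pred) -> float:
    """Normalised mutual information, arithmetic-mean normalisation."""
    truth, pred = _check_lengths(truth, pred)
    return float(normalized_mutual_info_score(truth, pred, average_method="arithmetic"))


class Silhouette(NamedTuple):
    raw: float      # mean silhouette width in [-1, 1]
    scaled: float   # (raw + 1) / 2, in [0, 1]


def asw(emb: np.ndarray, labels) -> Silhouette:
    """Mean silhouette width of ``labels`` in the embedding.

    Cells in singleton label groups get silhouette 0 (with a warning).
    Returns both the raw value and its [0, 1] rescaling.
    """
    emb = np.asarray(emb, dtype=np.float64)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two label groups")
    if (counts == 1).any():
        warnings.warn("singleton label group(s); their silhouette is set to 0")
    s = silhouette_samples(emb, labels, metric="euclidean")
    raw = float(np.mean(s))
    return Silhouette(raw=raw, scaled=(raw + 1.0) / 2.0)


def ilisi(emb: np.ndarray, batch, perplexity: float = 30.0) -> float:
    """Mean local inverse Simpson's index of the batch labels.

    For each cell, neighbour weights over its 3·perplexity nearest
    neighbours are calibrated (by binary search on the Gaussian bandwidth)
    to the target perplexity; the per-cell score is 1 / sum_b p_b² over the
    batch-summed weights.  With one batch the score is exactly 1.
    """
    emb = np.asarray(emb, dtype=np.float64)
    batch = np.asarray(batch)
    n = len(batch)
    if perplexity >= n:
        raise ValueError("perplexity must be smaller than the cell count")
    codes = np.unique(batch, return_inverse=True)[1]
    n_batches = codes.max() + 1
    if n_batches == 1:
        return 1.0
    k = min(n - 1, int(np.ceil(3 * perplexity)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    log_perp = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        lo, hi = 0.0, np.inf
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * (d2 - d2.min()))
            sw = w.sum()
            p = w / sw
            h = -np.sum(p * np.log(p + 1e-300))  # Shannon entropy
            if abs(h - log_perp) < 1e-5:
                break
            if h > log_perp:  # too flat -> increase beta
                lo = beta
                beta = beta * 2 if not np.isfinite(hi) else (lo + hi) / 2
            else:
                hi = beta
                beta = (lo + hi) / 2
        pb = np.bincount(codes[idx[i]], weights=p, minlength=n_batches)
        scores[i] = 1.0 / np.sum(pb**2)
    return float(scores.mean())


def batchkl(
    emb: np.ndarray,
    batch,
    n_cells_sampled: int = 100,
    k_neighbors: int | None = None,
    n_replicates: int = 100,
    seed: int = 0,
) -> float:
    """Mean KL divergence of local vs. global batch proportions.

    ``n_replicates`` bootstrap draws of ``n_cells_sampled`` cells each; for
    every sampled cell the batch proportions among its k nearest neighbours
    (the cell itself included) are compared to the global proportions with
    KL(local || global), natural log.  k defaults to min(100, n/10).
    """
    emb = np.asarray(emb, dtype=np.float64)
    batch = np.asarray(batch)
    n = len(batch)
    if k_neighbors is None:
        k_neighbors = max(1, min(100, n // 10))
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of cells {n}")
    codes = np.unique(batch, return_inverse=True)[1]
    n_batches = codes.max() + 1
    global_p = np.bincount(codes, minlength=n_batches) / n
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(emb)
    _, idx = nn.kneighbors(emb)  # neighbourhood includes the cell itself
    local_p = np.stack(
        [np.bincount(codes[row], minlength=n_batches) / k_neighbors for row in idx]
    )
    # KL(local || global); 0*log(0) := 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(local_p > 0, local_p * np.log(local_p / global_p), 0.0)
    kl_per_cell = terms.sum(axis=1)
    rng = np.random.default_rng(seed)
    reps = [
        kl_per_cell[rng.choice(n, size=min(n_cells_sampled, n), replace=True)].mean()
        for _ in range(n_replicates)
    ]
    return float(np.mean(reps))


def evaluate(
    emb: np.ndarray,
    celltype,
    batch,
    pred_labels=None,
    perplexity: float = 30.0,
    seed: int = 0,
) -> dict:
    """All six metrics for one embedding; ``pred_labels`` defaults to the
    cell-type labels for the clustering-agreement scores."""
    pred = celltype if pred_labels is None else pred_labels
    asw_ct = asw(emb, celltype)
    asw_b = asw(emb, batch) if len(np.unique(np.asarray(batch))) > 1 else Silhouette(0.0, 0.5)
    return {
        "ari": ari(celltype, pred),
        "nmi": nmi(celltype, pred),
        "asw_celltype": asw_ct.scaled,
        "asw_celltype_raw": asw_ct.raw,
        "asw_batch": asw_b.scaled,
        "asw_batch_raw": asw_b.raw,
        "ilisi": ilisi(emb, batch, perplexity=perplexity),
        "batchkl": batchkl(emb, batch, seed=seed),
    }
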