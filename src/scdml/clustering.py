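"""Graph-based initial clustering on the PCA embedding.

The initial partition is deliberately over-fine (default resolution 3.0):
downstream merging only requires each initial cluster to be *pure* (contained
in one true cell type), never that the cluster count match the type count.
"""

from __future__ import annotations

import random

import anndata as ad
import igraph
import leidenalg
import numpy as np
import scanpy as sc
import scipy.sparse as sp

__all__ = ["cluster_init"]


def _snn_graph(coords: np.ndarray, n_neighbors: int, seed: int) -> igraph.Graph:
    """UMAP-style fuzzy-connectivity graph on Euclidean k-NN in PCA space."""
    carrier = ad.AnnData(np.zeros((coords.shape[0], 1), dtype=np.float32))
    carrier.obsm["X_use"] = np.asarray(coords, dtype=np.float64)
    sc.pp.neighbors(
        carrier, n_neighbors=n_neighbors, use_rep="X_use", random_state=seed
    )
    conn = sp.triu(sp.coo_matrix(carrier.obsp["connectivities"]))
    g = igraph.Graph(
        n=coords.shape[0],
        edges=list(zip(conn.row.tolist(), conn.col.tolist())),
        edge_attrs={"weight": conn.data.tolist()},
    )
    return g


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 0..C-1 by decreasing size (ties: first seen)."""
    ids, counts = np.unique(membership, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[m] for m in membership], dtype=np.int64)


def cluster_init(
    coords: np.ndarray,
    resolution: float = 3.0,
    n_neighbors: int = 15,
    method: str = "louvain",
    seed: int = 0,
) -> np.ndarray:
    """Modularity clustering of cells on an SNN graph built in PCA space.

    Parameters
    ----------
    coords
        (cells, d) PCA coordinates.
    resolution
        Modularity resolution; larger values give more, smaller clusters.
    method
        ``louvain`` (multilevel modularity) or ``leiden``.
    seed
        Seeds both graph construction and community detection; identical
        inputs and seed give identical labels.

    Returns
    -------
    Integer labels 0..C-1, renumbered by decreasing cluster size.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if coords.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, "
            f"got {coords.shape[0]}"
        )
    g = _snn_graph(coords, n_neighbors, seed)
    weights = g.es["weight"] if g.ecount() else None
    if method == "louvain":
        igraph.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights=weights, resolution=float(resolution))
        membership = np.asarray(part.membership)
    elif method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=float(resolution),
            seed=int(seed),
            n_iterations=2,
        )
        membership = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}; use 'louvain' or 'leiden'")
    return _relabel_by_size(membership)
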