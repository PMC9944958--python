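"""End-to-end batch alignment estimator.

``SCDML`` chains the five stages — preprocessing, over-fine initial
clustering, intra-batch KNN / inter-batch MNN pair search, similarity-driven
hierarchical cluster merging, and hard-triplet metric learning — behind a
scikit-learn estimator interface: ``fit`` on a counts matrix (or AnnData)
with per-cell batch labels, then read the corrected 32-d embedding from
``embedding_`` and the merged cluster labels from ``labels_``.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import merge as _merge
from .clustering import cluster_init
from .embed import TripletEmbedder, final_labels
from .neighbors import knn_pairs_intra, mnn_pairs_inter, union_pairs
from .preprocess import preprocess

__all__ = ["SCDML"]


class SCDML(BaseEstimator, ClusterMixin, TransformerMixin):
    """Batch-effect removal by cluster merging and deep metric learning.

    Parameters
    ----------
    n_hvg : int, default 1000
        Highly variable genes retained (also the network input width).
    n_pca : int, default 100
        Principal components for the working embedding (capped by data size).
    resolution : float, default 3.0
        Louvain/Leiden resolution for the deliberately over-fine initial
        clustering.
    init_method : {'louvain', 'leiden'}
    n_neighbors : int, default 15
        Neighbour count of the SNN graph behind the initial clustering.
    k_in : int, default 5
        Within-batch KNN neighbours (cosine distance).
    k_bw : int, default 10
        Between-batch MNN neighbours (cosine distance).
    n_clusters : int or 'auto', default 'auto'
        Merge target.  'auto' uses the largest spectral (eigengap) candidate,
        i.e. the most conservative amount of merging; the full candidate
        list is kept in ``candidates_``.
    hidden_dim, embed_dim, margin, epochs, batch_size, learning_rate
        Triplet network architecture and schedule (see
        :class:`~scdml.embed.TripletEmbedder`).
    skip_norm : bool, default False
        Trust the input as already normalised (skips filtering and
        library-size/log normalisation).
    batch_key : str, default 'batch'
        ``obs`` column holding the batch label when fitting an AnnData.
    final_label_mode : {'reassigned', 'louvain'}, default 'reassigned'
        Whether ``labels_`` are the merged labels or a re-clustering of the
        learned embedding.
    random_state : int, default 0
        Seeds every stochastic stage; fits are reproducible.

    Attributes
    ----------
    adata_ : AnnData of retained cells with all intermediate annotations.
    init_labels_, labels_ : initial and final per-cell cluster labels.
    pair_counts_, sizes_, similarity_ : A matrix, cluster sizes, S matrix.
    candidates_ : spectral candidate cluster numbers (ascending).
    n_clusters_ : merged cluster count actually achieved.
    merge_plan_ : :class:`~scdml.merge.MergePlan` with the event trace.
    embedding_ : (cells, embed_dim) corrected embedding.
    """

    def __init__(
        self,
        n_hvg: int = 1000,
        n_pca: int = 100,
        resolution: float = 3.0,
        init_method: str = "louvain",
        n_neighbors: int = 15,
        k_in: int = 5,
        k_bw: int = 10,
        n_clusters: int | str = "auto",
        hidden_dim: int = 256,
        embed_dim: int = 32,
        margin: float = 0.2,
        epochs: int = 50,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        min_genes: int = 10,
        min_cells: int = 3,
        target_sum: float = 1e4,
        max_scale_value: float = 10.0,
        skip_norm: bool = False,
        hvg_per_batch: bool = True,
        batch_key: str = "batch",
        final_label_mode: str = "reassigned",
        final_resolution: float = 1.0,
        random_state: int = 0,
    ):
        self.n_hvg = n_hvg
        self.n_pca = n_pca
        self.resolution = resolution
        self.init_method = init_method
        self.n_neighbors = n_neighbors
        self.k_in = k_in
        self.k_bw = k_bw
        self.n_clusters = n_clusters
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.margin = margin
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.min_genes = min_genes
        self.min_cells = min_cells
        self.target_sum = target_sum
        self.max_scale_value = max_scale_value
        self.skip_norm = skip_norm
        self.hvg_per_batch = hvg_per_batch
        self.batch_key = batch_key
        self.final_label_mode = final_label_mode
        self.final_resolution = final_resolution
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _as_adata(self, X, batch) -> ad.AnnData:
        if isinstance(X, ad.AnnData):
            adata = X.copy()
            if batch is not None:
                adata.obs[self.batch_key] = np.asarray(batch)
            if self.batch_key not in adata.obs:
                raise ValueError(
                    f"obs[{self.batch_key!r}] missing and no batch argument given"
                )
        else:
            if batch is None:
                raise ValueError("batch labels are required when X is an array")
            X = np.asarray(X)
            adata = ad.AnnData(X=X.astype(np.float32))
            adata.obs[self.batch_key] = np.asarray(batch)
        adata.obs[self.batch_key] = adata.obs[self.batch_key].astype("category")
        return adata

    def fit(self, X, y=None, batch=None):
        """Run the full pipeline.

        ``X`` may be an AnnData (batch read from ``obs[batch_key]``) or a
        cells x genes array with ``batch`` given separately.  ``y`` is
        ignored (kept for sklearn API compatibility).
        """
        adata = self._as_adata(X, batch)
        seed = int(self.random_state)

        # 1) preprocessing -> scaled HVG matrix + PCA embedding
        adata = preprocess(
            adata,
            min_genes=self.min_genes,
            min_cells=self.min_cells,
            target_sum=self.target_sum,
            n_hvg=self.n_hvg,
            max_value=self.max_scale_value,
            n_pca=self.n_pca,
            batch_key=self.batch_key,
            hvg_per_batch=self.hvg_per_batch,
            skip_norm=self.skip_norm,
            seed=seed,
        )
        pca = np.asarray(adata.obsm["X_pca"])
        batches = np.asarray(adata.obs[self.batch_key])

        # 2) over-fine initial clustering
        init = cluster_init(
            pca,
            resolution=self.resolution,
            n_neighbors=self.n_neighbors,
            method=self.init_method,
            seed=seed,
        )
        adata.obs["init_cluster"] = init

        # 3) NN pairs
        intra = knn_pairs_intra(pca, batches, k_in=self.k_in)
        inter = mnn_pairs_inter(pca, batches, k_bw=self.k_bw)
        all_pairs = union_pairs(intra, inter)

        # 4) similarity + merge
        A, sizes = _merge.count_pairs(all_pairs.pairs, init)
        S = _merge.similarity_from_counts(A, sizes)
        self.candidates_ = _merge.infer_n_clusters(S)
        if self.n_clusters == "auto":
            target = int(self.candidates_[-1])
        else:
            target = int(self.n_clusters)
            if target > A.shape[0]:
                warnings.warn(
                    f"n_clusters={target} exceeds the {A.shape[0]} initial "
                    "clusters; no merging performed"
                )
                target = A.shape[0]
        plan = _merge.merge_clusters(A, sizes, target)
        merged = _merge.reassign_labels(plan, init)
        adata.obs["merged_cluster"] = merged

        # 5) triplet metric learning on the scaled HVG matrix
        Z = np.asarray(adata.X, dtype=np.float64)
        embedder = TripletEmbedder(
            hidden_dim=self.hidden_dim,
            embed_dim=self.embed_dim,
            margin=self.margin,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            random_state=seed,
        )
        emb = embedder.fit(Z, merged).transform(Z)
        adata.obsm["X_scdml"] = emb

        labels = final_labels(
            emb,
            merged,
            mode=self.final_label_mode,
            resolution=self.final_resolution,
            n_neighbors=self.n_neighbors,
            seed=seed,
        )
        adata.obs["scdml_cluster"] = labels

        self.adata_ = adata
        self.init_labels_ = init
        self.pairs_intra_ = intra
        self.pairs_inter_ = inter
        self.pair_counts_ = A
        self.sizes_ = sizes
        self.similarity_ = S
        self.merge_plan_ = plan
        self.merged_labels_ = merged
        self.n_clusters_ = int(plan.n_clusters)
        self.embedder_ = embedder
        self.embedding_ = emb
        self.labels_ = labels
        self.loss_history_ = embedder.loss_history_
        return self

    def fit_transform(self, X, y=None, batch=None) -> np.ndarray:
        """Fit and return the corrected embedding of the retained cells."""
        return self.fit(X, y=y, batch=batch).embedding_

    def transform(self, X) -> np.ndarray:
        """Map already scaled HVG-space rows through the learned network.

        ``X`` must live in the same scaled HVG space the network was trained
        on (``adata_.X``); use ``fit_transform`` for raw inputs.
        """
        check_is_fitted(self, "embedder_")
        return self.embedder_.transform(np.asarray(X, dtype=np.float64))
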