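"""Deep metric learning with hard-triplet mining.

A triplet (a, p, n) takes an anchor a, a positive p with the same cluster
label, and a negative n with a different label.  With Euclidean distances
d_ap = d(a, p) and d_an = d(a, n) and margin m, the loss is

    L = max(d_ap - d_an + m, 0)

and triplets fall into three categories:

* easy:      d_ap + m < d_an  (zero loss);
* semi-hard: d_ap < d_an < d_ap + m;
* hard:      d_an < d_ap  (the negative is closer than the positive).

Only hard triplets are used for training (mining all semi-hard triplets is
far more expensive and is not needed for convergence here).  The embedding
network is a small multilayer perceptron (input -> 256 ReLU -> 32 linear)
trained with Adam on the mean loss over all hard triplets mined in each
mini-batch; it is implemented directly in numpy with analytic gradients,
which keeps training bit-reproducible for a given seed.  Batch labels are
never shown to the trainer: batch information enters only through the merged
cluster labels.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "triplet_loss",
    "classify_triplet",
    "mine_hard_triplets",
    "TripletEmbedder",
    "final_labels",
]

_EPS = 1e-12


def triplet_loss(d_ap, d_an, margin: float = 0.2):
    """Hinge triplet loss max(d_ap - d_an + margin, 0); accepts arrays."""
    d_ap = np.asarray(d_ap, dtype=np.float64)
    d_an = np.asarray(d_an, dtype=np.float64)
    if (d_ap < 0).any() or (d_an < 0).any():
        raise ValueError("distances must be non-negative")
    out = np.maximum(d_ap - d_an + margin, 0.0)
    return float(out) if out.ndim == 0 else out


def classify_triplet(d_ap: float, d_an: float, margin: float = 0.2) -> str:
    """Triplet category from its two distances.

    Boundary ties (d_an == d_ap or d_an == d_ap + margin) are assigned
    ``semi_hard``.
    """
    if d_ap < 0 or d_an < 0:
        raise ValueError("distances must be non-negative")
    if d_ap + margin < d_an:
        return "easy"
    if d_an < d_ap:
        return "hard"
    return "semi_hard"


def _pairwise_euclid(E: np.ndarray) -> np.ndarray:
    sq = np.sum(E * E, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (E @ E.T)
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def _hard_mask(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Boolean tensor cond[a, p, n]: (a,p,n) is a hard triplet."""
    same = labels[:, None] == labels[None, :]
    pos = same.copy()
    np.fill_diagonal(pos, False)
    neg = ~same
    return pos[:, :, None] & neg[:, None, :] & (D[:, None, :] < D[:, :, None])


def mine_hard_triplets(
    emb: np.ndarray, labels: np.ndarray, minibatch: np.ndarray | None = None
) -> np.ndarray:
    """All hard triplets (a, p, n) within a mini-batch under current distances.

    Returns an (m, 3) array of cell indices (into the full data).  A
    mini-batch containing a single label yields an empty list with a warning.
    """
    emb = np.asarray(emb, dtype=np.float64)
    labels = np.asarray(labels)
    idx = np.arange(len(labels)) if minibatch is None else np.asarray(minibatch)
    sub_lab = labels[idx]
    if len(np.unique(sub_lab)) < 2:
        warnings.warn("mini-batch contains a single label; no triplets mineable")
        return np.empty((0, 3), dtype=np.int64)
    D = _pairwise_euclid(emb[idx])
    cond = _hard_mask(D, sub_lab)
    a, p, n = np.nonzero(cond)
    return np.column_stack([idx[a], idx[p], idx[n]]).astype(np.int64)


def _balanced_batches(
    labels: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Label-interleaved mini-batches so hard triplets stay mineable.

    Cells are shuffled within each label, then drawn round-robin across
    labels into one stream that is chunked into consecutive batches; each
    batch therefore mixes as many labels as the data allows.
    """
    by_label = [rng.permutation(np.flatnonzero(labels == c))
                for c in np.unique(labels)]
    order = rng.permutation(len(by_label))
    stream: list[int] = []
    pos = 0
    while any(len(g) > pos for g in by_label):
        for gi in order:
            g = by_label[gi]
            if pos < len(g):
                stream.append(int(g[pos]))
        pos += 1
    stream_arr = np.asarray(stream, dtype=np.int64)
    return [stream_arr[s : s + batch_size] for s in range(0, len(stream_arr), batch_size)]


class TripletEmbedder(BaseEstimator, TransformerMixin):
    """Batch-corrected low-dimensional embedding via hard-triplet learning.

    Fit on the scaled HVG matrix ``X`` with per-cell merged cluster labels
    ``y``; ``transform`` maps expression rows through the learned MLP into
    the ``embed_dim``-dimensional space in which same-cluster cells are
    pulled together and different clusters pushed apart.

    Parameters
    ----------
    hidden_dim, embed_dim : int
        MLP layer widths (input -> hidden ReLU -> embed linear).
    margin : float
        Triplet margin m.
    epochs, batch_size, learning_rate : training schedule (Adam).
    random_state : int
        Seeds weight init and batch sampling; training is bit-reproducible.

    Attributes
    ----------
    W1_, b1_, W2_, b2_ : learned weights.
    loss_history_ : list of dicts with per-epoch ``mean_loss`` and
        ``n_hard_triplets``.
    """

    def __init__(
        self,
        hidden_dim: int = 256,
        embed_dim: int = 32,
        margin: float = 0.2,
        epochs: int = 50,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        random_state: int = 0,
    ):
        self.hidden_dim = hidden_dim
        self.embed_dim = embed_dim
        self.margin = margin
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if np.unique(y).size < 2:
            raise ValueError("need at least two distinct labels to form triplets")
        singles = [c for c in np.unique(y) if np.sum(y == c) == 1]
        if singles:
            warnings.warn(
                f"labels {singles} have a single cell; they can only serve as negatives"
            )
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / p), size=(p, self.hidden_dim)),
            "b1": np.zeros(self.hidden_dim),
            "W2": rng.normal(0.0, np.sqrt(1.0 / self.hidden_dim),
                             size=(self.hidden_dim, self.embed_dim)),
            "b2": np.zeros(self.embed_dim),
        }
        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            losses, counts = [], 0
            for batch_idx in _balanced_batches(y, self.batch_size, rng):
                lab = y[batch_idx]
                if np.unique(lab).size < 2:
                    continue
                Xb = X[batch_idx]
                H = np.maximum(Xb @ params["W1"] + params["b1"], 0.0)
                E = H @ params["W2"] + params["b2"]
                D = _pairwise_euclid(E)
                cond = _hard_mask(D, lab)
                n_trip = int(cond.sum())
                if n_trip == 0:
                    losses.append(0.0)
                    continue
                # mean loss over all mined hard triplets:
                #   L = mean( D[a,p] - D[a,n] + m )  (all positive: hard => loss >= m)
                coef_pos = cond.sum(axis=2).astype(np.float64)  # counts of (a,p)
                coef_neg = cond.sum(axis=1).astype(np.float64)  # counts of (a,n)
                loss = (
                    float((coef_pos * D).sum() - (coef_neg * D).sum()) / n_trip
                    + self.margin
                )
                losses.append(loss)
                counts += n_trip
                # dL/dD as usage-weighted coefficients, then chain through
                # D[a,j] = ||E_a - E_j||
                G = (coef_pos - coef_neg) / n_trip
                Wd = G / (D + _EPS)
                np.fill_diagonal(Wd, 0.0)
                Wsym = Wd + Wd.T
                dE = Wsym.sum(axis=1)[:, None] * E - Wsym @ E
                dW2 = H.T @ dE
                db2 = dE.sum(axis=0)
                dH = (dE @ params["W2"].T) * (H > 0)
                dW1 = Xb.T @ dH
                db1 = dH.sum(axis=0)
                grads = {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}
                step += 1
                for k in params:
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                    m_hat = adam_m[k] / (1 - beta1**step)
                    v_hat = adam_v[k] / (1 - beta2**step)
                    params[k] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_history_.append(
                {"epoch": _epoch, "mean_loss": float(np.mean(losses)) if losses else 0.0,
                 "n_hard_triplets": counts}
            )
        self.W1_, self.b1_ = params["W1"], params["b1"]
        self.W2_, self.b2_ = params["W2"], params["b2"]
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=np.float64)
        H = np.maximum(X @ self.W1_ + self.b1_, 0.0)
        return H @ self.W2_ + self.b2_


def final_labels(
    emb: np.ndarray,
    merged: np.ndarray,
    mode: str = "reassigned",
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Final per-cell labels: the reassigned merged labels (default), or a
    fresh Louvain clustering of the learned embedding."""
    if mode == "reassigned":
        return np.asarray(merged, dtype=np.int64).copy()
    if mode == "louvain":
        from .clustering import cluster_init

        return cluster_init(
            emb, resolution=resolution, n_neighbors=n_neighbors,
            method="louvain", seed=seed,
        )
    raise ValueError(f"unknown mode {mode!r}")
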