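"""Nearest-neighbour pair discovery in the PCA embedding.

Two pair families drive cluster merging, both under cosine distance:

* intra-batch KNN pairs — cells i, j of the same batch are paired when
  *either* is among the other's ``k_in`` nearest within-batch neighbours
  (a symmetrised, not mutual, KNN graph);
* inter-batch MNN pairs — cells of different batches are paired only when
  *each* is among the other's ``k_bw`` nearest cross-batch neighbours.

Following the counting convention used downstream, (i, j) and (j, i) are kept
as two distinct ordered pairs; every pair set is closed under swapping.
Distance ties rank the lower cell index first, which makes brute-force
comparison exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["NNPairSet", "knn_pairs_intra", "mnn_pairs_inter", "union_pairs"]

# exact search below this cell count; approximate (pynndescent) above
EXACT_SEARCH_MAX_CELLS = 50_000


@dataclass
class NNPairSet:
    """Ordered cell-index pairs tagged by family.

    ``pairs`` is an (m, 2) integer array closed under swapping; ``kind`` is
    one of ``intra``, ``inter``, ``all``.
    """

    pairs: np.ndarray
    kind: str
    k: int = 0
    metric: str = "cosine"

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        if len(p):
            p = np.unique(p, axis=0)
            if (p[:, 0] == p[:, 1]).any():
                raise ValueError("self pairs (i, i) are not allowed")
        self.pairs = p

    def __len__(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.pairs.tolist()))


def _normalize_rows(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    norms = np.linalg.norm(coords, axis=1)
    if (norms == 0).any():
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(
            f"cell {bad} has a zero embedding vector; cosine distance undefined"
        )
    return coords / norms[:, None]


def _topk_by_cosine(
    queries: np.ndarray, targets: np.ndarray, target_ids: np.ndarray, k: int
) -> np.ndarray:
    """Indices (into ``target_ids``) of the k nearest targets per query row.

    Inputs must be row-normalised.  Ties in distance prefer the lower global
    cell index.  Rows of ``queries`` that also appear in ``targets`` must be
    excluded by the caller via ``exclude`` masking beforehand.
    """
    d = 1.0 - queries @ targets.T
    # lexsort: primary key distance, secondary key global index
    order = np.lexsort((np.broadcast_to(target_ids, d.shape), d), axis=1)
    return order[:, :k]


def _symmetric_closure(pairs: list[tuple[int, int]]) -> np.ndarray:
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.asarray(pairs, dtype=np.int64)
    both = np.vstack([arr, arr[:, ::-1]])
    return np.unique(both, axis=0)


def knn_pairs_intra(
    coords: np.ndarray, batch: np.ndarray, k_in: int = 5
) -> NNPairSet:
    """Symmetrised within-batch KNN pairs under cosine distance.

    A batch with fewer than ``k_in + 1`` cells has its k reduced (with a
    warning); single-cell batches contribute no pairs.
    """
    if k_in < 1:
        raise ValueError("k_in must be >= 1")
    X = _normalize_rows(coords)
    batch = np.asarray(batch)
    pairs: list[tuple[int, int]] = []
    for b in np.unique(batch):
        idx = np.flatnonzero(batch == b)
        n_b = len(idx)
        if n_b == 1:
            continue
        k = k_in
        if n_b < k_in + 1:
            k = n_b - 1
            warnings.warn(
                f"batch {b!r} has {n_b} cells < k_in+1; using k={k}"
            )
        sub = X[idx]
        if n_b <= EXACT_SEARCH_MAX_CELLS:
            d = 1.0 - sub @ sub.T
            np.fill_diagonal(d, np.inf)
            order = np.lexsort((np.broadcast_to(idx, d.shape), d), axis=1)
            nn = order[:, :k]
        else:  # pragma: no cover - large-data path
            import pynndescent

            index = pynndescent.NNDescent(sub, metric="cosine", n_neighbors=k + 1)
            nn = index.neighbor_graph[0][:, 1 : k + 1]
        for local_i in range(n_b):
            gi = int(idx[local_i])
            for local_j in nn[local_i]:
                pairs.append((gi, int(idx[local_j])))
    return NNPairSet(_symmetric_closure(pairs), kind="intra", k=k_in)


def mnn_pairs_inter(
    coords: np.ndarray, batch: np.ndarray, k_bw: int = 10
) -> NNPairSet:
    """Mutual nearest-neighbour pairs between every pair of batches.

    With a single batch the result is empty (warning, not an error)."""
    if k_bw < 1:
        raise ValueError("k_bw must be >= 1")
    X = _normalize_rows(coords)
    batch = np.asarray(batch)
    levels = np.unique(batch)
    if len(levels) < 2:
        warnings.warn("fewer than two batches; no inter-batch pairs")
        return NNPairSet(np.empty((0, 2), dtype=np.int64), kind="inter", k=k_bw)
    pairs: list[tuple[int, int]] = []
    for ai in range(len(levels)):
        for bi in range(ai + 1, len(levels)):
            ia = np.flatnonzero(batch == levels[ai])
            ib = np.flatnonzero(batch == levels[bi])
            ka = min(k_bw, len(ib))
            kb = min(k_bw, len(ia))
            # neighbours of each a-cell within batch b, and vice versa
            nn_ab = _topk_by_cosine(X[ia], X[ib], ib, ka)
            nn_ba = _topk_by_cosine(X[ib], X[ia], ia, kb)
            in_ab = np.zeros((len(ia), len(ib)), dtype=bool)
            in_ab[np.repeat(np.arange(len(ia)), ka), nn_ab.ravel()] = True
            in_ba = np.zeros((len(ib), len(ia)), dtype=bool)
            in_ba[np.repeat(np.arange(len(ib)), kb), nn_ba.ravel()] = True
            mutual = in_ab & in_ba.T
            for li, lj in zip(*np.nonzero(mutual)):
                pairs.append((int(ia[li]), int(ib[lj])))
    return NNPairSet(_symmetric_closure(pairs), kind="inter", k=k_bw)


def union_pairs(intra: NNPairSet, inter: NNPairSet) -> NNPairSet:
    """All NN pairs of the dataset: the union of the two families."""
    merged = np.vstack([intra.pairs, inter.pairs])
    return NNPairSet(merged, kind="all", k=0)
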