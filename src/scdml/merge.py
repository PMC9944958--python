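"""Cluster similarity, cluster-number inference, and hierarchical merging.

From the ordered NN pairs and the initial partition we count, for every pair
of clusters (i, j), the ordered pairs crossing them (a_ij; within-cluster
pairs are discarded, so diag(A) = 0) and normalise by the smaller cluster
size:

    s_ij = a_ij / min(m_i, m_j)

Merging is greedy agglomeration on S: at each step the currently most
similar pair of clusters is joined, counts are pooled
(a_wk = a_uk + a_vk, m_w = m_u + m_v) and similarities recomputed.  Each
accepted merge is an edge of an undirected graph over the initial cluster
ids; final labels are the connected components of that graph.  The pooled
recomputation rule is a reconstruction consistent with re-evaluating the
similarity on the coarser partition (see docs/methods.md).

Candidate cluster numbers are proposed from the eigenvalue spectrum of the
symmetrically normalised similarity matrix (eigengap heuristic, in the
spirit of self-tuning spectral clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "count_pairs",
    "similarity_from_counts",
    "infer_n_clusters",
    "merge_clusters",
    "reassign_labels",
    "MergePlan",
]


def count_pairs(pairs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ordered NN-pair counts between clusters.

    Returns ``(A, sizes)`` where ``A[i, j]`` is the number of ordered pairs
    (x, y) with label(x)=i, label(y)=j for i != j (within-cluster pairs are
    dropped), and ``sizes[i]`` is the number of cells in cluster i.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min(initial=0) < 0:
        raise ValueError("labels must be non-negative integers")
    C = int(labels.max()) + 1 if len(labels) else 0
    sizes = np.bincount(labels, minlength=C)
    A = np.zeros((C, C), dtype=np.int64)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs):
        li = labels[pairs[:, 0]]
        lj = labels[pairs[:, 1]]
        keep = li != lj
        np.add.at(A, (li[keep], lj[keep]), 1)
    return A, sizes


def similarity_from_counts(A: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Size-normalised similarity s_ij = a_ij / min(m_i, m_j), zero diagonal."""
    A = np.asarray(A, dtype=np.float64)
    sizes = np.asarray(sizes, dtype=np.float64)
    if (sizes < 1).any():
        raise ValueError("all cluster sizes must be >= 1")
    S = A / np.minimum.outer(sizes, sizes)
    np.fill_diagonal(S, 0.0)
    return S


def infer_n_clusters(S: np.ndarray, n_sd: float = 2.0) -> list[int]:
    """Candidate cluster numbers from the eigengap of the normalised similarity.

    Builds W = D^{-1/2} ((S + S^T)/2) D^{-1/2} with D the row sums (plus a
    tiny epsilon), takes eigenvalues in descending order, and proposes every
    K whose gap lambda_K - lambda_{K+1} exceeds mean(gaps) + ``n_sd``·sd, as
    well as the global max-gap K.  Returns a non-empty ascending list.
    All-zero S carries no merge evidence and yields ``[C]`` with a warning.
    """
    S = np.asarray(S, dtype=np.float64)
    C = S.shape[0]
    if C < 2:
        raise ValueError("need at least two clusters")
    Ssym = (S + S.T) / 2.0
    if Ssym.max() == 0:
        warnings.warn("similarity matrix is all zero; no evidence to merge")
        return [C]
    d = Ssym.sum(axis=1) + 1e-12
    inv_sqrt = 1.0 / np.sqrt(d)
    W = inv_sqrt[:, None] * Ssym * inv_sqrt[None, :]
    lam = np.sort(np.linalg.eigvalsh(W))[::-1]
    gaps = lam[:-1] - lam[1:]  # gaps[K-1] = lambda_K - lambda_{K+1}
    thresh = gaps.mean() + n_sd * gaps.std()
    cand = set(int(k) for k in (np.flatnonzero(gaps > thresh) + 1))
    cand.add(int(np.argmax(gaps)) + 1)
    return sorted(cand)


@dataclass
class MergePlan:
    """Record of a greedy agglomeration over initial clusters.

    ``events`` lists (u, v, similarity) in merge order, with u and v the
    smallest original ids of the two merged groups; ``edges`` are the
    accepted merge edges; ``components`` partitions the original cluster ids;
    ``label_map`` sends each original id to its merged id (0..K-1, ordered by
    smallest member id).
    """

    n_initial: int
    events: list[tuple[int, int, float]] = field(default_factory=list)
    edges: list[tuple[int, int]] = field(default_factory=list)
    components: list[list[int]] = field(default_factory=list)
    label_map: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    n_clusters: int = 0


def _components_from_edges(C: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(C))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[max(ru, rv)] = min(ru, rv)
    groups: dict[int, list[int]] = {}
    for i in range(C):
        groups.setdefault(find(i), []).append(i)
    return [sorted(groups[r]) for r in sorted(groups)]


def merge_clusters(A: np.ndarray, sizes: np.ndarray, target_k: int) -> MergePlan:
    """Greedily merge the most similar cluster pair until ``target_k`` remain.

    Ties in the argmax break on the lexicographically smallest (i, j).  If
    every remaining similarity is 0 before ``target_k`` is reached, merging
    stops early with a warning and the achieved count is returned.
    """
    A = np.asarray(A, dtype=np.float64).copy()
    sizes = np.asarray(sizes, dtype=np.float64).copy()
    C = A.shape[0]
    if not 1 <= target_k <= C:
        raise ValueError(f"target_k must be in [1, {C}], got {target_k}")
    plan = MergePlan(n_initial=C)
    active = np.ones(C, dtype=bool)
    for _ in range(C - target_k):
        S = similarity_from_counts(A, np.maximum(sizes, 1.0))
        S[~active, :] = -np.inf
        S[:, ~active] = -np.inf
        np.fill_diagonal(S, -np.inf)
        best = np.max(S)
        if best <= 0:
            warnings.warn(
                "all remaining similarities are zero; stopping early at "
                f"{int(active.sum())} clusters"
            )
            break
        flat = np.flatnonzero(S == best)  # row-major => lexicographic order
        u, v = divmod(int(flat[0]), C)
        if u > v:
            u, v = v, u
        plan.events.append((u, v, float(best)))
        plan.edges.append((u, v))
        A[u, :] += A[v, :]
        A[:, u] += A[:, v]
        A[u, u] = 0.0
        A[v, :] = 0.0
        A[:, v] = 0.0
        sizes[u] += sizes[v]
        sizes[v] = 0.0
        active[v] = False
    plan.components = _components_from_edges(C, plan.edges)
    plan.n_clusters = len(plan.components)
    label_map = np.empty(C, dtype=np.int64)
    for new_id, comp in enumerate(sorted(plan.components, key=lambda c: c[0])):
        for orig in comp:
            label_map[orig] = new_id
    plan.label_map = label_map
    return plan


def reassign_labels(plan: MergePlan, init_labels: np.ndarray) -> np.ndarray:
    """Per-cell merged labels via the plan's connected components."""
    init_labels = np.asarray(init_labels, dtype=np.int64)
    if init_labels.max(initial=-1) >= plan.n_initial:
        raise ValueError("labels reference clusters outside the plan")
    return plan.label_map[init_labels]
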