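import numpy as np
import pytest

from scdml.merge import (
    count_pairs,
    infer_n_clusters,
    merge_clusters,
    reassign_labels,
    similarity_from_counts,
)


# ---------------------------------------------------------------- oracles
def oracle_count(pairs, labels):
    C = labels.max() + 1
    A = np.zeros((C, C), dtype=int)
    for x, y in pairs:
        if labels[x] != labels[y]:
            A[labels[x], labels[y]] += 1
    return A


def oracle_greedy(A, sizes, target_k):
    """Independent dict-based greedy agglomeration with the pooled-count
    recomputation rule and lexicographic tie-breaks."""
    groups = {i: {"a": dict(enumerate(row)), "m": sizes[i], "min_id": i}
              for i, row in enumerate(np.asarray(A, dtype=float))}
    events = []
    while len(groups) > target_k:
        best, arg = -np.inf, None
        for u in sorted(groups):
            for v in sorted(groups):
                if u >= v:
                    continue
                s = groups[u]["a"].get(v, 0.0) / min(groups[u]["m"], groups[v]["m"])
                if s > best + 1e-15:
                    best, arg = s, (u, v)
        if best <= 0:
            break
        u, v = arg
        events.append((groups[u]["min_id"], groups[v]["min_id"], best))
        gu, gv = groups.pop(u), groups.pop(v)
        merged_a = {}
        for k in set(gu["a"]) | set(gv["a"]):
            if k not in (u, v):
                merged_a[k] = gu["a"].get(k, 0.0) + gv["a"].get(k, 0.0)
        new = {"a": merged_a, "m": gu["m"] + gv["m"],
               "min_id": min(gu["min_id"], gv["min_id"])}
        key = min(u, v)
        groups[key] = new
        for g in groups.values():
            if g is not new:
                pooled = g["a"].get(u, 0.0) + g["a"].get(v, 0.0)
                g["a"].pop(u, None)
                g["a"].pop(v, None)
                g["a"][key] = pooled
    return events


def oracle_union_find(C, edges, labels):
    parent = list(range(C))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru
    roots = sorted({find(i) for i in range(C)}, key=lambda r: min(
        i for i in range(C) if find(i) == r))
    remap = {}
    for new, r in enumerate(sorted(roots, key=lambda r: min(
            i for i in range(C) if find(i) == r))):
        remap[r] = new
    return np.array([remap[find(labels[c])] for c in range(len(labels))])


# ---------------------------------------------------------------- count_pairs
class TestCountPairs:
    def test_ordered_pairs_counted(self):
        labels = np.array([0, 1])
        A, sizes = count_pairs(np.array([[0, 1], [1, 0]]), labels)
        assert A[0, 1] == A[1, 0] == 1  # one ordered pair each way
        assert A[0, 0] == A[1, 1] == 0
        assert list(sizes) == [1, 1]

    def test_within_cluster_pairs_dropped(self):
        labels = np.zeros(4, dtype=int)
        A, _ = count_pairs(np.array([[0, 1], [1, 0], [2, 3], [3, 2]]), labels)
        assert not A.any()

    def test_matches_bruteforce_recount(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 8, size=100)
        raw = rng.integers(0, 100, size=(400, 2))
        raw = raw[raw[:, 0] != raw[:, 1]]
        pairs = np.unique(np.vstack([raw, raw[:, ::-1]]), axis=0)
        A, sizes = count_pairs(pairs, labels)
        assert np.array_equal(A, oracle_count(pairs, labels))
        assert np.array_equal(sizes, np.bincount(labels))
        assert np.array_equal(A, A.T)


# ---------------------------------------------------------------- similarity
class TestSimilarity:
    def test_arithmetic(self):
        A = np.array([[0, 4], [4, 0]])
        S = similarity_from_counts(A, np.array([2, 4]))
        assert S[0, 1] == S[1, 0] == 2.0

    def test_zero_counts_zero_similarity(self):
        S = similarity_from_counts(np.zeros((3, 3)), np.array([1, 2, 3]))
        assert not S.any()

    def test_homogeneity_in_min_size(self):
        A = np.array([[0, 6], [6, 0]])
        s1 = similarity_from_counts(A, np.array([3, 5]))[0, 1]
        s2 = similarity_from_counts(A, np.array([6, 10]))[0, 1]
        assert s2 == pytest.approx(s1 / 2)

    def test_zero_size_cluster_fails(self):
        with pytest.raises(ValueError, match="sizes"):
            similarity_from_counts(np.zeros((2, 2)), np.array([0, 3]))

    def test_exactness_from_exported_counts(self):
        """S recomputed from A and sizes matches to machine precision."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            C = rng.integers(3, 12)
            A = rng.integers(0, 50, size=(C, C))
            A = A + A.T
            np.fill_diagonal(A, 0)
            sizes = rng.integers(1, 40, size=C)
            S = similarity_from_counts(A, sizes)
            expected = np.array(
                [[A[i, j] / min(sizes[i], sizes[j]) if i != j else 0.0
                  for j in range(C)] for i in range(C)]
            )
            assert np.array_equal(S, expected)


# ---------------------------------------------------------------- eigengap
class TestInferNClusters:
    def _block_S(self, rng, block_sizes, noise=0.0):
        C = sum(block_sizes)
        S = np.zeros((C, C))
        start = 0
        for bs in block_sizes:
            blk = rng.uniform(5.0, 10.0, size=(bs, bs))
            S[start:start + bs, start:start + bs] = (blk + blk.T) / 2
            start += bs
        if noise:
            off = rng.uniform(0, noise, size=(C, C))
            off = (off + off.T) / 2
            S = S + off
        np.fill_diagonal(S, 0.0)
        return S

    def test_two_clean_blocks(self):
        S = self._block_S(np.random.default_rng(2), [4, 4])
        assert 2 in infer_n_clusters(S)

    def test_three_blocks_with_weak_noise(self):
        rng = np.random.default_rng(3)
        S = self._block_S(rng, [5, 4, 6], noise=0.05)  # off-block < 1% of in-block
        assert 3 in infer_n_clusters(S)

    def test_all_zero_returns_C_with_warning(self):
        with pytest.warns(UserWarning, match="no evidence"):
            assert infer_n_clusters(np.zeros((7, 7))) == [7]

    def test_candidates_ascending_nonempty(self):
        rng = np.random.default_rng(4)
        S = self._block_S(rng, [3, 3, 3], noise=0.5)
        cands = infer_n_clusters(S)
        assert cands and cands == sorted(cands)


# ---------------------------------------------------------------- merging
class TestMergeClusters:
    def test_no_merge_when_target_equals_C(self):
        A = np.array([[0, 3], [3, 0]])
        plan = merge_clusters(A, np.array([2, 2]), target_k=2)
        assert plan.events == [] and plan.edges == []
        assert np.array_equal(plan.label_map, [0, 1])

    def test_unique_maximum_single_merge(self):
        # clusters 0,1 strongly linked; 2 weakly linked to 0
        A = np.array([[0, 10, 1], [10, 0, 0], [1, 0, 0]])
        sizes = np.array([2, 2, 10])
        plan = merge_clusters(A, sizes, target_k=2)
        assert len(plan.events) == 1
        u, v, s = plan.events[0]
        assert (u, v) == (0, 1) and s == pytest.approx(5.0)
        assert sorted(map(tuple, plan.components)) == [(0, 1), (2,)]

    def test_nested_structure_merges_tight_pairs_first(self):
        # two tight pairs (0,1) and (2,3) with weak cross links
        A = np.array(
            [[0, 20, 2, 1],
             [20, 0, 1, 2],
             [2, 1, 0, 18],
             [1, 2, 18, 0]]
        )
        sizes = np.array([4, 4, 4, 4])
        plan = merge_clusters(A, sizes, target_k=2)
        first_two = {tuple(sorted(e[:2])) for e in plan.events[:2]}
        assert first_two == {(0, 1), (2, 3)}

    @pytest.mark.parametrize("seed", range(8))
    def test_event_order_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        C = int(rng.integers(4, 12))
        A = rng.integers(0, 30, size=(C, C))
        A = A + A.T
        np.fill_diagonal(A, 0)
        sizes = rng.integers(1, 25, size=C)
        target = int(rng.integers(1, C))
        plan = merge_clusters(A, sizes, target)
        expected = oracle_greedy(A, sizes, target)
        assert len(plan.events) == len(expected)
        for got, exp in zip(plan.events, expected):
            assert tuple(sorted(got[:2])) == tuple(sorted(exp[:2]))
            assert got[2] == pytest.approx(exp[2])

    def test_early_stop_on_zero_similarity(self):
        A = np.array([[0, 5, 0], [5, 0, 0], [0, 0, 0]])  # cluster 2 isolated
        with pytest.warns(UserWarning, match="stopping early"):
            plan = merge_clusters(A, np.array([2, 2, 2]), target_k=1)
        assert plan.n_clusters == 2

    def test_rare_batch_unique_cluster_never_absorbed(self):
        """A cluster with zero NN pairs to every other cluster stays its own
        component for any target at or above the true type count."""
        rng = np.random.default_rng(9)
        C = 8
        A = rng.integers(1, 30, size=(C, C))
        A = A + A.T
        A[3, :] = 0
        A[:, 3] = 0  # cluster 3 isolated (batch-unique type)
        np.fill_diagonal(A, 0)
        sizes = rng.integers(1, 20, size=C)
        for target in range(2, C + 1):
            plan = merge_clusters(A, sizes, target)
            assert [3] in plan.components


# ---------------------------------------------------------------- reassign
class TestReassign:
    def test_single_edge(self):
        plan = merge_clusters(
            np.array([[0, 9, 0], [9, 0, 0], [0, 0, 0]]), np.array([1, 1, 1]), 2
        )
        labels = reassign_labels(plan, np.array([0, 1, 2, 2]))
        assert labels[0] == labels[1] != labels[2]

    def test_empty_plan_is_identity_up_to_renumbering(self):
        plan = merge_clusters(np.zeros((3, 3)), np.ones(3), 3)
        init = np.array([2, 0, 1, 0])
        assert np.array_equal(reassign_labels(plan, init), init)

    def test_matches_union_find_oracle_on_random_plan(self):
        rng = np.random.default_rng(10)
        C = 50
        A = rng.integers(0, 5, size=(C, C))
        A = A + A.T
        np.fill_diagonal(A, 0)
        sizes = rng.integers(1, 10, size=C)
        plan = merge_clusters(A, sizes, target_k=12)
        init = rng.integers(0, C, size=400)
        got = reassign_labels(plan, init)
        exp = oracle_union_find(C, plan.edges, init)
        assert np.array_equal(got, exp)


# ---------------------------------------------------------------- properties
from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_count_and_similarity_symmetry(seed):
    """Symmetric pair sets always give symmetric A and S with zero diagonal
    and sizes summing to the cell count."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    labels = rng.integers(0, rng.integers(2, 8), size=n)
    raw = rng.integers(0, n, size=(n * 2, 2))
    raw = raw[raw[:, 0] != raw[:, 1]]
    pairs = np.unique(np.vstack([raw, raw[:, ::-1]]), axis=0) if len(raw) else raw
    A, sizes = count_pairs(pairs, labels)
    assert np.array_equal(A, A.T)
    assert not np.diag(A).any()
    assert sizes.sum() == n
    S = similarity_from_counts(A, np.maximum(sizes, 1))
    assert np.array_equal(S, S.T)
    assert not np.diag(S).any()
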