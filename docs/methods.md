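# Methods

This note documents the model, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
decisions made where the design was genuinely open.

## Pipeline and assumptions

The method assumes the data have *categorical* structure — discrete cell
types, possibly hierarchically organised — rather than continuous
differentiation trajectories; merging clusters along a trajectory is
meaningless. It also assumes the initial clustering is *pure*: every
initial cluster lies inside one true cell type. That is why the initial
resolution is deliberately high (3.0); over-splitting is harmless (the
merge step repairs it), under-splitting is not. No corrected
gene-expression matrix is produced; the output is a corrected embedding
plus merged labels.

Stage order is fixed: filter → normalise/log1p → HVG selection → per-batch
scaling → PCA → initial clustering → NN pairs → similarity → merge →
triplet training. Cells are filtered before genes; gene filtering can
re-lower some cells' expressed-gene count below the cell threshold and the
cell filter is deliberately not re-applied.

## Tunable parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `min_genes`, `min_cells` | 10, 3 | quality filter (expressed genes per cell / cells per gene) |
| `target_sum` | 10,000 | per-cell library-size normalisation constant |
| `n_hvg` | 1000 | HVGs kept; equals the network input width |
| `max_scale_value` | 10 | z-score truncation bound (common convention; the bound itself is conventional, not derived) |
| `n_pca` | 100 | PCA dimensions for clustering and pair search |
| `resolution` | 3.0 | initial Louvain/Leiden resolution (over-fine on purpose) |
| `n_neighbors` | 15 | SNN-graph neighbours for initial clustering (toolkit default) |
| `k_in` | 5 | intra-batch KNN neighbours, cosine distance |
| `k_bw` | 10 | inter-batch MNN neighbours, cosine distance |
| `n_clusters` | `'auto'` | merge target; `'auto'` takes the *largest* eigengap candidate (fewest merges, most conservative) |
| `hidden_dim`, `embed_dim` | 256, 32 | MLP layer widths |
| `margin` | 0.2 | triplet margin *m* |
| `epochs`, `batch_size`, `learning_rate` | 50, 256, 1e-3 | Adam schedule; training converges quickly on separable merged labels, and there is no early stopping |

## Details and open-design decisions

**HVG selection** uses the mean-binned normalised-dispersion criterion,
computed per batch and aggregated by how many batches select each gene
(ties by median dispersion) — batch-aware HVGs are the standard for
integration tasks; `hvg_per_batch=False` switches to a joint ranking.

**Per-batch scaling** z-scores each gene within each batch with the
population (ddof = 0) standard deviation; zero-variance genes become 0, a
single-cell batch is centred with divisor 1 (warned).

**PCA** uses seeded randomized SVD: determinism is required, exactness is
not.

**Louvain** runs through python-igraph's multilevel modularity optimiser on
the scanpy UMAP-connectivity SNN graph, with igraph's RNG seeded; Leiden
runs through leidenalg with its native seed. Cluster ids are renumbered by
decreasing size.

**Pair search** is exact below 50,000 cells (brute-force cosine); distance
ties rank the lower cell index first, which makes oracle comparison exact.
(i, j) and (j, i) are counted as two ordered pairs throughout; this doubles
all counts symmetrically and cancels in the merge argmax, but is kept for
fidelity to the pair-set definitions. Rows are cosine-normalised once;
all-zero embedding rows are rejected.

**Merge recomputation rule** (a reconstruction — the exact update is one of
the genuinely open choices): after merging clusters u and v into w, counts
pool (a_wk = a_uk + a_vk), sizes add (m_w = m_u + m_v), and similarities
are recomputed as s_wk = a_wk / min(m_w, m_k). This is the unique rule
consistent with re-evaluating the similarity definition on the coarser
partition. The greedy argmax breaks ties on the lexicographically smallest
pair. Event similarities are recorded but monotonicity is *not* asserted:
under the pooling rule a merged cluster's similarity to a third cluster can
exceed earlier merge similarities, so the dendrogram may be non-monotone.
If all remaining similarities hit 0 before the target is reached, merging
stops early with a warning (components cannot be joined without evidence).

**Cluster-number inference** (also a reconstruction, in the spirit of
self-tuning spectral clustering): build
W = D<sup>−1/2</sup> ((S + Sᵀ)/2) D<sup>−1/2</sup> with D the row sums
(+1e−12), take descending eigenvalues, and propose every K whose gap
λ_K − λ_{K+1} exceeds mean + 2·sd of all gaps, plus the global max-gap K.
An all-zero S yields [C] with a warning. The candidate list is kept in
`candidates_`; when the true type count is known (the usual benchmarking
protocol) it is passed explicitly as `n_clusters`.

**Triplet training.** Category boundaries are ties-to-semi-hard
(d_an = d_ap or d_an = d_ap + m). Mini-batches are label-interleaved
(cells shuffled within each label and drawn round-robin) so hard triplets
stay mineable; batch-all hard mining computes the mean loss over *all*
hard triplets in the mini-batch with a vectorised O(b²)-memory gradient.
The network uses ReLU hidden activation, a linear output, He/Glorot-style
Gaussian init and Adam — conventional choices where the published
architecture stops at layer sizes. With no hard triplets in any mini-batch
the parameters are provably untouched. Labels with a single cell never act
as anchors or positives (warned); batch labels are never visible to the
trainer.

**Metrics.** ARI/NMI/silhouette delegate to scikit-learn (arithmetic-mean
NMI normalisation). Raw silhouette lives in [−1, 1]; because integration
benchmarks conventionally quote a [0, 1] quantity, both the raw value and
(s + 1)/2 are reported — the rescaled one wherever a [0, 1] scale is
expected. iLISI calibrates Gaussian weights over 3·perplexity (default 30)
neighbours to the target perplexity by bisection and averages the per-cell
inverse Simpson index of batch weights. BatchKL has no canonical printed
formula; the implementation uses 100 bootstrap replicates of 100 sampled
cells, k = min(100, n/10) nearest neighbours *including the cell itself*
(so that locally proportional data score exactly 0), natural log — all
configurable. All three are Euclidean in the evaluation embedding and
invariant to isometries (tested).

## Synthetic data generator

The generator emulates the standard splatter-style model: gamma baseline
gene means, per-type multiplicative DE factors (fraction 0.1, log-fold
±1.0), per-batch per-gene log-normal effects (sd 0.75), log-normal library
sizes (mean 2,500, sigma 0.25) and negative-binomial counts
(Var = μ + 0.2 μ²). The default design — 3 batches × 6 types, ~2,880 cells
× 2,000 genes, one type at ~2% abundance, one type present in a single
batch — exercises every property the merge rule must protect: the batch
effect is strong enough that an uncorrected PCA/Louvain analysis splits
types by batch, the rare type tests size-normalisation of the similarity,
and the batch-unique type tests that isolated clusters are never absorbed.
Optional one-level hierarchies give subtypes that share parent DE genes
plus smaller-effect private genes (scale < 1), so subtype centroids sit
closer than parent centroids and subtype merges must precede type merges.

What it does **not** emulate: dropout beyond NB sampling, ambient RNA,
doublets, gene–gene correlation within modules, continuous trajectories,
and realistic library-size/depth confounding between batches. Passing
tests therefore demonstrate the algorithmic contracts (purity, merging
order, rare-type preservation, batch mixing) under a clean generative
model, not performance on any real tissue.

## Problem sizes and degenerate inputs

Tests and the acceptance script run at desk scale: ~2,900 cells for the
end-to-end design, a few hundred cells elsewhere, chosen so each stage's
behaviour is unambiguous while the whole suite stays fast. Degenerate
inputs fail loudly and specifically: zero-total cells (named), all-removed
filters, zero embedding rows (cosine undefined, named), zero-size
clusters, single-batch MNN (empty with warning, not an error), single-cell
batches (centred, warned), singleton label groups in silhouette (0,
warned).

## Known limitations

* Applicable to categorical population structure only; not to
  differentiation continua.
* No corrected expression matrix — downstream DE analysis must use other
  tools.
* The merge recomputation rule and the eigengap recipe are reconstructions
  of procedures whose exact published form was unavailable; both are
  flagged above and exposed as configuration.
* `transform` on new data assumes the input is already in the scaled HVG
  space of the training run; full out-of-sample projection (new batches,
  new depth) is not supported.
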