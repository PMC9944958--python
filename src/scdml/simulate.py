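"""Synthetic multi-batch scRNA-seq count generator.

Generates negative-binomial counts with cell-type mean structure,
multiplicative per-batch gene effects, rare and batch-unique cell types, and
optional nested (parent type / subtype) hierarchy.  The generative skeleton
follows the splatter family: gamma-distributed baseline gene means,
log-normal library sizes, multiplicative differential-expression factors.

The defaults describe the benchmark design used throughout the test suite:
3 batches x 6 cell types (~2,880 cells x 2,000 genes), one type at ~2%
abundance, one type present in a single batch only, and a batch effect strong
enough that an uncorrected PCA/Louvain analysis mixes types across batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import anndata as ad
import numpy as np
import pandas as pd

__all__ = ["SimConfig", "simulate", "make_nested", "default_cell_grid"]


def default_cell_grid() -> np.ndarray:
    """Batches x types cell-count grid for the default benchmark design.

    Four common types, one rare type (~2% of cells overall), and one type
    unique to the first batch (zeros elsewhere encode absence).
    """
    return np.array(
        [
            [230, 230, 230, 230, 20, 60],
            [230, 230, 230, 230, 20, 0],
            [230, 230, 230, 230, 20, 0],
        ],
        dtype=int,
    )


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Attributes
    ----------
    n_batches, n_types
        Grid dimensions; must match ``cells_per_type_per_batch`` if given.
    cells_per_type_per_batch
        (n_batches, n_types) integer grid; zeros encode types absent from a
        batch (batch-unique types are a column with a single nonzero row).
    n_genes
        Number of genes simulated.
    de_fraction
        Fraction of genes that are differentially expressed per cell type.
    de_log_fold_change
        Magnitude of the (natural-log) fold change applied to DE genes.
    batch_effect_sd
        SD of the per-batch, per-gene log-normal multiplicative effect.
        0 disables batch effects.
    nb_dispersion
        Negative-binomial dispersion phi with Var = mu + phi * mu^2;
        0 degenerates to Poisson.
    library_size_mean, library_size_sigma
        Mean and log-scale SD of the log-normal per-cell library size.
    hierarchy
        Optional list of ``(parent_type, subtype, subtype_effect_scale)``
        tuples.  A subtype inherits its parent's DE factors and adds its own
        smaller-effect DE genes (scale < 1 keeps subtypes closer to each
        other than distinct parent types are).
    seed
        Seed for the generator; identical configs give identical data.
    """

    n_batches: int = 3
    n_types: int = 6
    cells_per_type_per_batch: Optional[np.ndarray] = None
    n_genes: int = 2000
    de_fraction: float = 0.1
    de_log_fold_change: float = 1.0
    batch_effect_sd: float = 0.75
    nb_dispersion: float = 0.2
    library_size_mean: float = 2500.0
    library_size_sigma: float = 0.25
    hierarchy: Sequence[Tuple[int, int, float]] = field(default_factory=list)
    seed: int = 0

    def grid(self) -> np.ndarray:
        if self.cells_per_type_per_batch is None:
            if (self.n_batches, self.n_types) == (3, 6):
                return default_cell_grid()
            # even allocation, ~960 cells per batch, when a custom shape is
            # requested without an explicit grid
            per = max(1, 960 // self.n_types)
            return np.full((self.n_batches, self.n_types), per, dtype=int)
        g = np.asarray(self.cells_per_type_per_batch, dtype=int)
        if g.shape != (self.n_batches, self.n_types):
            raise ValueError(
                f"cells_per_type_per_batch has shape {g.shape}, expected "
                f"{(self.n_batches, self.n_types)}"
            )
        if (g < 0).any():
            raise ValueError("cell counts must be non-negative")
        return g


def _type_factors(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-type multiplicative DE factors, shape (n_types, n_genes)."""
    n_de = max(1, int(round(cfg.de_fraction * cfg.n_genes)))
    parents = {sub: (par, scale) for par, sub, scale in cfg.hierarchy}
    for par, sub, scale in cfg.hierarchy:
        for t in (par, sub):
            if not (0 <= t < cfg.n_types):
                raise ValueError(f"hierarchy references unknown type {t}")
        if par == sub:
            raise ValueError("a type cannot be its own parent")
        if par in parents:
            raise ValueError("nested hierarchies deeper than one level are not supported")
        if scale >= 1.0:
            warnings.warn(
                "subtype_effect_scale >= 1: subtype separation is not "
                "guaranteed to be smaller than parent separation",
                stacklevel=3,
            )

    factors = np.ones((cfg.n_types, cfg.n_genes))
    own = {}
    # draw parent-level (and plain-type) factors first so subtypes can inherit
    for t in range(cfg.n_types):
        genes = rng.choice(cfg.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        own[t] = (genes, signs)
    for t in range(cfg.n_types):
        if t in parents:
            par, scale = parents[t]
            pg, ps = own[par]
            factors[t, pg] *= np.exp(ps * cfg.de_log_fold_change)
            g, s = own[t]
            factors[t, g] *= np.exp(s * cfg.de_log_fold_change * scale)
        else:
            g, s = own[t]
            factors[t, g] *= np.exp(s * cfg.de_log_fold_change)
    return factors


def simulate(cfg: SimConfig | None = None, **kwargs) -> ad.AnnData:
    """Draw a multi-batch count matrix from the configured model.

    Returns an :class:`anndata.AnnData` with integer counts in ``X``,
    ``obs['batch']`` and ``obs['celltype']`` categoricals, and the full
    configuration recorded in ``uns['sim_params']``.
    """
    if cfg is None:
        cfg = SimConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimConfig or keyword overrides, not both")
    grid = cfg.grid()
    rng = np.random.default_rng(cfg.seed)

    base = rng.gamma(shape=0.6, scale=1.0 / 0.3, size=cfg.n_genes) + 1e-4
    type_fac = _type_factors(cfg, rng)
    batch_fac = (
        np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=(cfg.n_batches, cfg.n_genes)))
        if cfg.batch_effect_sd > 0
        else np.ones((cfg.n_batches, cfg.n_genes))
    )

    n_cells = int(grid.sum())
    X = np.empty((n_cells, cfg.n_genes), dtype=np.int64)
    batch_lab = np.empty(n_cells, dtype=object)
    type_lab = np.empty(n_cells, dtype=object)

    log_mu = np.log(cfg.library_size_mean) - cfg.library_size_sigma**2 / 2.0
    row = 0
    for b in range(cfg.n_batches):
        for t in range(cfg.n_types):
            m = int(grid[b, t])
            if m == 0:
                continue
            mean = base * type_fac[t] * batch_fac[b]
            p = mean / mean.sum()
            lib = rng.lognormal(log_mu, cfg.library_size_sigma, size=m)
            mu = lib[:, None] * p[None, :]
            if cfg.nb_dispersion > 0:
                r = 1.0 / cfg.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mu))
            else:
                counts = rng.poisson(mu)
            X[row : row + m] = counts
            batch_lab[row : row + m] = f"batch{b}"
            type_lab[row : row + m] = f"type{t}"
            row += m

    obs = pd.DataFrame(
        {
            "batch": pd.Categorical(batch_lab),
            "celltype": pd.Categorical(type_lab),
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    var = pd.DataFrame(index=[f"gene{j}" for j in range(cfg.n_genes)])
    adata = ad.AnnData(X=X.astype(np.float32), obs=obs, var=var)
    adata.uns["sim_params"] = {
        "n_batches": cfg.n_batches,
        "n_types": cfg.n_types,
        "n_genes": cfg.n_genes,
        "de_fraction": cfg.de_fraction,
        "de_log_fold_change": cfg.de_log_fold_change,
        "batch_effect_sd": cfg.batch_effect_sd,
        "nb_dispersion": cfg.nb_dispersion,
        "library_size_mean": cfg.library_size_mean,
        "library_size_sigma": cfg.library_size_sigma,
        "hierarchy": [list(h) for h in cfg.hierarchy],
        "seed": cfg.seed,
    }
    return adata


def make_nested(cfg: SimConfig) -> ad.AnnData:
    """Simulate with a non-empty parent/subtype hierarchy.

    Subtypes share their parent's DE genes plus smaller-effect private genes,
    so same-parent subtype centroids sit closer together than centroids of
    different parents.
    """
    if not cfg.hierarchy:
        raise ValueError("make_nested requires a non-empty hierarchy")
    return simulate(cfg)
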