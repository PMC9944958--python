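"""Readers and writers for the supported single-cell formats.

Accepted inputs: an ``.h5ad`` container, a 10x-style MTX directory
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``/``genes.tsv``), or
delimited text (cells x genes, or transposed).  Per-cell annotations for MTX
and text inputs may come from a sidecar TSV with one row per cell.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

__all__ = ["read_data", "write_result"]


def _read_mtx_dir(path: Path) -> ad.AnnData:
    mtx = next((p for p in (path / "matrix.mtx", path / "matrix.mtx.gz") if p.exists()), None)
    if mtx is None:
        raise FileNotFoundError(f"no matrix.mtx in {path}")
    adata = sc.read_mtx(mtx).T  # MTX convention: genes x cells
    bc = path / "barcodes.tsv"
    if bc.exists():
        adata.obs_names = pd.read_csv(bc, header=None, sep="\t")[0].astype(str)
    for name in ("features.tsv", "genes.tsv"):
        f = path / name
        if f.exists():
            feat = pd.read_csv(f, header=None, sep="\t")
            adata.var_names = feat[feat.shape[1] - 1 if feat.shape[1] == 1 else 1].astype(str)
            break
    return adata


def read_data(
    path: str | Path,
    *,
    transpose: bool = False,
    obs_table: str | Path | None = None,
    batch_key: str = "batch",
    label_key: str | None = None,
) -> ad.AnnData:
    """Load a counts matrix with its per-cell annotations.

    ``obs_table`` (TSV/CSV, one row per cell, header) supplies the batch and
    optional cell-type columns for MTX and text inputs; for h5ad they are
    read from ``obs`` directly.  Raises if the batch column is absent.
    """
    path = Path(path)
    if path.is_dir():
        adata = _read_mtx_dir(path)
    elif path.suffix == ".h5ad":
        adata = ad.read_h5ad(path)
    elif path.suffix in {".csv", ".tsv", ".txt"}:
        delim = "," if path.suffix == ".csv" else "\t"
        adata = sc.read_text(path, delimiter=delim)
    else:
        raise ValueError(f"unrecognised input {path}")
    if transpose:
        adata = adata.T
    if obs_table is not None:
        obs_path = Path(obs_table)
        obs = pd.read_csv(obs_path, sep="," if obs_path.suffix == ".csv" else "\t")
        if len(obs) != adata.n_obs:
            raise ValueError(
                f"obs table has {len(obs)} rows for {adata.n_obs} cells"
            )
        obs.index = adata.obs_names
        for col in obs.columns:
            adata.obs[col] = obs[col].values
    if batch_key not in adata.obs:
        raise ValueError(f"batch column {batch_key!r} not found in per-cell annotations")
    adata.obs[batch_key] = adata.obs[batch_key].astype("category")
    if label_key is not None and label_key not in adata.obs:
        raise ValueError(f"label column {label_key!r} not found")
    return adata


def write_result(adata: ad.AnnData, path: str | Path) -> None:
    """Write the result container (h5ad) with all embedded annotations."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    adata.write_h5ad(path)
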