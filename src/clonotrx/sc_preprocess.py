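"""Single-cell UMI matrix preprocessing: cell filter, gene filter, TPM-like values.

Pipeline (order matters and is part of the contract):

1. ``filter_cells_by_mito`` — remove cells whose mitochondrial UMI fraction,
   computed on raw counts before any gene filtering, exceeds 10% (strict >).
2. ``filter_genes`` — keep genes with more than 2 UMIs in more than 5% of the
   remaining cells (both inequalities strict).
3. ``normalize_expression`` — per cell, divide each retained gene's count by
   the cell's retained-count sum, multiply by 10,000 (a TPM-like value) and
   add 1.  No log transform is applied; downstream rank tests are invariant
   to monotone transforms anyway.

Matrices are held as AnnData (cells x genes); raw UMI counts stay in ``.X``
and normalized values go to ``.layers["normalized"]``.  Multi-channel data
are filtered per channel and concatenated on the gene intersection.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import anndata as ad
import numpy as np
import scipy.sparse as sp

__all__ = [
    "mito_gene_mask",
    "mito_fraction",
    "filter_cells_by_mito",
    "filter_genes",
    "normalize_expression",
    "preprocess_channel",
    "merge_channels",
]

MITO_PREFIX = "MT-"


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def mito_gene_mask(adata: ad.AnnData, mito_genes: Sequence[str] | None = None,
                   mito_prefix: str = MITO_PREFIX) -> np.ndarray:
    """Boolean mask of mitochondrial genes.

    Defaults to the human "MT-" symbol prefix; an explicit gene list
    overrides the prefix rule.
    """
    names = adata.var_names
    if mito_genes is not None:
        missing = set(mito_genes) - set(names)
        if missing:
            raise ValueError(f"mito genes not in matrix: {sorted(missing)}")
        return names.isin(list(mito_genes))
    return np.asarray(names.str.startswith(mito_prefix))


def mito_fraction(adata: ad.AnnData, mito_genes: Sequence[str] | None = None,
                  mito_prefix: str = MITO_PREFIX) -> np.ndarray:
    """Per-cell mitochondrial UMI fraction on raw counts.

    Cells with zero total UMIs get NaN (fraction undefined).
    """
    X = _dense(adata.X).astype(float)
    mask = mito_gene_mask(adata, mito_genes, mito_prefix)
    total = X.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, X[:, mask].sum(axis=1) / np.where(total > 0, total, 1), np.nan)
    return frac


def filter_cells_by_mito(adata: ad.AnnData, mito_genes: Sequence[str] | None = None,
                         max_frac: float = 0.10, mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Remove cells with mito fraction strictly above ``max_frac`` (default 10%).

    Cells at exactly the threshold are retained.  Zero-UMI cells are removed
    with a warning (their fraction is undefined).
    """
    frac = mito_fraction(adata, mito_genes, mito_prefix)
    zero = np.isnan(frac)
    if zero.any():
        warnings.warn(f"removing {int(zero.sum())} cells with 0 total UMIs", stacklevel=2)
    keep = ~zero & (frac <= max_frac)
    out = adata[keep].copy()
    out.uns.setdefault("preprocess", {})["n_cells_before_mito_filter"] = adata.n_obs
    out.uns["preprocess"]["n_cells_after_mito_filter"] = out.n_obs
    out.uns["preprocess"]["max_mito_frac"] = max_frac
    return out


def filter_genes(adata: ad.AnnData, min_umi: int = 2, min_cell_frac: float = 0.05) -> ad.AnnData:
    """Keep genes with more than ``min_umi`` UMIs in more than ``min_cell_frac``
    of cells (both strict).
    """
    if adata.n_obs == 0:
        raise ValueError("no cells: apply the gene filter after the cell filter")
    X = _dense(adata.X)
    n_expressing = (X > min_umi).sum(axis=0)
    keep = n_expressing / adata.n_obs > min_cell_frac
    out = adata[:, keep].copy()
    out.uns.setdefault("preprocess", {})["n_genes_before_filter"] = adata.n_vars
    out.uns["preprocess"]["n_genes_after_filter"] = out.n_vars
    out.uns["preprocess"]["min_umi"] = min_umi
    out.uns["preprocess"]["min_cell_frac"] = min_cell_frac
    return out


def normalize_expression(adata: ad.AnnData, scale: float = 1e4,
                         use_prefilter_sums: bool = False,
                         log: bool = False) -> ad.AnnData:
    """Compute TPM-like expression values: 10,000 * count / cellsum + 1.

    ``cellsum`` is the per-cell sum over retained genes; set
    ``use_prefilter_sums`` to normalize by the pre-gene-filter totals stored
    by :func:`filter_genes` instead (requires ``adata.obs["total_umis_prefilter"]``).
    ``log`` applies log2 after the +1 offset (off by default; expression is
    defined as TPM-like + 1).
    """
    X = _dense(adata.X).astype(float)
    if use_prefilter_sums:
        if "total_umis_prefilter" not in adata.obs:
            raise ValueError("prefilter sums requested but not recorded")
        cellsum = adata.obs["total_umis_prefilter"].to_numpy(float)
    else:
        cellsum = X.sum(axis=1)
    if (cellsum <= 0).any():
        raise ValueError("cell with zero retained counts; filters must be applied first")
    norm = scale * X / cellsum[:, None] + 1.0
    out = adata.copy()
    out.layers["normalized"] = np.log2(norm) if log else norm
    out.uns.setdefault("preprocess", {})["normalization_scale"] = scale
    out.uns["preprocess"]["log_transformed"] = log
    return out


def preprocess_channel(adata: ad.AnnData, mito_genes: Sequence[str] | None = None,
                       max_mito_frac: float = 0.10, min_umi: int = 2,
                       min_cell_frac: float = 0.05,
                       mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Full per-channel cascade: mito cell filter, gene filter, normalization."""
    out = filter_cells_by_mito(adata, mito_genes, max_mito_frac, mito_prefix)
    out.obs["total_umis_prefilter"] = _dense(out.X).sum(axis=1)
    out = filter_genes(out, min_umi, min_cell_frac)
    return normalize_expression(out)


def merge_channels(channels: Sequence[ad.AnnData]) -> ad.AnnData:
    """Concatenate preprocessed channels on their gene intersection."""
    if not channels:
        raise ValueError("no channels to merge")
    if len(channels) == 1:
        return channels[0]
    merged = ad.concat(channels, join="inner", merge="same",
                       label="channel", index_unique="-")
    return merged
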