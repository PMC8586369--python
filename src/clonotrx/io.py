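"""File I/O for the formats the pipeline consumes and emits.

FASTQ/FASTA through Bio.SeqIO (gzip transparent), MatrixMarket count
matrices (10x layout: genes x cells on disk, cells x genes in memory) with
genes.tsv / barcodes.tsv sidecars, sample-metadata CSV, and the cell-clone
map TSV.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO

from .barcode_quant import SampleMeta
from .bridge_map import CellCloneMap

__all__ = [
    "read_sequences",
    "write_fastq",
    "write_fasta",
    "read_meta_csv",
    "write_meta_csv",
    "read_mtx_channel",
    "write_mtx_channel",
    "read_cell_clone_map",
    "write_cell_clone_map",
]

META_COLUMNS = ["sample_id", "mouse_id", "tissue", "timepoint_days",
                "treatment_arm", "passage", "frac_human_of_mnc", "frac_gfp_of_human"]


def _open_text(path: Path, mode: str = "rt"):
    path = Path(path)
    return gzip.open(path, mode) if path.suffix == ".gz" else open(path, mode)


def read_sequences(path, fmt: str | None = None) -> Iterator:
    """Iterate SeqRecords from FASTQ or FASTA (gzip allowed); format inferred
    from the file name unless given."""
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        yield from SeqIO.parse(fh, fmt)


def write_fastq(path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as FASTQ with uniform quality."""
    with _open_text(Path(path), "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(path, reads: Iterable[tuple[str, str]]) -> None:
    with _open_text(Path(path), "wt") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def read_meta_csv(path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    metas = {}
    for _, row in df.iterrows():
        m = SampleMeta(
            sample_id=str(row["sample_id"]), mouse_id=str(row["mouse_id"]),
            tissue=str(row["tissue"]), timepoint_days=float(row["timepoint_days"]),
            treatment_arm=str(row["treatment_arm"]), passage=int(row["passage"]),
            frac_human_of_mnc=float(row["frac_human_of_mnc"]),
            frac_gfp_of_human=float(row["frac_gfp_of_human"]),
        )
        if m.sample_id in metas:
            raise ValueError(f"duplicate sample_id {m.sample_id}")
        metas[m.sample_id] = m
    return metas


def write_meta_csv(path, metas: Iterable[SampleMeta]) -> None:
    rows = [{c: getattr(m, c) for c in META_COLUMNS} for m in metas]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, index=False)


def read_mtx_channel(directory) -> ad.AnnData:
    """Load matrix.mtx + genes.tsv + barcodes.tsv as an AnnData (cells x genes)."""
    d = Path(directory)
    X = scipy.io.mmread(d / "matrix.mtx").tocsr().T  # disk is genes x cells
    genes = pd.read_csv(d / "genes.tsv", header=None, sep="\t")[0].astype(str)
    cells = pd.read_csv(d / "barcodes.tsv", header=None, sep="\t")[0].astype(str)
    adata = ad.AnnData(X=X, obs=pd.DataFrame(index=cells), var=pd.DataFrame(index=genes))
    adata.obs_names.name = None
    return adata


def write_mtx_channel(adata: ad.AnnData, directory, layer: str | None = None) -> None:
    """Write an AnnData channel in the genes x cells MTX + TSV layout."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.layers[layer] if layer else adata.X
    M = sp.coo_matrix(np.asarray(X).T if not sp.issparse(X) else X.T)
    scipy.io.mmwrite(str(d / "matrix.mtx"), M)
    pd.Series(adata.var_names).to_csv(d / "genes.tsv", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", index=False, header=False)
    if "preprocess" in adata.uns:
        (d / "preprocess.json").write_text(
            json.dumps(adata.uns["preprocess"], indent=2, default=float))


def read_cell_clone_map(path) -> CellCloneMap:
    """Read the two-column assignment TSV plus its sidecar exclusions TSV."""
    path = Path(path)
    out = CellCloneMap()
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "clone"])
    out.assignments = dict(zip(df["cell"].astype(str), df["clone"].astype(str)))
    excl = path.with_name(path.stem + ".exclusions.tsv")
    if excl.exists():
        e = pd.read_csv(excl, sep="\t", header=None, names=["cell", "reason"])
        for _, row in e.iterrows():
            if row["reason"] == "multimapped":
                out.excluded_multimapped.add(str(row["cell"]))
            else:
                out.unmapped_cells.add(str(row["cell"]))
    return out


def write_cell_clone_map(ccmap: CellCloneMap, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for cell in sorted(ccmap.assignments):
            fh.write(f"{cell}\t{ccmap.assignments[cell]}\n")
    with open(path.with_name(path.stem + ".exclusions.tsv"), "w") as fh:
        for cell in sorted(ccmap.excluded_multimapped):
            fh.write(f"{cell}\tmultimapped\n")
        for cell in sorted(ccmap.unmapped_cells):
            fh.write(f"{cell}\tunmapped\n")
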