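"""Readers/writers for 10x-style MTX triplets and pipeline tables.

On disk the matrix is genes x cells (MatrixMarket coordinate integer format
with 1-based indices); in memory everything is an AnnData with cells as
observations. Gzipped and plain triplets are both accepted.
"""
from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["read_10x_mtx", "write_10x_mtx"]


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}(.gz) not found in {directory}")


def _open(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path, "rt")


def _read_tsv_column(path: Path) -> pd.DataFrame:
    with _open(path) as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def read_10x_mtx(directory) -> ad.AnnData:
    """Load a matrix.mtx/barcodes.tsv/features.tsv triplet as AnnData.

    Duplicate feature ids are disambiguated deterministically with numeric
    suffixes. Dimension mismatches between the matrix header and the tsv
    files raise an error naming the offending files.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    bc_path = _find(directory, "barcodes.tsv")
    try:
        ft_path = _find(directory, "features.tsv")
    except FileNotFoundError:
        ft_path = _find(directory, "genes.tsv")

    with _open(mtx_path) as fh:
        M = scipy.io.mmread(fh)  # genes x cells
    M = sp.csr_matrix(M.T)  # cells x genes
    barcodes = _read_tsv_column(bc_path)
    features = _read_tsv_column(ft_path)
    if M.shape[0] != len(barcodes):
        raise ValueError(
            f"{mtx_path.name} has {M.shape[0]} cells but {bc_path.name} lists {len(barcodes)}"
        )
    if M.shape[1] != len(features):
        raise ValueError(
            f"{mtx_path.name} has {M.shape[1]} genes but {ft_path.name} lists {len(features)}"
        )
    var = pd.DataFrame(index=pd.Index(features[0], name="gene_id"))
    if features.shape[1] > 1:
        var["gene_name"] = features[1].to_numpy()
    adata = ad.AnnData(X=M, var=var)
    adata.obs_names = barcodes[0].to_numpy()
    adata.var_names_make_unique()
    adata.obs_names_make_unique()
    return adata


def write_10x_mtx(adata: ad.AnnData, directory, gzipped: bool = False) -> None:
    """Write an AnnData back to a genes x cells MTX triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)
    suffix = ".gz" if gzipped else ""
    opener = (lambda p: gzip.open(p, "wb")) if gzipped else (lambda p: open(p, "wb"))
    with opener(directory / f"matrix.mtx{suffix}") as fh:
        scipy.io.mmwrite(fh, X, field="integer" if np.issubdtype(X.dtype, np.integer) else "real")
    topen = (lambda p: gzip.open(p, "wt")) if gzipped else (lambda p: open(p, "wt"))
    with topen(directory / f"barcodes.tsv{suffix}") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    with topen(directory / f"features.tsv{suffix}") as fh:
        names = (adata.var["gene_name"] if "gene_name" in adata.var
                 else pd.Series(adata.var_names, index=adata.var_names))
        for gid, gname in zip(adata.var_names, names):
            fh.write(f"{gid}\t{gname}\tGene Expression\n")
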