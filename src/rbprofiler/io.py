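"""Reading and writing the TSV / MTX dialects the pipeline consumes.

Matrices are headered TSV with gene symbols in the first column and
samples in the header; sample/cell metadata are side-car TSVs. Large
single-cell matrices may arrive as a MatrixMarket triplet plus gene
and barcode index files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

from .cytotox import SingleCellMatrix
from .expression import ExpressionMatrix

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_sample_meta",
    "read_expression_tsv",
    "read_sc_tsv",
    "read_sc_mtx",
    "write_sc_mtx",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Genes x samples TSV with symbols in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "symbol") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_meta(path, index_col: str = "sample") -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    if index_col not in meta.columns:
        raise ValueError(f"metadata file lacks a {index_col!r} column")
    return meta.set_index(index_col)


def read_expression_tsv(matrix_path, meta_path, unit: str) -> ExpressionMatrix:
    values = read_matrix_tsv(matrix_path)
    meta = read_sample_meta(meta_path)
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    return ExpressionMatrix(values, meta.loc[values.columns], unit=unit)


def read_sc_tsv(matrix_path, meta_path=None) -> SingleCellMatrix:
    counts = read_matrix_tsv(matrix_path).astype(int)
    meta = None
    if meta_path is not None:
        meta = read_sample_meta(meta_path, index_col="barcode")
        meta = meta.loc[counts.columns]
    return SingleCellMatrix(counts, meta)


def read_sc_mtx(mtx_path, genes_path, barcodes_path, meta_path=None) -> (
    SingleCellMatrix
):
    """MatrixMarket triplet (genes x cells) + index files."""
    mat = spio.mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    counts = pd.DataFrame(
        sparse.coo_matrix(mat).toarray().astype(int),
        index=genes,
        columns=barcodes,
    )
    meta = None
    if meta_path is not None:
        meta = read_sample_meta(meta_path, index_col="barcode").loc[counts.columns]
    return SingleCellMatrix(counts, meta)


def write_sc_mtx(sc: SingleCellMatrix, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "matrix.mtx", sparse.coo_matrix(sc.counts.to_numpy()))
    pd.Series(sc.genes).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(sc.cells).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    sc.cell_meta.to_csv(out / "cells.tsv", sep="\t", index_label="barcode")
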