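"""Readers and writers for the package's on-disk formats.

Images are 8-bit RGB TIFF/PNG (tifffile / imageio); instance maps are
single-channel integer TIFFs; expression matrices travel as CSV (cells x
genes, header row of gene names) or MatrixMarket with gene/cell sidecars;
reference profiles as CSV with profile names as the row index; cell tables
as CSV.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .core import (CellTable, ExpressionMatrix, HEPatch, InstanceMap,
                   ReferenceProfiles)

__all__ = [
    "read_patch", "write_patch", "read_instance_map", "write_instance_map",
    "read_expression_csv", "write_expression_csv",
    "read_expression_mtx", "write_expression_mtx",
    "read_reference_profiles", "write_reference_profiles",
    "read_cell_table", "write_cell_table",
]


def write_patch(path: str, patch: HEPatch) -> None:
    arr = patch.pixels.astype(np.uint8)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_patch(path: str, origin=(0, 0), mpp: float = 0.5) -> HEPatch:
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return HEPatch(arr, origin=tuple(origin), mpp=mpp)


def write_instance_map(path: str, imap: InstanceMap) -> None:
    tifffile.imwrite(path, imap.labels.astype(np.int32))


def read_instance_map(path: str) -> InstanceMap:
    return InstanceMap(tifffile.imread(path).astype(np.int64))


def write_expression_csv(path: str, expr: ExpressionMatrix,
                         cell_ids=None) -> None:
    idx = cell_ids if cell_ids is not None else np.arange(expr.n_cells)
    pd.DataFrame(expr.values, index=idx, columns=expr.gene_names) \
        .to_csv(path, index_label="cell_id")


def read_expression_csv(path: str, scale: str = "raw_counts") -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=np.float64), list(df.columns), scale=scale)


def write_expression_mtx(prefix: str, expr: ExpressionMatrix, cell_ids=None) -> None:
    """Write <prefix>.mtx plus <prefix>.genes.txt / <prefix>.cells.txt sidecars."""
    mmwrite(prefix + ".mtx", csr_matrix(expr.values))
    with open(prefix + ".genes.txt", "w") as fh:
        fh.write("\n".join(expr.gene_names) + "\n")
    ids = cell_ids if cell_ids is not None else np.arange(expr.n_cells)
    with open(prefix + ".cells.txt", "w") as fh:
        fh.write("\n".join(str(i) for i in ids) + "\n")


def read_expression_mtx(prefix: str, scale: str = "raw_counts") -> ExpressionMatrix:
    values = np.asarray(mmread(prefix + ".mtx").todense(), dtype=np.float64)
    with open(prefix + ".genes.txt") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return ExpressionMatrix(values, genes, scale=scale)


def write_reference_profiles(path: str, ref: ReferenceProfiles) -> None:
    pd.DataFrame(ref.R, index=ref.profile_names, columns=ref.gene_names) \
        .to_csv(path, index_label="profile")


def read_reference_profiles(path: str) -> ReferenceProfiles:
    df = pd.read_csv(path, index_col=0)
    return ReferenceProfiles(df.to_numpy(dtype=np.float64),
                             [str(i) for i in df.index], list(df.columns))


def write_cell_table(path: str, cells: CellTable) -> None:
    cells.df.to_csv(path, index=False)


def read_cell_table(path: str, mpp: float = 0.5) -> CellTable:
    return CellTable(pd.read_csv(path), mpp=mpp)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
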