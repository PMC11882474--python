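"""Reading and writing the on-disk formats used throughout the pipeline.

Count matrices travel as CellRanger-style triplets: ``matrix.mtx`` (MatrixMarket
integer coordinate, features x barcodes, 1-based indices), ``features.tsv`` and
``barcodes.tsv``.  Gene sets travel as GMT.  Barcode metadata travels as TSV with
one row per barcode.  In memory everything is an :class:`anndata.AnnData` with
nuclei as observations and genes as variables.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "MTXParseError",
    "read_10x",
    "write_10x",
    "read_gmt",
    "write_gmt",
    "read_metadata",
    "write_metadata",
]

METADATA_COLUMNS = (
    "barcode",
    "pool",
    "individual",
    "stress",
    "wheel",
    "dist_40d",
    "dist_24h",
    "dist_3h",
    "dist_30_90m",
    "dist_30m",
)


class MTXParseError(ValueError):
    """Raised when a MatrixMarket file is malformed; message names the line."""


def _parse_mtx(path: str) -> sp.coo_matrix:
    """Validating MatrixMarket coordinate reader.

    Stricter than a generic reader: indices must be 1-based and in range,
    entries must be integral, and the entry count must match the header.
    Errors carry the 1-based line number of the offending line.
    """
    with open(path, "rt") as fh:
        lines = fh.readlines()
    if not lines:
        raise MTXParseError(f"{path}: line 1: empty file")
    header = lines[0].strip().split()
    if (
        len(header) < 4
        or header[0] != "%%MatrixMarket"
        or header[1].lower() != "matrix"
        or header[2].lower() != "coordinate"
    ):
        raise MTXParseError(
            f"{path}: line 1: expected '%%MatrixMarket matrix coordinate ...' header"
        )
    field = header[3].lower()
    if field not in ("integer", "real"):
        raise MTXParseError(f"{path}: line 1: unsupported field type '{field}'")

    # skip comments
    ln = 1
    while ln < len(lines) and lines[ln].lstrip().startswith("%"):
        ln += 1
    if ln >= len(lines):
        raise MTXParseError(f"{path}: line {ln + 1}: missing size line")
    size_line = ln  # 0-based index of the size line
    parts = lines[size_line].split()
    if len(parts) != 3:
        raise MTXParseError(
            f"{path}: line {size_line + 1}: size line must have 3 fields"
        )
    try:
        n_rows, n_cols, nnz = (int(p) for p in parts)
    except ValueError as exc:
        raise MTXParseError(
            f"{path}: line {size_line + 1}: non-integer size entry"
        ) from exc

    body = [l for l in lines[size_line + 1 :] if l.strip()]
    if len(body) != nnz:
        raise MTXParseError(
            f"{path}: line {size_line + 1}: header promises {nnz} entries, "
            f"file has {len(body)}"
        )
    rows = np.empty(nnz, dtype=np.int64)
    cols = np.empty(nnz, dtype=np.int64)
    vals = np.empty(nnz, dtype=np.int64)
    for k, line in enumerate(body):
        lineno = size_line + 2 + k
        parts = line.split()
        if len(parts) != 3:
            raise MTXParseError(f"{path}: line {lineno}: expected 'row col value'")
        try:
            i, j = int(parts[0]), int(parts[1])
            v = float(parts[2])
        except ValueError as exc:
            raise MTXParseError(f"{path}: line {lineno}: unparsable entry") from exc
        if i < 1 or j < 1:
            raise MTXParseError(
                f"{path}: line {lineno}: indices are 1-based; got ({i}, {j})"
            )
        if i > n_rows or j > n_cols:
            raise MTXParseError(
                f"{path}: line {lineno}: index ({i}, {j}) outside declared "
                f"{n_rows} x {n_cols} shape"
            )
        if v != int(v):
            raise MTXParseError(
                f"{path}: line {lineno}: non-integer count value {parts[2]}"
            )
        rows[k], cols[k], vals[k] = i - 1, j - 1, int(v)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n_rows, n_cols))


def read_10x(directory: str) -> ad.AnnData:
    """Read a CellRanger-style directory into an AnnData (nuclei x genes).

    Expects ``matrix.mtx`` (features x barcodes), ``features.tsv`` and
    ``barcodes.tsv``.  If ``metadata.tsv`` is present it is merged into
    ``.obs`` on the barcode column.
    """
    mtx = _parse_mtx(os.path.join(directory, "matrix.mtx"))
    features = pd.read_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=None
    )
    barcodes = pd.read_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=None
    )
    if len(features) != mtx.shape[0]:
        raise MTXParseError(
            f"features.tsv has {len(features)} rows but matrix declares "
            f"{mtx.shape[0]} features"
        )
    if len(barcodes) != mtx.shape[1]:
        raise MTXParseError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix declares "
            f"{mtx.shape[1]} barcodes"
        )
    var = pd.DataFrame(index=pd.Index(features[0].astype(str), name="gene"))
    if features.shape[1] > 1:
        var["gene_name"] = features[1].astype(str).values
    adata = ad.AnnData(
        X=sp.csr_matrix(mtx.T),
        obs=pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="barcode")),
        var=var,
    )
    meta_path = os.path.join(directory, "metadata.tsv")
    if os.path.exists(meta_path):
        meta = read_metadata(meta_path).set_index("barcode")
        adata.obs = adata.obs.join(meta, how="left")
    return adata


def write_10x(adata: ad.AnnData, directory: str) -> None:
    """Write an AnnData (nuclei x genes) as matrix.mtx + features/barcodes TSV.

    The matrix is written features x barcodes with integer entries; any
    barcode metadata in ``.obs`` is written alongside as ``metadata.tsv``.
    """
    os.makedirs(directory, exist_ok=True)
    X = sp.coo_matrix(adata.X).T.astype(np.int64)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), X, field="integer")
    # mmwrite appends .mtx if missing; it does not here since we pass it.
    feats = pd.DataFrame({0: adata.var_names})
    if "gene_name" in adata.var:
        feats[1] = adata.var["gene_name"].values
    feats.to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )
    if adata.obs.shape[1]:
        meta = adata.obs.reset_index()
        meta = meta.rename(columns={meta.columns[0]: "barcode"})
        meta.to_csv(os.path.join(directory, "metadata.tsv"), sep="\t", index=False)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file into {set name: member genes} (duplicates dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    "and at least one gene"
                )
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str,
              description: str = "na") -> None:
    with open(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_metadata(path: str) -> pd.DataFrame:
    """Read a barcode metadata TSV; requires at least the barcode column."""
    meta = pd.read_csv(path, sep="\t")
    if "barcode" not in meta.columns:
        raise ValueError(f"{path}: metadata TSV must have a 'barcode' column")
    return meta


def write_metadata(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)
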