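"""Readers and writers for the on-disk formats.

Counts come either as MatrixMarket triplets (``counts.mtx`` +
``genes.tsv`` + ``barcodes.tsv``, genes-by-spots as in CellRanger output)
or as a dense CSV with spots in rows and a gene header. Marker tables are
two-column CSV/TSV (``gene,cell_type``). Coordinates are CSV with
``spot_id,row,col`` (array platforms) or ``spot_id,x,y`` (Euclidean);
covariates are CSV with a ``spot_id`` column followed by numeric columns
(a ``batch`` column is treated as categorical and one-hot encoded with
the first level dropped).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .graph import SpotCoordinates
from .nb_mixture import CountMatrix, MarkerMatrix

__all__ = [
    "read_counts_mtx",
    "read_counts_csv",
    "write_counts_mtx",
    "read_markers",
    "marker_table_to_matrix",
    "read_coords",
    "coords_from_dataframe",
    "read_covariates",
]

logger = logging.getLogger(__name__)


def read_counts_mtx(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """MatrixMarket triplet (genes x spots) with gene/barcode lists."""
    M = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(M):
        M = M.toarray()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    if M.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {M.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    if not np.allclose(M, np.round(M)):
        r, c = np.argwhere(~np.isclose(M, np.round(M)))[0]
        raise ValueError(f"non-integer count at gene row {r}, spot column {c}")
    return CountMatrix(M.T, spot_ids=barcodes, gene_ids=genes)


def read_counts_csv(path) -> CountMatrix:
    """Dense CSV: first column spot ids, header row gene ids."""
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy()
    if not np.allclose(vals, np.round(vals.astype(float))):
        r, c = np.argwhere(~np.isclose(vals.astype(float),
                                       np.round(vals.astype(float))))[0]
        raise ValueError(f"non-integer count at row {df.index[r]}, column {df.columns[c]}")
    return CountMatrix(vals, spot_ids=[str(i) for i in df.index],
                       gene_ids=[str(c) for c in df.columns])


def write_counts_mtx(counts: CountMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "counts.mtx"),
                     scipy.sparse.coo_matrix(counts.Y.T))
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False,
                                      header=False)
    pd.Series(counts.spot_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False,
                                      header=False)


def marker_table_to_matrix(table: pd.DataFrame, gene_ids: list[str]):
    """Build rho from a (gene, cell_type) table over known genes.

    Unknown genes are warned about and skipped; duplicate rows are
    deduplicated; type order follows first appearance in the table. A gene
    may mark several types (multiple ones in its row). Returns the marker
    matrix and the marker-gene order (the model input view).
    """
    cols = [c.lower() for c in table.columns]
    table = table.rename(columns=dict(zip(table.columns, cols)))
    if not {"gene", "cell_type"}.issubset(cols):
        raise ValueError("marker table needs 'gene' and 'cell_type' columns")
    known = set(gene_ids)
    unknown = sorted(set(table["gene"].astype(str)) - known)
    if unknown:
        logger.warning("dropping %d marker genes absent from the counts: %s",
                       len(unknown), unknown[:10])
    table = table[table["gene"].astype(str).isin(known)]
    if table.duplicated(["gene", "cell_type"]).any():
        logger.warning("duplicate (gene, cell_type) rows deduplicated")
        table = table.drop_duplicates(["gene", "cell_type"])
    if table.empty:
        raise ValueError("no marker genes overlap the count matrix")
    type_names = list(dict.fromkeys(table["cell_type"].astype(str)))
    marker_genes = [g for g in gene_ids if g in set(table["gene"].astype(str))]
    rho = np.zeros((len(marker_genes), len(type_names)))
    g_lut = {g: i for i, g in enumerate(marker_genes)}
    t_lut = {t: i for i, t in enumerate(type_names)}
    for _, row in table.iterrows():
        rho[g_lut[str(row["gene"])], t_lut[str(row["cell_type"])]] = 1.0
    matrix = MarkerMatrix(rho=rho, type_names=type_names, gene_ids=marker_genes)
    return matrix, marker_genes


def read_markers(path, gene_ids: list[str]):
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return marker_table_to_matrix(pd.read_csv(path, sep=sep), gene_ids)


def coords_from_dataframe(df: pd.DataFrame, platform: str = "st") -> SpotCoordinates:
    cols = {c.lower(): c for c in df.columns}
    mode = {"st": "array_grid_square", "visium": "array_grid_hex",
            "knn": "euclidean"}.get(platform)
    if mode is None:
        raise ValueError(f"unknown platform {platform!r}")
    if mode == "euclidean":
        if not {"x", "y"}.issubset(cols):
            raise ValueError("euclidean coordinates need 'x' and 'y' columns")
        pos = df[[cols["x"], cols["y"]]].to_numpy(dtype=float)
    else:
        if not {"row", "col"}.issubset(cols):
            raise ValueError("grid coordinates need 'row' and 'col' columns")
        pos = df[[cols["row"], cols["col"]]].to_numpy(dtype=float)
    ids = ([str(i) for i in df[cols["spot_id"]]] if "spot_id" in cols
           else [str(i) for i in df.index])
    return SpotCoordinates(positions=pos, mode=mode, spot_ids=ids)


def read_coords(path, platform: str = "st") -> SpotCoordinates:
    return coords_from_dataframe(pd.read_csv(path), platform)


def read_covariates(path, spot_ids: list[str]):
    """Covariate CSV aligned to the spot order; 'batch' is one-hot encoded
    with the first level as reference."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "spot_id" in cols:
        df = df.set_index(cols["spot_id"])
        df.index = df.index.astype(str)
        df = df.loc[[str(s) for s in spot_ids]]
    parts = []
    names: list[str] = []
    for col in df.columns:
        if col.lower() == "batch":
            onehot = pd.get_dummies(df[col].astype(str), prefix="batch",
                                    drop_first=True)
            parts.append(onehot.to_numpy(dtype=float))
            names.extend(onehot.columns)
        else:
            parts.append(df[[col]].to_numpy(dtype=float))
            names.append(col)
    X = np.hstack(parts) if parts else np.zeros((len(df), 0))
    return X, names
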