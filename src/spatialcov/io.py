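"""Readers/writers for cell-by-gene matrices, coordinates and artifacts.

Canonical orientation everywhere is cells x genes; on-disk artifacts carry
gene *names*, never indices.  Supported formats: delimited text (CSV/TSV
with a gene-name header row and a first column of cell ids), MatrixMarket
triplets with ``genes.tsv`` / ``barcodes.tsv`` sidecars, and AnnData
``.h5ad`` containers as a convenience.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["DatasetBundle", "read_bundle", "write_bundle", "read_coordinates",
           "write_covet_h5", "read_covet_h5"]


@dataclass
class DatasetBundle:
    expression: pd.DataFrame  # cells x genes, cell ids as index
    coordinates: np.ndarray | None = None  # (n, 2|3)
    labels: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.expression.columns.duplicated().any():
            dups = self.expression.columns[self.expression.columns.duplicated()]
            raise ValueError(f"duplicate gene names: {list(dups[:5])}")
        if self.expression.index.duplicated().any():
            raise ValueError("duplicate cell ids")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape[0] != self.expression.shape[0]:
                raise ValueError(
                    f"coordinate rows ({self.coordinates.shape[0]}) do not match "
                    f"cell count ({self.expression.shape[0]})"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.expression.columns]

    @property
    def cell_ids(self) -> list[str]:
        return [str(c) for c in self.expression.index]

    @property
    def counts(self) -> np.ndarray:
        return self.expression.to_numpy(dtype=float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def read_coordinates(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """CSV with columns cell_id, x, y[, z]; returns (coords, cell ids)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"{path}: coordinate file must have x and y columns")
    axes = [df.columns[cols.index(a)] for a in ("x", "y", "z") if a in cols]
    ids = df[df.columns[0]].astype(str).tolist() if df.columns[0].lower() not in (
        "x", "y", "z") else [str(i) for i in range(len(df))]
    return df[axes].to_numpy(dtype=float), ids


def read_bundle(
    path: str | Path,
    fmt: str | None = None,
    coords_path: str | Path | None = None,
    labels_path: str | Path | None = None,
    orientation: str = "auto",  # auto | cells_x_genes | genes_x_cells
) -> DatasetBundle:
    """Read an expression dataset (plus optional coordinates and labels).

    ``fmt`` is inferred from the suffix when omitted (.csv/.tsv/.mtx/.h5ad).
    MatrixMarket input expects ``genes.tsv`` and ``barcodes.tsv`` sidecars
    next to the matrix; orientation is resolved from the sidecar lengths
    and must be overridden explicitly when ambiguous (square matrices).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv",
               ".mtx": "mtx", ".h5ad": "h5ad", ".h5": "h5ad"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    provenance = {"source": str(path), "sha256": _sha256(path), "format": fmt}

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.columns = [str(c) for c in df.columns]
        expr = df
        if orientation == "genes_x_cells":
            expr = df.T
    elif fmt == "mtx":
        mat = spio.mmread(path)
        mat = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        genes_file = path.parent / "genes.tsv"
        barcodes_file = path.parent / "barcodes.tsv"
        if not genes_file.exists() or not barcodes_file.exists():
            raise FileNotFoundError(
                f"MTX input needs genes.tsv and barcodes.tsv next to {path}"
            )
        genes = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(barcodes_file, sep="\t", header=None)[0].astype(str).tolist()
        nr, nc = mat.shape
        if orientation == "auto":
            if nr == len(cells) and nc == len(genes) and nr != nc:
                pass
            elif nr == len(genes) and nc == len(cells) and nr != nc:
                mat = mat.T
            else:
                raise ValueError(
                    "matrix orientation is ambiguous; pass orientation="
                    "'cells_x_genes' or 'genes_x_cells'"
                )
        elif orientation == "genes_x_cells":
            mat = mat.T
        expr = pd.DataFrame(mat, index=cells, columns=genes)
    elif fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X)
        expr = pd.DataFrame(X, index=adata.obs_names.astype(str),
                            columns=adata.var_names.astype(str))
        bundle_coords = None
        for slot in ("spatial", "X_spatial", "coords"):
            if slot in adata.obsm:
                bundle_coords = np.asarray(adata.obsm[slot], dtype=float)
                break
        labels = None
        for col in ("cell_type", "label", "labels"):
            if col in adata.obs:
                labels = adata.obs[col].astype(str)
                labels.index = expr.index
                break
        if coords_path is None and bundle_coords is not None:
            return DatasetBundle(expr, bundle_coords, labels, provenance)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    coords = None
    labels = None
    if coords_path is not None:
        coords, _ = read_coordinates(coords_path)
        provenance["coords"] = str(coords_path)
    if labels_path is not None:
        ldf = pd.read_csv(labels_path)
        labels = ldf[ldf.columns[-1]].astype(str)
        labels.index = expr.index[: len(labels)]
        provenance["labels"] = str(labels_path)
    return DatasetBundle(expr, coords, labels, provenance)


def write_bundle(bundle: DatasetBundle, out_dir: str | Path, fmt: str = "tsv") -> None:
    """Write counts (TSV or MTX + sidecars), coordinates and labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        bundle.expression.to_csv(out / f"counts.{fmt}", sep=sep)
    elif fmt == "mtx":
        spio.mmwrite(out / "counts.mtx", sparse.csr_matrix(bundle.counts))
        pd.Series(bundle.gene_ids).to_csv(out / "genes.tsv", sep="\t",
                                          header=False, index=False)
        pd.Series(bundle.cell_ids).to_csv(out / "barcodes.tsv", sep="\t",
                                          header=False, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if bundle.coordinates is not None:
        cols = ["x", "y", "z"][: bundle.coordinates.shape[1]]
        pd.DataFrame(bundle.coordinates, columns=cols, index=bundle.cell_ids) \
            .rename_axis("cell_id").to_csv(out / "coordinates.csv")
    if bundle.labels is not None:
        pd.DataFrame({"cell_id": bundle.cell_ids, "label": bundle.labels.values}) \
            .to_csv(out / "labels.csv", index=False)


def write_covet_h5(path: str | Path, sigma: np.ndarray, sigma_sqrt: np.ndarray,
                   gene_ids: list[str] | None, cell_ids: list[str] | None,
                   config: dict | None = None) -> None:
    """Persist a COVET tensor (n, g, g) with name attributes and config hash."""
    with h5py.File(path, "w") as f:
        f.create_dataset("sigma", data=sigma, compression="gzip")
        f.create_dataset("sigma_sqrt", data=sigma_sqrt, compression="gzip")
        if gene_ids is not None:
            f.create_dataset("genes", data=np.array(gene_ids, dtype="S"))
        if cell_ids is not None:
            f.create_dataset("cells", data=np.array(cell_ids, dtype="S"))
        if config is not None:
            blob = json.dumps(config, sort_keys=True)
            f.attrs["config"] = blob
            f.attrs["config_sha256"] = hashlib.sha256(blob.encode()).hexdigest()


def read_covet_h5(path: str | Path) -> dict:
    with h5py.File(path, "r") as f:
        out = {
            "sigma": f["sigma"][:],
            "sigma_sqrt": f["sigma_sqrt"][:],
            "genes": [g.decode() for g in f["genes"][:]] if "genes" in f else None,
            "cells": [c.decode() for c in f["cells"][:]] if "cells" in f else None,
            "config": json.loads(f.attrs["config"]) if "config" in f.attrs else None,
        }
    return out
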