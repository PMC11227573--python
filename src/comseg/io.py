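"""Readers and writers for point clouds, nucleus landmarks and results.

Point clouds are CSV/TSV with configurable column names; nucleus
landmarks are TIFF label images (2D or 3D) or centroid tables; count
matrices are written as MatrixMarket MTX with plain-text cell and gene
index files; the run manifest is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio, sparse

from .config import ComSegConfig
from .datatypes import (
    UNASSIGNED,
    CellAssignment,
    CellProfileMatrix,
    NucleusLandmarks,
    RNAPointCloud,
    ValidationError,
)

DEFAULT_COLUMNS = {"x": "x", "y": "y", "z": "z", "gene": "gene", "id": "id"}


def read_point_cloud(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    gene_names: list[str] | None = None,
    sep: str | None = None,
) -> RNAPointCloud:
    """Read a molecule table into a validated :class:`RNAPointCloud`.

    Parameters
    ----------
    path : str or Path
        CSV or TSV file with at least x, y and gene columns.
    column_map : dict, optional
        Maps the canonical names ``x, y, z, gene, id`` to the file's
        column names.  A missing ``z`` mapping (or column) yields a 2D
        cloud with z = 0; a missing ``id`` column numbers molecules
        0..n-1 in file order.
    gene_names : list of str, optional
        Fixed gene vocabulary.  Default: first-appearance order.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for key in ("x", "y", "gene"):
        if cols[key] not in df.columns:
            raise ValidationError(f"missing required column '{cols[key]}'")
    n = len(df)
    pos = np.zeros((n, 3))
    for axis, j in (("x", 0), ("y", 1)):
        vals = pd.to_numeric(df[cols[axis]], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(vals)):
            row = int(np.where(~np.isfinite(vals))[0][0])
            raise ValidationError(f"non-finite {axis} coordinate at row {row}")
        pos[:, j] = vals
    if cols["z"] in df.columns:
        vals = pd.to_numeric(df[cols["z"]], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(vals)):
            row = int(np.where(~np.isfinite(vals))[0][0])
            raise ValidationError(f"non-finite z coordinate at row {row}")
        pos[:, 2] = vals
    gene_col = df[cols["gene"]].astype(str)
    if gene_names is None:
        gene_names = list(dict.fromkeys(gene_col))
    lookup = {g: i for i, g in enumerate(gene_names)}
    try:
        genes = np.array([lookup[g] for g in gene_col], dtype=np.int64)
    except KeyError as e:
        raise ValidationError(f"gene {e} not in the supplied vocabulary") from None
    if cols["id"] in df.columns:
        ids = df[cols["id"]].to_numpy(np.int64)
    else:
        ids = np.arange(n, dtype=np.int64)
    return RNAPointCloud(positions=pos, genes=genes, ids=ids, gene_names=gene_names)


def read_nucleus_landmarks(
    path: str | Path,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    column_map: dict[str, str] | None = None,
) -> NucleusLandmarks:
    """Read nuclei from a TIFF label image or an id,x,y[,z] centroid table.

    ``voxel_size`` is µm per voxel along (x, y, z); it only applies to
    raster input (centroid tables are already in µm).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        lab = tifffile.imread(path)
        return NucleusLandmarks.from_label_image(lab, voxel_size)
    cols = {"id": "id", "x": "x", "y": "y", "z": "z"}
    if column_map:
        cols.update(column_map)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for key in ("id", "x", "y"):
        if cols[key] not in df.columns:
            raise ValidationError(f"missing required column '{cols[key]}'")
    ids = df[cols["id"]].to_numpy(np.int64)
    cents = np.zeros((len(df), 3))
    cents[:, 0] = df[cols["x"]].to_numpy(float)
    cents[:, 1] = df[cols["y"]].to_numpy(float)
    if cols["z"] in df.columns:
        cents[:, 2] = df[cols["z"]].to_numpy(float)
    return NucleusLandmarks(nucleus_ids=ids, centroids=cents)


def write_results(
    assignment: CellAssignment,
    profiles: CellProfileMatrix,
    cloud: RNAPointCloud,
    out_dir: str | Path,
    config: ComSegConfig | None = None,
) -> dict[str, Path]:
    """Persist a run: assignment table, MTX count matrix, manifest.

    Writes ``assignment.csv`` (id, x, y, z, gene, cell_id, provenance),
    ``counts.mtx`` + ``cells.txt`` + ``genes.txt``, and ``manifest.json``
    holding the full configuration.  Raises on cell-id mismatch between
    the assignment and the profile matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assigned = set(np.unique(assignment.cell_ids)) - {UNASSIGNED}
    known = set(profiles.cell_ids.tolist())
    if not assigned <= known:
        raise ValidationError(
            f"assignment names cell ids absent from the profile matrix: {sorted(assigned - known)}"
        )
    paths = {}
    df = assignment.to_frame(cloud)
    paths["assignment"] = out_dir / "assignment.csv"
    df.to_csv(paths["assignment"], index=False)
    paths["counts"] = out_dir / "counts.mtx"
    spio.mmwrite(paths["counts"], sparse.coo_matrix(profiles.counts))
    paths["cells"] = out_dir / "cells.txt"
    np.savetxt(paths["cells"], profiles.cell_ids, fmt="%d")
    paths["genes"] = out_dir / "genes.txt"
    Path(paths["genes"]).write_text("\n".join(profiles.gene_names) + "\n")
    manifest = {
        "n_molecules": len(cloud),
        "n_cells": len(profiles.cell_ids),
        "n_assigned": assignment.n_assigned,
        "gene_names": profiles.gene_names,
        "config": config.to_dict() if config is not None else None,
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=float))
    return paths


def read_profiles(out_dir: str | Path) -> CellProfileMatrix:
    """Round-trip reader for the MTX output of :func:`write_results`."""
    out_dir = Path(out_dir)
    counts = sparse.csr_matrix(spio.mmread(out_dir / "counts.mtx"))
    cell_ids = np.loadtxt(out_dir / "cells.txt", dtype=np.int64, ndmin=1)
    genes = (out_dir / "genes.txt").read_text().splitlines()
    return CellProfileMatrix(counts=counts, cell_ids=cell_ids, gene_names=genes)


def read_assignment(path: str | Path) -> pd.DataFrame:
    """Read an assignment table written by :func:`write_results`."""
    return pd.read_csv(path)
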