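"""Proximity-weighted expression and the gene co-expression matrix.

Co-expression is estimated from the image itself.  Around every molecule
``x`` a proximity-weighted expression (PE) vector V(x) is computed: for
each gene g, the sum over the (at most ``k_pe``) nearest neighbors y
within radius ``r_pe`` that carry gene g of the linearly decaying kernel

    (r_pe - ||x - y||) / r_pe

so that a neighbor at the anchor contributes 1 and a neighbor at the
radius contributes 0.  Stacking V(x) over molecules gives the PE matrix;
the gene × gene co-expression matrix W is the Pearson correlation of its
columns.  W can alternatively be imported from external data such as
single-cell RNA sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .config import ComSegConfig
from .datatypes import RNAPointCloud, ValidationError


@dataclass
class CoexpressionMatrix:
    """Symmetric gene × gene correlation matrix aligned to a vocabulary.

    Entries lie in [-1, 1].  Genes whose PE column has zero variance
    (never locally expressed) carry 0 everywhere, including the
    diagonal: they contribute no co-expression evidence.
    """

    weights: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        g = len(self.gene_names)
        if self.weights.shape != (g, g):
            raise ValidationError("co-expression matrix must be gene x gene")

    def __getitem__(self, key):
        return self.weights[key]


def _knn_within(positions: np.ndarray, k: int, radius: float, workers: int = 1):
    """Indices/distances of up to ``k`` nearest neighbors within ``radius``
    for every point, excluding the point itself.  Ties at the k-th
    distance are broken by index (cKDTree's deterministic ordering)."""
    n = len(positions)
    tree = cKDTree(positions)
    k_query = min(k + 1, n)
    dist, idx = tree.query(positions, k=k_query, workers=workers)
    if k_query == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    keep = (idx != np.arange(n)[:, None]) & (dist <= radius) & np.isfinite(dist)
    return dist, idx, keep


def compute_pe_vector(
    cloud: RNAPointCloud, anchor: int, cfg: ComSegConfig
) -> np.ndarray:
    """PE vector of a single molecule (by id), from the definition.

    The anchor is excluded from its own neighborhood; an isolated anchor
    yields the zero vector.
    """
    where = np.where(cloud.ids == anchor)[0]
    if len(where) == 0:
        raise ValidationError(f"molecule id {anchor} not in cloud")
    i = int(where[0])
    pos = cloud.scaled_positions(cfg.z_anisotropy_factor)
    d = np.linalg.norm(pos - pos[i], axis=1)
    d[i] = np.inf
    candidates = np.where(d <= cfg.r_pe)[0]
    order = np.lexsort((candidates, d[candidates]))  # distance, then id
    chosen = candidates[order][: cfg.k_pe]
    v = np.zeros(cloud.n_genes)
    np.add.at(v, cloud.genes[chosen], (cfg.r_pe - d[chosen]) / cfg.r_pe)
    return v


def compute_pe_matrix(cloud: RNAPointCloud, cfg: ComSegConfig) -> np.ndarray:
    """PE matrix (n_molecules × n_genes), rows ordered like the cloud.

    Spatial-index implementation of the per-row definition: row i equals
    :func:`compute_pe_vector` for molecule i up to floating tolerance.
    """
    if len(cloud) == 0:
        raise ValidationError("cannot compute PE matrix of an empty cloud")
    pos = cloud.scaled_positions(cfg.z_anisotropy_factor)
    dist, idx, keep = _knn_within(pos, cfg.k_pe, cfg.r_pe)
    rows, cols = np.nonzero(keep)
    w = (cfg.r_pe - dist[rows, cols]) / cfg.r_pe
    genes = cloud.genes[idx[rows, cols]]
    mat = sparse.coo_matrix(
        (w, (rows, genes)), shape=(len(cloud), cloud.n_genes)
    )
    return np.asarray(mat.todense())


def compute_coexpression(
    pe: np.ndarray, gene_names: list[str]
) -> CoexpressionMatrix:
    """Pearson correlation of PE columns.

    Zero-variance columns get 0 against every gene (diagonal included).
    Requires at least two rows, otherwise correlation is undefined.
    """
    pe = np.asarray(pe, dtype=float)
    if pe.shape[0] < 2:
        raise ValidationError("co-expression needs at least two molecules")
    std = pe.std(axis=0)
    degenerate = std == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.corrcoef(pe, rowvar=False)
    w = np.atleast_2d(w)
    w[degenerate, :] = 0.0
    w[:, degenerate] = 0.0
    w = np.clip(w, -1.0, 1.0)
    w = (w + w.T) / 2
    return CoexpressionMatrix(weights=w, gene_names=list(gene_names))


def import_external_coexpression(
    table: pd.DataFrame, gene_names: list[str], tol: float = 1e-8
) -> CoexpressionMatrix:
    """Validate and align an externally supplied gene × gene matrix.

    The table must be square, symmetric within ``tol``, and its index
    must cover the run's vocabulary; rows/columns are realigned to the
    vocabulary order.
    """
    if table.shape[0] != table.shape[1]:
        raise ValidationError("external co-expression table must be square")
    if list(table.index) != list(table.columns):
        raise ValidationError("row and column gene names must match")
    missing = [g for g in gene_names if g not in table.index]
    if missing:
        raise ValidationError(f"external matrix missing genes: {missing}")
    aligned = table.loc[gene_names, gene_names].to_numpy(float)
    if np.max(np.abs(aligned - aligned.T)) > tol:
        raise ValidationError("external co-expression matrix is not symmetric")
    return CoexpressionMatrix(weights=(aligned + aligned.T) / 2, gene_names=list(gene_names))
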