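"""Core data containers shared by every stage of the pipeline.

All coordinates are physical micrometres.  Raster inputs are converted at
read time using the voxel size, so the physical hyper-parameters (mean
cell diameter, maximum cell radius) apply uniformly regardless of the
acquisition pixel size.  2D data are represented as 3D with z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, ndimage

UNASSIGNED = 0
"""Sentinel cell id for unassigned molecules (matches the label-image
background convention)."""


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class RNAPointCloud:
    """Detected RNA molecules: positions, gene identities, stable ids.

    Attributes
    ----------
    positions : (n, 3) float array
        x, y, z in µm.  2D clouds carry z = 0.
    genes : (n,) int array
        Index of each molecule's gene in ``gene_names``.
    ids : (n,) int array
        Stable unique per-molecule identifiers.
    gene_names : list of str
        Ordered gene vocabulary; fixed for the run.
    """

    positions: np.ndarray
    genes: np.ndarray
    ids: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.genes = np.asarray(self.genes, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be (n, 3)")
        n = len(self.positions)
        if len(self.genes) != n or len(self.ids) != n:
            raise ValidationError("positions, genes and ids must have equal length")
        if not np.all(np.isfinite(self.positions)):
            bad = int(np.where(~np.isfinite(self.positions).all(axis=1))[0][0])
            raise ValidationError(f"non-finite coordinate at row {bad}")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("molecule ids must be unique")
        if n and (self.genes.min() < 0 or self.genes.max() >= len(self.gene_names)):
            raise ValidationError("gene index out of vocabulary range")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def is_2d(self) -> bool:
        return bool(np.all(self.positions[:, 2] == 0))

    def scaled_positions(self, z_factor: float = 1.0) -> np.ndarray:
        """Positions with z multiplied by the anisotropy factor."""
        if z_factor == 1.0:
            return self.positions
        p = self.positions.copy()
        p[:, 2] *= z_factor
        return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "gene": [self.gene_names[g] for g in self.genes],
            }
        )


@dataclass
class NucleusLandmarks:
    """Nucleus positions as a label image, a centroid table, or both.

    The label image uses 0 as background and positive integers as nucleus
    ids; ``voxel_size`` is µm per voxel along (x, y, z) matching the
    array axes (z, y, x) order of the raster.  Centroids are in µm.
    """

    nucleus_ids: np.ndarray
    centroids: np.ndarray  # (n, 3) µm
    label_image: np.ndarray | None = None
    voxel_size: tuple[float, float, float] | None = None  # (x, y, z) µm/voxel

    def __post_init__(self) -> None:
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(np.unique(self.nucleus_ids)) != len(self.nucleus_ids):
            raise ValidationError("duplicate nucleus ids")
        if len(self.nucleus_ids) and self.nucleus_ids.min() <= 0:
            raise ValidationError("nucleus ids must be positive")
        if self.centroids.shape != (len(self.nucleus_ids), 3):
            raise ValidationError("centroids must be (n_nuclei, 3)")

    def __len__(self) -> int:
        return len(self.nucleus_ids)

    @classmethod
    def from_label_image(
        cls, label_image: np.ndarray, voxel_size: tuple[float, float, float]
    ) -> "NucleusLandmarks":
        """Build landmarks from an integer raster; centroids are region
        means converted to µm.  2D rasters are lifted to a single z plane."""
        lab = np.asarray(label_image)
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValidationError("label image must be integer-typed")
        if lab.min() < 0:
            raise ValidationError("negative labels are not allowed")
        if lab.ndim == 2:
            lab = lab[None, :, :]
        ids = np.unique(lab)
        ids = ids[ids > 0]
        vx, vy, vz = voxel_size
        cents = np.zeros((len(ids), 3))
        if len(ids):
            # center_of_mass returns (z, y, x) voxel coordinates
            com = ndimage.center_of_mass(lab > 0, lab, ids)
            com = np.atleast_2d(np.asarray(com))
            cents[:, 0] = com[:, 2] * vx
            cents[:, 1] = com[:, 1] * vy
            cents[:, 2] = com[:, 0] * vz
        return cls(nucleus_ids=ids, centroids=cents, label_image=lab, voxel_size=voxel_size)

    def molecule_nucleus(
        self, cloud: RNAPointCloud, membership_radius: float | None = None
    ) -> np.ndarray:
        """Nucleus id per molecule (0 outside every nucleus).

        Uses raster lookup when a label image is available, otherwise a
        sphere of ``membership_radius`` µm around each centroid.
        """
        n = len(cloud)
        out = np.zeros(n, dtype=np.int64)
        if self.label_image is not None:
            vx, vy, vz = self.voxel_size
            ix = np.floor(cloud.positions[:, 0] / vx).astype(int)
            iy = np.floor(cloud.positions[:, 1] / vy).astype(int)
            iz = np.floor(cloud.positions[:, 2] / vz).astype(int) if vz else np.zeros(n, int)
            nz, ny, nx = self.label_image.shape
            inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
            out[inside] = self.label_image[iz[inside], iy[inside], ix[inside]]
        else:
            if membership_radius is None:
                raise ValueError("membership_radius required for centroid-only landmarks")
            from scipy.spatial import cKDTree

            if len(self):
                tree = cKDTree(self.centroids)
                dist, idx = tree.query(cloud.positions)
                hit = dist <= membership_radius
                out[hit] = self.nucleus_ids[idx[hit]]
        return out


@dataclass
class CellAssignment:
    """The output partition: per-molecule cell id with provenance.

    ``cell_ids`` uses 0 for unassigned molecules.  ``provenance`` holds
    ``"nuclear"`` (molecule inside the cell's nucleus), ``"graph"``
    (claimed through the geodesic assignment) or ``"unassigned"``.
    """

    molecule_ids: np.ndarray
    cell_ids: np.ndarray
    provenance: np.ndarray
    cell_centroids: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.provenance = np.asarray(self.provenance)
        if not (len(self.molecule_ids) == len(self.cell_ids) == len(self.provenance)):
            raise ValidationError("assignment arrays must have equal length")

    def __len__(self) -> int:
        return len(self.molecule_ids)

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.cell_ids != UNASSIGNED))

    def to_frame(self, cloud: RNAPointCloud) -> pd.DataFrame:
        df = cloud.to_frame()
        order = {m: i for i, m in enumerate(self.molecule_ids)}
        idx = np.array([order[m] for m in cloud.ids])
        df["cell_id"] = self.cell_ids[idx]
        df["provenance"] = self.provenance[idx]
        return df


@dataclass
class CellProfileMatrix:
    """Sparse cells × genes count matrix — the deliverable of segmentation."""

    counts: sparse.csr_matrix
    cell_ids: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_names)):
            raise ValidationError("count matrix shape mismatch")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())
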