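"""End-to-end segmentation model.

:class:`ComSegModel` bundles a point cloud, nucleus landmarks and a
configuration; :meth:`ComSegModel.fit` runs the five pipeline stages —

1. proximity-weighted expression matrix,
2. gene co-expression matrix (or an imported external one),
3. co-expression-weighted KNN graph with nucleus-constrained Louvain,
4. in-situ Leiden clustering of community expression → domain map,
5. centroid labeling and geodesic RNA-to-cell assignment —

and returns a :class:`ComSegResults` holding the assignment, the
single-cell profile matrix and all intermediates, with ``summary()``
and ``save()`` helpers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as _assign
from . import clustering as _clust
from . import coexpression as _coexpr
from . import graph as _graph
from . import io as _io
from .config import ComSegConfig
from .datatypes import (
    UNASSIGNED,
    CellAssignment,
    CellProfileMatrix,
    NucleusLandmarks,
    RNAPointCloud,
)


@dataclass
class ComSegResults:
    """Fitted segmentation: assignment, profiles and diagnostics."""

    model: "ComSegModel"
    assignment: CellAssignment
    profiles: CellProfileMatrix
    domain_map: _clust.TranscriptomicDomainMap
    partition: _graph.CommunityPartition
    coexpression: _coexpr.CoexpressionMatrix
    pe_matrix: np.ndarray
    centroids: list

    @property
    def n_cells(self) -> int:
        return len(self.profiles.cell_ids)

    @property
    def n_assigned(self) -> int:
        return self.assignment.n_assigned

    @property
    def n_unassigned(self) -> int:
        return len(self.assignment) - self.n_assigned

    def summary(self) -> str:
        counts = np.asarray(self.profiles.counts.sum(axis=1)).ravel()
        lines = [
            "ComSeg segmentation results",
            "===========================",
            f"molecules:            {len(self.assignment)}",
            f"genes:                {len(self.profiles.gene_names)}",
            f"cells (nuclei):       {self.n_cells}",
            f"assigned molecules:   {self.n_assigned}"
            f" ({100 * self.n_assigned / max(len(self.assignment), 1):.1f}%)",
            f"unassigned molecules: {self.n_unassigned}",
            f"communities:          {len(self.partition.communities)}",
            f"profile labels:       {self.domain_map.n_labels}",
            f"modularity Q:         {self.partition.modularity:.4f}",
            f"mean counts per cell: {counts.mean():.2f}",
        ]
        return "\n".join(lines)

    def assignment_frame(self) -> pd.DataFrame:
        df = self.assignment.to_frame(self.model.cloud)
        df["profile_label"] = self.domain_map.molecule_labels
        return df

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        return _io.write_results(
            self.assignment, self.profiles, self.model.cloud, out_dir, self.model.config
        )


class ComSegModel:
    """Graph-based RNA-to-cell assignment from coordinates and nuclei.

    Parameters
    ----------
    cloud : RNAPointCloud
        Detected molecules (µm coordinates + gene identities).
    landmarks : NucleusLandmarks
        Nucleus label image or centroid table.
    config : ComSegConfig
        Hyper-parameters; the two that matter are the mean cell
        diameter D and the maximum cell radius.
    coexpression : CoexpressionMatrix, optional
        External gene × gene co-expression; computed from the image
        when omitted.
    """

    def __init__(
        self,
        cloud: RNAPointCloud,
        landmarks: NucleusLandmarks,
        config: ComSegConfig,
        coexpression: _coexpr.CoexpressionMatrix | None = None,
    ) -> None:
        self.cloud = cloud
        self.landmarks = landmarks
        self.config = config
        self.external_coexpression = coexpression

    @classmethod
    def from_files(
        cls,
        points_path: str | Path,
        nuclei_path: str | Path,
        config: ComSegConfig,
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
        column_map: dict[str, str] | None = None,
    ) -> "ComSegModel":
        cloud = _io.read_point_cloud(points_path, column_map=column_map)
        landmarks = _io.read_nucleus_landmarks(nuclei_path, voxel_size=voxel_size)
        return cls(cloud, landmarks, config)

    def fit(self) -> ComSegResults:
        cfg = self.config
        pe = _coexpr.compute_pe_matrix(self.cloud, cfg)
        if self.external_coexpression is not None:
            W = self.external_coexpression
        else:
            W = _coexpr.compute_coexpression(pe, self.cloud.gene_names)
        g = _graph.build_graph(self.cloud, W, cfg)
        merged, member_of = _graph.merge_landmark_nodes(g, self.landmarks, self.cloud, cfg)
        partition = _graph.louvain_with_priors(merged, cfg)
        expr = _clust.community_expression(partition, pe, self.cloud, merged)
        comm_labels, centroids_x = _clust.cluster_communities(expr, cfg)
        dmap = _clust.build_domain_map(
            expr, comm_labels, centroids_x, partition, merged, self.cloud
        )
        dmap = _clust.relabel_small_communities(
            dmap, expr, partition, merged, self.cloud, cfg
        )
        cents = _assign.label_centroids(dmap, self.landmarks, merged, self.cloud, cfg)
        assignment = _assign.geodesic_assign(
            merged, cents, dmap, self.cloud, member_of, cfg
        )
        profiles = _assign.profiles_from_assignment(
            assignment, self.cloud, cell_ids=np.asarray(self.landmarks.nucleus_ids)
        )
        return ComSegResults(
            model=self,
            assignment=assignment,
            profiles=profiles,
            domain_map=dmap,
            partition=partition,
            coexpression=W,
            pe_matrix=pe,
            centroids=cents,
        )
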