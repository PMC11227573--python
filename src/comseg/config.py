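"""Run configuration.

The method exposes two physical hyper-parameters: the mean cell diameter
``D`` and the maximum cell radius ``r_max`` (both in µm).  Every other
length scale is derived from ``D``:

========================  =========  ============================================
derived radius            value      role
========================  =========  ============================================
``r_pe``                  D / 2      neighborhood for proximity-weighted expression
``r_knn``                 D / 4      maximum edge length of the molecule graph
``r_centroid``            D / 2      neighborhood for labeling empty-nucleus centroids
========================  =========  ============================================

The neighbor caps (``k_pe`` = 40, ``k_knn`` = 10, ``k_centroid`` = 15) are
fixed defaults that have little influence on the output and rarely need
changing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class ComSegConfig:
    """Parameters controlling every stage of the pipeline.

    Parameters
    ----------
    mean_cell_diameter : float
        Mean cell diameter ``D`` in µm.  All derived radii recompute from
        this value automatically.
    max_cell_radius : float, optional
        Geodesic cut-off ``r_max`` in µm beyond which a molecule is left
        unassigned.  Defaults to ``D`` (one diameter).
    k_pe : int
        Neighbor cap for the proximity-weighted expression vector.
    k_knn : int
        Neighbor count of the molecule KNN graph.
    k_centroid : int
        Neighbors consulted when voting a profile label for a centroid
        whose nucleus contains no RNA.
    k_small : int, optional
        Neighbors consulted when relabeling communities below the
        clustering size threshold; defaults to ``k_knn``.
    leiden_resolution : float
        Resolution of the Leiden clustering of community expression
        vectors.
    pca_gene_threshold : int
        Apply PCA before Leiden when the panel exceeds this many genes.
    pca_components : int
        Components retained when PCA is applied (capped at ``n_genes - 1``).
    min_community_size : int
        Communities with fewer molecules are not clustered directly; they
        inherit the majority label of nearby labeled molecules.
    cluster_merge_threshold : float or None
        After Leiden, clusters whose expression centroids have cosine
        similarity at or above this value are merged (single linkage).
        Leiden on sparse KNN graphs tends to split homogeneous profiles;
        merging near-identical centroids restores one label per
        expression profile.  None disables merging.
    z_anisotropy_factor : float
        Multiplier applied to z before any distance computation, for
        stacks whose axial spacing differs from the lateral pixel size.
    centroid_membership_radius : float, optional
        When nuclei are given as centroids only (no label image), a
        molecule within this radius of a centroid counts as nuclear.
        Defaults to ``D / 4``.
    label_constrained_paths : bool
        If True (default), geodesic assignment only travels through
        molecules sharing the source centroid's profile label.
    seed : int
        Seed propagated to every stochastic step (Louvain sweep order,
        Leiden, sub-sampling).
    """

    mean_cell_diameter: float
    max_cell_radius: float | None = None
    k_pe: int = 40
    k_knn: int = 10
    k_centroid: int = 15
    k_small: int | None = None
    leiden_resolution: float = 1.0
    pca_gene_threshold: int = 30
    pca_components: int = 20
    min_community_size: int = 3
    cluster_merge_threshold: float | None = 0.9
    z_anisotropy_factor: float = 1.0
    centroid_membership_radius: float | None = None
    label_constrained_paths: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean_cell_diameter > 0:
            raise ValueError("mean_cell_diameter must be positive")
        if self.max_cell_radius is None:
            self.max_cell_radius = float(self.mean_cell_diameter)
        if self.max_cell_radius < self.mean_cell_diameter / 2:
            raise ValueError("max_cell_radius must be at least D/2")
        for name in ("k_pe", "k_knn", "k_centroid"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.k_small is None:
            self.k_small = self.k_knn
        if self.centroid_membership_radius is None:
            self.centroid_membership_radius = self.mean_cell_diameter / 4

    # Radii derived from D; recomputed on access so that updating D keeps
    # everything consistent.
    @property
    def r_pe(self) -> float:
        """Radius of the proximity-expression neighborhood (D/2, µm)."""
        return self.mean_cell_diameter / 2

    @property
    def r_knn(self) -> float:
        """Maximum edge length of the molecule graph (D/4, µm)."""
        return self.mean_cell_diameter / 4

    @property
    def r_centroid(self) -> float:
        """Radius of the centroid labeling neighborhood (D/2, µm)."""
        return self.mean_cell_diameter / 2

    def to_dict(self) -> dict:
        """All parameters (including derived radii) for the run manifest."""
        d = asdict(self)
        d.update(r_pe=self.r_pe, r_knn=self.r_knn, r_centroid=self.r_centroid)
        return d
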