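"""Segmentation-free in-situ clustering of RNA communities.

Each community C receives an expression vector V_C, the arithmetic mean
of the proximity-weighted expression vectors of its member molecules.
Communities with at least ``min_community_size`` molecules are clustered
in expression space — total-sum scaling to the median community total,
log1p, optional PCA for large panels, a cosine KNN graph, then Leiden —
and every molecule inherits its community's cluster as a profile label
L_i.  Communities too small to carry a reliable expression vector are
relabeled afterwards by a majority vote over the spatially nearest
labeled molecules.  The labeled point cloud is the transcriptomic
domain map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import ComSegConfig
from .datatypes import RNAPointCloud, ValidationError
from .graph import CommunityPartition, expand_members

UNLABELED = -1


@dataclass
class CommunityExpression:
    """Per-community mean PE vectors with sizes and spatial centroids."""

    community_ids: np.ndarray
    vectors: np.ndarray  # (n_communities, n_genes)
    sizes: np.ndarray  # number of member molecules
    centroids: np.ndarray  # (n_communities, 3) µm


@dataclass
class TranscriptomicDomainMap:
    """Profile labels L_i per community and per molecule.

    ``molecule_labels`` is aligned with the cloud's molecule order;
    UNLABELED (-1) marks molecules whose community has not been labeled
    yet (resolved by :func:`relabel_small_communities`).
    """

    community_labels: dict[int, int]
    molecule_labels: np.ndarray
    cluster_centroids: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    @property
    def n_labels(self) -> int:
        labs = [l for l in self.community_labels.values() if l != UNLABELED]
        return len(set(labs))


def community_expression(
    partition: CommunityPartition,
    pe: np.ndarray,
    cloud: RNAPointCloud,
    graph,
) -> CommunityExpression:
    """Mean PE vector, size and spatial centroid of every community.

    Cell nodes contribute the PE rows of the molecules they absorbed.
    Communities that contain no molecule at all (a bare cell node from
    an RNA-free nucleus) are skipped — they have no expression.
    """
    row_of = {int(m): i for i, m in enumerate(cloud.ids)}
    members = expand_members(partition, graph)
    ids, vecs, sizes, cents = [], [], [], []
    for c in sorted(members):
        mols = members[c]
        if not mols:
            continue
        rows = [row_of[m] for m in mols]
        ids.append(c)
        vecs.append(pe[rows].mean(axis=0))
        sizes.append(len(rows))
        cents.append(cloud.positions[rows].mean(axis=0))
    return CommunityExpression(
        community_ids=np.array(ids, dtype=int),
        vectors=np.array(vecs) if vecs else np.zeros((0, pe.shape[1])),
        sizes=np.array(sizes, dtype=int),
        centroids=np.array(cents) if cents else np.zeros((0, 3)),
    )


def _normalize_vectors(vectors: np.ndarray) -> np.ndarray:
    """Total-sum scaling to the median community total, then log1p."""
    totals = vectors.sum(axis=1)
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    scale = np.divide(target, totals, out=np.ones_like(totals), where=totals > 0)
    return np.log1p(vectors * scale[:, None])


def cluster_communities(
    expr: CommunityExpression,
    cfg: ComSegConfig,
    cloud_labels_out: np.ndarray | None = None,
) -> tuple[dict[int, int], np.ndarray]:
    """Leiden-cluster the expression vectors of large-enough communities.

    Returns (community id → label) for communities of size ≥
    ``cfg.min_community_size`` plus the cluster centroid matrix (in
    normalized expression space).  Small communities are left out and
    labeled by :func:`relabel_small_communities`.
    """
    big = expr.sizes >= cfg.min_community_size
    if not np.any(big):
        raise ValidationError(
            "no community reaches the clustering size threshold; "
            "consider a larger mean cell diameter"
        )
    vectors = expr.vectors[big]
    x = _normalize_vectors(vectors)
    n, n_genes = x.shape
    if n_genes > cfg.pca_gene_threshold and n > 2:
        n_comp = min(n_genes - 1, cfg.pca_components, n - 1)
        x = PCA(n_components=n_comp, random_state=cfg.seed).fit_transform(x)
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        # cosine KNN graph in expression space (edges weighted by cosine
        # similarity so dissimilar near-neighbors do not glue clusters
        # together when n is small), then Leiden
        k = min(15, n - 1)
        norms = np.linalg.norm(x, axis=1)
        safe = x.copy()
        safe[norms == 0] = 1.0  # zero vectors: treat as uniform direction
        nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(safe)
        dist, idx = nn.kneighbors(safe)
        edges: dict[tuple[int, int], float] = {}
        for i in range(n):
            for j_pos in range(1, idx.shape[1]):
                j = int(idx[i, j_pos])
                sim = max(1.0 - float(dist[i, j_pos]), 0.0)
                edges[(min(i, j), max(i, j))] = sim
        pairs = sorted(edges)
        g = igraph.Graph(n=n, edges=pairs)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=[edges[p] for p in pairs],
            resolution_parameter=cfg.leiden_resolution,
            seed=cfg.seed,
            n_iterations=-1,
        )
        labels = np.asarray(part.membership, dtype=int)
    if cfg.cluster_merge_threshold is not None:
        labels = _merge_similar_clusters(
            _normalize_vectors(vectors), labels, cfg.cluster_merge_threshold
        )
    comm_labels = {
        int(c): int(l) for c, l in zip(expr.community_ids[big], labels)
    }
    centroids = np.vstack(
        [_normalize_vectors(vectors)[labels == l].mean(axis=0) for l in np.unique(labels)]
    )
    return comm_labels, centroids


def _merge_similar_clusters(x: np.ndarray, labels: np.ndarray, threshold: float) -> np.ndarray:
    """Single-linkage merge of clusters whose centroids have cosine
    similarity ≥ ``threshold``; returns contiguous relabeled labels."""
    uniq = np.unique(labels)
    cents = np.vstack([x[labels == l].mean(axis=0) for l in uniq])
    norms = np.linalg.norm(cents, axis=1)
    norms[norms == 0] = 1.0
    sim = (cents @ cents.T) / np.outer(norms, norms)
    g = igraph.Graph(
        n=len(uniq),
        edges=[(i, j) for i in range(len(uniq)) for j in range(i + 1, len(uniq)) if sim[i, j] >= threshold],
    )
    comp = np.asarray(g.connected_components().membership)
    mapping = {int(l): int(comp[i]) for i, l in enumerate(uniq)}
    merged = np.array([mapping[int(l)] for l in labels])
    _, merged = np.unique(merged, return_inverse=True)
    return merged


def build_domain_map(
    expr: CommunityExpression,
    comm_labels: dict[int, int],
    centroids: np.ndarray,
    partition: CommunityPartition,
    graph,
    cloud: RNAPointCloud,
) -> TranscriptomicDomainMap:
    """Project community labels onto molecules (UNLABELED where absent)."""
    row_of = {int(m): i for i, m in enumerate(cloud.ids)}
    members = expand_members(partition, graph)
    mol_labels = np.full(len(cloud), UNLABELED, dtype=int)
    all_labels = {int(c): comm_labels.get(int(c), UNLABELED) for c in members}
    for c, mols in members.items():
        lab = all_labels[int(c)]
        for m in mols:
            mol_labels[row_of[m]] = lab
    return TranscriptomicDomainMap(
        community_labels=all_labels,
        molecule_labels=mol_labels,
        cluster_centroids=centroids,
    )


def majority_label_vote(
    query: np.ndarray,
    labeled_positions: np.ndarray,
    labels: np.ndarray,
    k: int,
    radius: float | None = None,
) -> int:
    """Majority label among the ≤ k nearest labeled molecules to ``query``.

    Ties break toward the label of the single nearest molecule.  Returns
    UNLABELED when no labeled molecule qualifies (empty neighborhood).
    """
    if len(labeled_positions) == 0:
        return UNLABELED
    tree = cKDTree(labeled_positions)
    k_eff = min(k, len(labeled_positions))
    dist, idx = tree.query(query, k=k_eff)
    dist = np.atleast_1d(dist)
    idx = np.atleast_1d(idx)
    if radius is not None:
        keep = dist <= radius
        dist, idx = dist[keep], idx[keep]
    if len(idx) == 0:
        return UNLABELED
    votes = labels[idx]
    counts = np.bincount(votes)
    winners = np.where(counts == counts.max())[0]
    if len(winners) == 1:
        return int(winners[0])
    nearest_label = int(votes[np.argmin(dist)])
    return nearest_label if nearest_label in winners else int(winners[0])


def relabel_small_communities(
    domain_map: TranscriptomicDomainMap,
    expr: CommunityExpression,
    partition: CommunityPartition,
    graph,
    cloud: RNAPointCloud,
    cfg: ComSegConfig,
) -> TranscriptomicDomainMap:
    """Give unlabeled (small) communities the majority label of the
    ``cfg.k_small`` labeled molecules nearest to their spatial centroid."""
    labeled = domain_map.molecule_labels != UNLABELED
    if not np.any(labeled):
        raise ValidationError("no labeled molecules to vote from")
    labeled_pos = cloud.positions[labeled]
    labeled_lab = domain_map.molecule_labels[labeled]
    row_of = {int(m): i for i, m in enumerate(cloud.ids)}
    members = expand_members(partition, graph)
    cent_of = dict(zip(expr.community_ids.tolist(), expr.centroids))
    new_comm = dict(domain_map.community_labels)
    new_mol = domain_map.molecule_labels.copy()
    for c, lab in domain_map.community_labels.items():
        if lab != UNLABELED or not members[c]:
            continue
        centroid = cent_of[c]
        vote = majority_label_vote(centroid, labeled_pos, labeled_lab, cfg.k_small)
        new_comm[c] = vote
        for m in members[c]:
            new_mol[row_of[m]] = vote
    return TranscriptomicDomainMap(
        community_labels=new_comm,
        molecule_labels=new_mol,
        cluster_centroids=domain_map.cluster_centroids,
    )
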