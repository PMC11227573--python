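"""Final RNA-to-cell assignment by same-label geodesic proximity.

Every nucleus contributes a centroid node (its cell node in the merged
graph, positioned at the nucleus centroid).  The centroid takes the
profile label of its nuclear RNAs; an RNA-free nucleus takes the
majority label of the ≤ ``k_centroid`` molecules within ``r_centroid``
of its centroid.  Each labeled centroid then claims the molecules of
its own label by shortest-path (geodesic) distance through the molecule
graph, Euclidean edge lengths, computed with multi-source Dijkstra.
Molecules farther than ``max_cell_radius`` from every same-label
centroid stay unassigned.  Geodesic rather than straight-line distance
lets non-convex cells claim their distant arms and respects lacunar
spaces in the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .clustering import UNLABELED, TranscriptomicDomainMap, majority_label_vote
from .config import ComSegConfig
from .datatypes import (
    UNASSIGNED,
    CellAssignment,
    CellProfileMatrix,
    NucleusLandmarks,
    RNAPointCloud,
)
from .graph import cell_node_key, is_cell_node


@dataclass
class CentroidNode:
    """A labeled cell centroid ready to claim molecules."""

    cell_id: int
    position: np.ndarray
    label: int  # UNLABELED when no molecule is near an RNA-free nucleus
    provenance: str  # "nuclear-rna" | "neighbor-vote" | "label-less"


def label_centroids(
    domain_map: TranscriptomicDomainMap,
    landmarks: NucleusLandmarks,
    graph: nx.Graph,
    cloud: RNAPointCloud,
    cfg: ComSegConfig,
) -> list[CentroidNode]:
    """Assign a profile label to every nucleus centroid.

    Nuclei with nuclear RNAs take the majority label of those RNAs
    (ties toward the label of the RNA nearest the centroid).  RNA-free
    nuclei take the majority label of the ≤ ``k_centroid`` nearest
    molecules within ``r_centroid`` (Euclidean).  Nuclei with no
    molecule in reach are label-less and will produce empty cells.
    """
    row_of = {int(m): i for i, m in enumerate(cloud.ids)}
    out: list[CentroidNode] = []
    for n_idx, nucleus in enumerate(landmarks.nucleus_ids):
        cn = cell_node_key(nucleus)
        centroid = landmarks.centroids[n_idx]
        members = graph.nodes[cn]["members"] if cn in graph else []
        label, prov = UNLABELED, "label-less"
        if members:
            rows = np.array([row_of[m] for m in members])
            label = majority_label_vote(
                centroid,
                cloud.positions[rows],
                domain_map.molecule_labels[rows],
                k=len(rows),
            )
            prov = "nuclear-rna"
        else:
            labeled = domain_map.molecule_labels != UNLABELED
            label = majority_label_vote(
                centroid,
                cloud.positions[labeled],
                domain_map.molecule_labels[labeled],
                k=cfg.k_centroid,
                radius=cfg.r_centroid,
            )
            prov = "neighbor-vote" if label != UNLABELED else "label-less"
        out.append(
            CentroidNode(cell_id=int(nucleus), position=centroid, label=label, provenance=prov)
        )
    return out


def geodesic_assign(
    graph: nx.Graph,
    centroids: list[CentroidNode],
    domain_map: TranscriptomicDomainMap,
    cloud: RNAPointCloud,
    member_of: np.ndarray,
    cfg: ComSegConfig,
) -> CellAssignment:
    """Assign each molecule to the nearest same-label centroid by
    geodesic distance, cutting off at ``cfg.max_cell_radius``.

    Nuclear molecules are assigned to their own nucleus unconditionally.
    With ``cfg.label_constrained_paths`` (default) paths may only travel
    through molecules carrying the source label, so a cell cannot tunnel
    through foreign transcriptomic territory; set it to False to allow
    paths through any molecule.  Exact distance ties break toward the
    smaller cell id.
    """
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n_nodes = len(nodes)
    row_of = {int(m): i for i, m in enumerate(cloud.ids)}
    pos = cloud.scaled_positions(cfg.z_anisotropy_factor)

    rows_, cols_, vals_ = [], [], []
    for u, v, data in graph.edges(data=True):
        iu, iv = index[u], index[v]
        rows_ += [iu, iv]
        cols_ += [iv, iu]
        vals_ += [data["euclid_length"]] * 2
    # RNA-free nuclei: bridge their bare cell node to nearby molecules so
    # the centroid can claim RNAs at all (same rule as its labeling).
    free_nodes = [nd for nd in nodes if not is_cell_node(nd)]
    free_rows = np.array([row_of[nd] for nd in free_nodes], dtype=int)
    if len(free_rows):
        tree = cKDTree(pos[free_rows])
    for c in centroids:
        cn = cell_node_key(c.cell_id)
        if cn not in index or graph.nodes[cn]["members"] or not len(free_rows):
            continue
        centroid_scaled = c.position * np.array([1.0, 1.0, cfg.z_anisotropy_factor])
        k_eff = min(cfg.k_centroid, len(free_rows))
        dist, idx = tree.query(centroid_scaled, k=k_eff)
        dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
        for d_, j_ in zip(dist, idx):
            if d_ > cfg.r_centroid:
                continue
            iu, iv = index[cn], index[free_nodes[int(j_)]]
            rows_ += [iu, iv]
            cols_ += [iv, iu]
            vals_ += [float(d_)] * 2
    adj = sparse.coo_matrix((vals_, (rows_, cols_)), shape=(n_nodes, n_nodes)).tocsr()

    node_label = np.full(n_nodes, UNLABELED, dtype=int)
    is_mol = np.zeros(n_nodes, dtype=bool)
    for i, nd in enumerate(nodes):
        if is_cell_node(nd):
            continue
        is_mol[i] = True
        node_label[i] = domain_map.molecule_labels[row_of[nd]]

    cell_ids = np.zeros(len(cloud), dtype=np.int64)
    geodesic = np.full(len(cloud), np.inf)
    provenance = np.full(len(cloud), "unassigned", dtype=object)

    by_label: dict[int, list[CentroidNode]] = {}
    for c in centroids:
        if c.label != UNLABELED:
            by_label.setdefault(c.label, []).append(c)

    for label, cents in by_label.items():
        cents = sorted(cents, key=lambda c: c.cell_id)
        src_idx = [index[cell_node_key(c.cell_id)] for c in cents if cell_node_key(c.cell_id) in index]
        src_cells = [c.cell_id for c in cents if cell_node_key(c.cell_id) in index]
        if not src_idx:
            continue
        if cfg.label_constrained_paths:
            allowed = (is_mol & (node_label == label)).copy()
        else:
            allowed = is_mol.copy()
        for i in src_idx:
            allowed[i] = True
        sub = np.where(allowed)[0]
        sub_pos = {g: i for i, g in enumerate(sub)}
        sub_adj = adj[sub][:, sub]
        sources = [sub_pos[i] for i in src_idx]
        dmat = dijkstra(sub_adj, directed=False, indices=sources)
        for j, g in enumerate(sub):
            nd = nodes[g]
            if is_cell_node(nd) or node_label[g] != label:
                continue
            dcol = dmat[:, j]
            dmin = dcol.min()
            if not np.isfinite(dmin) or dmin > cfg.max_cell_radius:
                continue
            winner = min(src_cells[s] for s in range(len(sources)) if dcol[s] == dmin)
            r = row_of[nd]
            if dmin < geodesic[r]:
                geodesic[r] = dmin
                cell_ids[r] = winner
                provenance[r] = "graph"

    # nuclear molecules override everything: they belong to their nucleus
    nuclear = member_of > 0
    cell_ids[nuclear] = member_of[nuclear]
    geodesic[nuclear] = 0.0
    provenance[nuclear] = "nuclear"

    return CellAssignment(
        molecule_ids=cloud.ids,
        cell_ids=cell_ids,
        provenance=np.asarray(provenance, dtype=object),
        cell_centroids={c.cell_id: c.position for c in centroids},
    )


def profiles_from_assignment(
    assignment: CellAssignment,
    cloud: RNAPointCloud,
    cell_ids: np.ndarray | None = None,
) -> CellProfileMatrix:
    """Cells × genes integer counts; unassigned molecules excluded.

    ``cell_ids`` fixes the row order (cells without molecules keep zero
    rows); defaults to the centroid ids recorded in the assignment.
    """
    if cell_ids is None:
        if assignment.cell_centroids:
            cell_ids = np.array(sorted(assignment.cell_centroids), dtype=np.int64)
        else:
            present = np.unique(assignment.cell_ids)
            cell_ids = present[present != UNASSIGNED]
    row_lookup = {int(c): i for i, c in enumerate(cell_ids)}
    order = {int(m): i for i, m in enumerate(assignment.molecule_ids)}
    rows, cols = [], []
    for i, m in enumerate(cloud.ids):
        c = int(assignment.cell_ids[order[int(m)]])
        if c == UNASSIGNED or c not in row_lookup:
            continue
        rows.append(row_lookup[c])
        cols.append(int(cloud.genes[i]))
    counts = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(cell_ids), cloud.n_genes),
    ).tocsr()
    return CellProfileMatrix(counts=counts, cell_ids=cell_ids, gene_names=cloud.gene_names)
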