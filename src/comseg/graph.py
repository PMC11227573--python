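"""Molecule graph construction and landmark-constrained community detection.

The RNA point cloud becomes an undirected KNN graph (union of directed
k-nearest relations, ``k_knn`` neighbors, edges no longer than
``r_knn`` = D/4).  Each edge carries two weights: the co-expression
weight W[g_u, g_v] of the two genes, used by modularity, and the
Euclidean length in µm, used later for geodesic assignment.

Nuclei enter as priors: all molecules inside one nucleus are contracted
into a single "cell node".  A modified Louvain then partitions the
graph, with the constraint that two cell nodes can never end up in the
same community — each community belongs to at most one cell.  Only
positively weighted edges contribute to modularity; negative
co-expression (genes from different cell types) never drives a merge.

Node convention: molecule nodes are keyed by their (non-negative)
molecule id; the cell node of nucleus ``n`` is keyed by ``-n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import ComSegConfig
from .coexpression import CoexpressionMatrix, _knn_within
from .datatypes import NucleusLandmarks, RNAPointCloud, ValidationError


def cell_node_key(nucleus_id: int) -> int:
    return -int(nucleus_id)


def is_cell_node(node: int) -> bool:
    return node < 0


def build_graph(
    cloud: RNAPointCloud, W: CoexpressionMatrix, cfg: ComSegConfig
) -> nx.Graph:
    """Undirected KNN graph over molecules with dual edge weights.

    Each molecule links to its ≤ ``k_knn`` nearest neighbors within
    ``r_knn`` (after z-anisotropy scaling); the union of the directed
    relations is kept.  ``coexpr_weight`` = W[g_u, g_v];
    ``euclid_length`` = pairwise distance in µm.
    """
    if W.gene_names != cloud.gene_names:
        raise ValidationError("co-expression matrix not aligned to the cloud vocabulary")
    if len(cloud) and cloud.ids.min() < 0:
        raise ValidationError("molecule ids must be non-negative")
    pos = cloud.scaled_positions(cfg.z_anisotropy_factor)
    g = nx.Graph()
    for i in range(len(cloud)):
        g.add_node(
            int(cloud.ids[i]),
            gene=int(cloud.genes[i]),
            position=cloud.positions[i],
            is_cell=False,
        )
    if len(cloud) > 1:
        dist, idx, keep = _knn_within(pos, cfg.k_knn, cfg.r_knn)
        rows, cols = np.nonzero(keep)
        for r, c in zip(rows, cols):
            u = int(cloud.ids[r])
            v = int(cloud.ids[idx[r, c]])
            if g.has_edge(u, v):
                continue
            g.add_edge(
                u,
                v,
                coexpr_weight=float(W.weights[cloud.genes[r], cloud.genes[idx[r, c]]]),
                euclid_length=float(dist[r, c]),
            )
    return g


def merge_landmark_nodes(
    graph: nx.Graph,
    landmarks: NucleusLandmarks,
    cloud: RNAPointCloud,
    cfg: ComSegConfig,
) -> tuple[nx.Graph, np.ndarray]:
    """Contract all molecules of each nucleus into one cell node.

    Membership uses raster lookup when a label image is available,
    otherwise a sphere of ``cfg.centroid_membership_radius`` around each
    centroid (each molecule belongs to at most one nucleus — the nearest
    — by construction).  Contracted parallel edges sum their
    co-expression weights; their Euclidean length is the minimum of the
    merged lengths (the shortest physical link to the nucleus).
    Self-edges inside a nucleus are dropped.  Nuclei without molecules
    still yield (isolated) cell nodes.

    Returns the merged graph and the per-molecule nucleus id array
    (0 = extranuclear).
    """
    member_of = landmarks.molecule_nucleus(cloud, cfg.centroid_membership_radius)
    g = graph.copy()
    id_to_nucleus = dict(zip(cloud.ids.tolist(), member_of.tolist()))
    for n_idx, nucleus in enumerate(landmarks.nucleus_ids):
        cn = cell_node_key(nucleus)
        members = [int(m) for m in cloud.ids[member_of == nucleus]]
        g.add_node(
            cn,
            is_cell=True,
            nucleus=int(nucleus),
            position=landmarks.centroids[n_idx],
            members=members,
        )
    for u, v, data in graph.edges(data=True):
        nu = id_to_nucleus.get(u, 0)
        nv = id_to_nucleus.get(v, 0)
        if nu == 0 and nv == 0:
            continue
        uu = cell_node_key(nu) if nu else u
        vv = cell_node_key(nv) if nv else v
        g.remove_edge(u, v)
        if uu == vv:
            continue  # intranuclear edge → self-loop, dropped
        if g.has_edge(uu, vv):
            g[uu][vv]["coexpr_weight"] += data["coexpr_weight"]
            g[uu][vv]["euclid_length"] = min(
                g[uu][vv]["euclid_length"], data["euclid_length"]
            )
        else:
            g.add_edge(uu, vv, **dict(data))
    g.remove_nodes_from([m for m, n in id_to_nucleus.items() if n != 0])
    return g, member_of


@dataclass
class CommunityPartition:
    """A partition of the (merged) graph into communities.

    ``membership`` maps graph node → community id; ``communities`` the
    inverse; ``community_nucleus`` holds the nucleus id of the single
    cell node a community may contain (0 if none); ``modularity`` the
    final Q; ``q_history`` the Q value after each Louvain pass.
    """

    membership: dict[int, int]
    communities: dict[int, list[int]] = field(init=False)
    community_nucleus: dict[int, int] = field(init=False)
    modularity: float = 0.0
    q_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.communities = {}
        self.community_nucleus = {}
        for node, c in self.membership.items():
            self.communities.setdefault(c, []).append(node)
            if is_cell_node(node):
                if self.community_nucleus.get(c, 0):
                    raise ValidationError("two cell nodes share a community")
                self.community_nucleus[c] = -node
            else:
                self.community_nucleus.setdefault(c, 0)


def _positive_arrays(graph: nx.Graph):
    """Index the graph for modularity: nodes, positive-weight adjacency."""
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adj: list[dict[int, float]] = [dict() for _ in nodes]
    for u, v, data in graph.edges(data=True):
        w = data["coexpr_weight"]
        if w <= 0 or u == v:
            continue
        iu, iv = index[u], index[v]
        adj[iu][iv] = adj[iu].get(iv, 0.0) + w
        adj[iv][iu] = adj[iv].get(iu, 0.0) + w
    return nodes, index, adj


def modularity(graph: nx.Graph, partition: CommunityPartition) -> float:
    """Newman modularity Q of a partition over the positive-weight graph.

    Q = 1/(2m) Σ_{u,v} [w_{uv} − k_u k_v / (2m)] δ(C_u, C_v), summed over
    ordered node pairs; k_u is the positive-weighted degree and m the
    total positive edge weight.  With no positive edges Q = 0 by
    convention.
    """
    missing = [n for n in graph.nodes if n not in partition.membership]
    if missing:
        raise ValidationError(f"partition misses nodes: {missing[:5]}")
    nodes, index, adj = _positive_arrays(graph)
    k = np.array([sum(a.values()) for a in adj])
    m = k.sum() / 2
    if m == 0:
        return 0.0
    comm = np.array([partition.membership[n] for n in nodes])
    intra = 0.0
    for iu, a in enumerate(adj):
        for iv, w in a.items():
            if comm[iu] == comm[iv]:
                intra += w  # ordered pairs: each edge counted twice overall
    q = intra / (2 * m)
    for c in np.unique(comm):
        tot = k[comm == c].sum()
        q -= (tot / (2 * m)) ** 2
    return float(q)


def _level_modularity(adj, self_w, k, node_comm, m) -> float:
    intra = 0.0
    for u, a in enumerate(adj):
        intra += 2 * self_w[u]
        for v, w in a.items():
            if node_comm[u] == node_comm[v]:
                intra += w
    q = intra / (2 * m)
    tot = {}
    for u, c in enumerate(node_comm):
        tot[c] = tot.get(c, 0.0) + k[u]
    return q - sum((t / (2 * m)) ** 2 for t in tot.values())


def _one_level(adj, self_w, has_cell, k, m, rng, init=None) -> tuple[np.ndarray, bool]:
    """One local-moving phase.  Returns (community per node, any move made).

    Nodes are swept in seeded random order (reshuffled each sweep) and
    greedily moved to the community with the largest modularity gain;
    candidates are the neighboring communities plus an empty community
    (isolation), so the converged state is a local optimum over every
    possible single-node move.  Ties break toward the smallest
    community id.  A node carrying a cell flag never joins a community
    already holding another cell node.
    """
    n = len(adj)
    node_comm = np.arange(n) if init is None else np.asarray(init, dtype=int).copy()
    comm_tot = np.zeros(n, dtype=float)
    comm_cells = np.zeros(n, dtype=int)
    comm_size = np.zeros(n, dtype=int)
    for u in range(n):
        comm_tot[node_comm[u]] += k[u]
        comm_cells[node_comm[u]] += has_cell[u]
        comm_size[node_comm[u]] += 1
    moved_any = False
    while True:
        moved = False
        for u in rng.permutation(n):
            c_old = node_comm[u]
            neigh_w: dict[int, float] = {}
            for v, w in adj[u].items():
                neigh_w[node_comm[v]] = neigh_w.get(node_comm[v], 0.0) + w
            comm_tot[c_old] -= k[u]
            comm_cells[c_old] -= has_cell[u]
            comm_size[c_old] -= 1
            best_c = c_old
            best_gain = neigh_w.get(c_old, 0.0) - k[u] * comm_tot[c_old] / (2 * m)
            if best_gain < -1e-12 and comm_size[c_old] > 0:
                # isolating u in an empty community would gain 0
                empties = np.where(comm_size == 0)[0]
                if len(empties):
                    best_c, best_gain = int(empties[0]), 0.0
            for c in sorted(neigh_w):
                if c == best_c:
                    continue
                if has_cell[u] and comm_cells[c] > 0:
                    continue  # constraint: one cell node per community
                gain = neigh_w[c] - k[u] * comm_tot[c] / (2 * m)
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            node_comm[u] = best_c
            comm_tot[best_c] += k[u]
            comm_cells[best_c] += has_cell[u]
            comm_size[best_c] += 1
            if best_c != c_old:
                moved = moved_any = True
        if not moved:
            break
    return node_comm, moved_any


def louvain_with_priors(graph: nx.Graph, cfg: ComSegConfig) -> CommunityPartition:
    """Landmark-constrained Louvain partition of the merged graph.

    Standard two-phase Louvain (greedy local moves, then aggregation of
    communities into nodes, repeated until no gain) run on the
    positive-weight graph, with the added constraint that communities
    holding distinct cell nodes are never merged.  A final refinement
    sweep at the original-node level makes the returned partition a
    local optimum over every single-node move (aggregation alone only
    guarantees optimality over aggregated-node moves).  Fully
    deterministic given ``cfg.seed``.  With no positive edges the
    all-singleton partition (Q = 0) is returned.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes, index, adj = _positive_arrays(graph)
    n = len(nodes)
    has_cell = np.array([is_cell_node(nd) for nd in nodes])
    self_w = np.zeros(n)
    k = np.array([sum(a.values()) for a in adj], dtype=float)
    m = k.sum() / 2
    adj0, self_w0, has_cell0, k0 = adj, self_w.copy(), has_cell.copy(), k.copy()
    assign = np.arange(n)  # original node -> current-level node
    q_history: list[float] = []
    if m > 0:
        while True:
            node_comm, moved = _one_level(adj, self_w, has_cell, k, m, rng)
            labels, node_comm = np.unique(node_comm, return_inverse=True)
            q_history.append(_level_modularity(adj, self_w, k, node_comm, m))
            assign = node_comm[assign]
            if not moved or len(labels) == len(adj):
                break
            # aggregation: communities become nodes
            n_new = len(labels)
            new_adj: list[dict[int, float]] = [dict() for _ in range(n_new)]
            new_self = np.zeros(n_new)
            new_cell = np.zeros(n_new, dtype=bool)
            for u, a in enumerate(adj):
                cu = node_comm[u]
                new_self[cu] += self_w[u]
                new_cell[cu] |= has_cell[u]
                for v, w in a.items():
                    cv = node_comm[v]
                    if cu == cv:
                        if u < v:
                            new_self[cu] += w
                    else:
                        new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
            adj, self_w, has_cell = new_adj, new_self, new_cell
            k = np.array(
                [sum(a.values()) + 2 * s for a, s in zip(adj, self_w)], dtype=float
            )
        # refinement at the original-node level from the final partition
        _, assign = np.unique(assign, return_inverse=True)
        assign, _ = _one_level(adj0, self_w0, has_cell0, k0, m, rng, init=assign)
        q_history.append(_level_modularity(adj0, self_w0, k0, assign, m))
    membership = {nodes[i]: int(assign[i]) for i in range(n)}
    # renumber communities contiguously, ordered by smallest member node
    seen: dict[int, int] = {}
    for nd in nodes:
        c = membership[nd]
        if c not in seen:
            seen[c] = len(seen)
        membership[nd] = seen[c]
    part = CommunityPartition(membership=membership, q_history=q_history)
    part.modularity = q_history[-1] if q_history else 0.0
    return part


def expand_members(
    partition: CommunityPartition, graph: nx.Graph
) -> dict[int, list[int]]:
    """Per community, the molecule ids it contains (cell nodes expanded)."""
    out: dict[int, list[int]] = {}
    for c, members in partition.communities.items():
        mols: list[int] = []
        for nd in members:
            if is_cell_node(nd):
                mols.extend(graph.nodes[nd]["members"])
            else:
                mols.append(nd)
        out[c] = mols
    return out
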