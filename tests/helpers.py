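"""Shared builders and independent brute-force oracles for the tests.

The oracles deliberately re-derive each quantity from its definition
(double loops over pairs, explicit set arithmetic) without touching the
package's spatial-index or sparse implementations.
"""

from __future__ import annotations

import numpy as np

from comseg import ComSegConfig, RNAPointCloud


def make_cloud(positions, genes, gene_names=None, ids=None) -> RNAPointCloud:
    positions = np.asarray(positions, dtype=float)
    if positions.shape[1] == 2:
        positions = np.column_stack([positions, np.zeros(len(positions))])
    genes = np.asarray(genes, dtype=int)
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(genes.max() + 1 if len(genes) else 1)]
    if ids is None:
        ids = np.arange(len(positions))
    return RNAPointCloud(positions=positions, genes=genes, ids=np.asarray(ids), gene_names=list(gene_names))


def brute_force_pe_matrix(cloud: RNAPointCloud, cfg: ComSegConfig) -> np.ndarray:
    """O(N^2) all-pairs construction of the proximity-expression matrix."""
    pos = cloud.scaled_positions(cfg.z_anisotropy_factor)
    n, g = len(cloud), cloud.n_genes
    out = np.zeros((n, g))
    for i in range(n):
        d = np.sqrt(((pos - pos[i]) ** 2).sum(axis=1))
        cand = [(d[j], j) for j in range(n) if j != i and d[j] <= cfg.r_pe]
        cand.sort()
        for dist, j in cand[: cfg.k_pe]:
            out[i, cloud.genes[j]] += (cfg.r_pe - dist) / cfg.r_pe
    return out


def modularity_direct(nodes, edges, membership) -> float:
    """Direct double-sum evaluation of Q over ordered node pairs.

    ``edges`` is {(u, v): weight} with u != v, undirected (one entry per
    pair); only positive weights count.
    """
    w = {}
    for (u, v), wt in edges.items():
        if wt > 0:
            w[(u, v)] = wt
            w[(v, u)] = wt
    k = {u: sum(wt for (a, _), wt in w.items() if a == u) for u in nodes}
    m = sum(w.values()) / 2
    if m == 0:
        return 0.0
    q = 0.0
    for u in nodes:
        for v in nodes:
            if membership[u] != membership[v]:
                continue
            q += w.get((u, v), 0.0) - k[u] * k[v] / (2 * m)
    return q / (2 * m)


def set_metrics(x: set, y: set) -> tuple[float, float, float]:
    """(J, WA, MS) from explicit set arithmetic; WA is nan for empty y."""
    j = len(x & y) / len(x | y) if x | y else 0.0
    wa = len(y - x) / len(y) if y else float("nan")
    ms = len(x - y) / len(x)
    return j, wa, ms


def toy_graph(edges: dict, genes: dict | None = None, positions: dict | None = None):
    """Build an RNA-style networkx graph straight from an edge dict
    {(u, v): (coexpr_weight, euclid_length)}."""
    import networkx as nx

    g = nx.Graph()
    nodes = sorted({u for e in edges for u in e})
    for n in nodes:
        g.add_node(
            n,
            gene=(genes or {}).get(n, 0),
            position=np.asarray((positions or {}).get(n, (0.0, 0.0, 0.0)), dtype=float),
            is_cell=n < 0,
        )
        if n < 0:
            g.nodes[n]["nucleus"] = -n
            g.nodes[n].setdefault("members", [])
    for (u, v), (cw, el) in edges.items():
        g.add_edge(u, v, coexpr_weight=float(cw), euclid_length=float(el))
    return g
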