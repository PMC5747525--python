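"""Peptidergic connectome construction and graph statistics.

A peptide->receptor *channel* induces a directed graph over cells: an
edge runs from every cell expressing the proneuropeptide (sender) to
every cell expressing the matching deorphanized GPCR (receiver), with
weight equal to the geometric mean of the two log-normalized expression
values — a proxy for the strength of potential volume-transmission
signaling. Channel graphs are combined by summing parallel edge weights
into the multichannel peptidergic connectome, which is then summarized
with the usual graph-theory toolkit: density, weighted degrees, HITS
authority/hub scores, clustering, shortest paths, weakly connected
components, Louvain modularity, and a small-world coefficient.
"""

from __future__ import annotations

import logging
import math
import warnings

import networkx as nx
import numpy as np

from .io import ChannelGraph, ExpressionMatrix, NetworkStats, NodeLayout, PairTable

logger = logging.getLogger("peptinet")

__all__ = [
    "build_channel_graph",
    "build_all_channel_graphs",
    "combine_channels",
    "graph_density",
    "degree_stats",
    "hits_authority",
    "clustering_and_paths",
    "detect_communities",
    "small_world_sigma",
    "network_stats",
]


def build_channel_graph(
    matrix: ExpressionMatrix,
    channel,
    level: str = "cell",
    layout: NodeLayout | None = None,
    expression_threshold: float = 0.0,
) -> ChannelGraph:
    """Build the directed signaling graph of one ligand-receptor channel.

    An edge s->t exists iff expr(s, ligand) > threshold and
    expr(t, receptor) > threshold; its weight is
    sqrt(expr(s, ligand) * expr(t, receptor)). A cell expressing both
    partners yields an autocrine self-loop.

    At ``level='node'`` each cell's edges are replicated across its
    mirror-node instances from ``layout`` (cross-side edges included for
    distinct cells); autocrine loops stay per-node self-loops.
    """
    for gene in (channel.ligand_gene, channel.receptor_gene):
        if gene not in matrix.values.columns:
            raise ValueError(
                f"channel {channel.channel_id!r}: gene {gene!r} absent from matrix"
            )
    if level == "node" and layout is None:
        raise ValueError("level='node' requires a NodeLayout")

    lig = matrix.values[channel.ligand_gene]
    rec = matrix.values[channel.receptor_gene]
    senders = [c for c in matrix.cell_ids if lig[c] > expression_threshold]
    receivers = [c for c in matrix.cell_ids if rec[c] > expression_threshold]

    g = nx.DiGraph()
    if level == "cell":
        g.add_nodes_from(matrix.cell_ids)
        for s in senders:
            for t in receivers:
                g.add_edge(s, t, weight=math.sqrt(lig[s] * rec[t]))
    else:
        node_map = {c: layout.nodes_of_cell(c) for c in matrix.cell_ids}
        for c in matrix.cell_ids:
            g.add_nodes_from(node_map[c])
        for s in senders:
            for t in receivers:
                w = math.sqrt(lig[s] * rec[t])
                if s == t:
                    for u in node_map[s]:  # autocrine: per-node self-loop only
                        g.add_edge(u, u, weight=w)
                else:
                    for u in node_map[s]:
                        for v in node_map[t]:
                            g.add_edge(u, v, weight=w)
    return ChannelGraph(channel_id=channel.channel_id, graph=g, level=level)


def build_all_channel_graphs(
    matrix: ExpressionMatrix,
    pairs: PairTable,
    level: str = "cell",
    layout: NodeLayout | None = None,
    expression_threshold: float = 0.0,
) -> list[ChannelGraph]:
    return [
        build_channel_graph(matrix, ch, level=level, layout=layout,
                            expression_threshold=expression_threshold)
        for ch in pairs
    ]


def combine_channels(graphs: list[ChannelGraph], channel_id: str = "combined") -> ChannelGraph:
    """Sum per-channel graphs into one multichannel connectome.

    Parallel edges between the same ordered node pair collapse by summing
    weights; the per-channel contributions are kept in the ``channels``
    edge attribute.
    """
    if not graphs:
        raise ValueError("no channel graphs to combine")
    levels = {g.level for g in graphs}
    if len(levels) != 1:
        raise ValueError(f"cannot combine graphs at mixed levels {sorted(levels)}")
    out = nx.DiGraph()
    for cg in graphs:
        out.add_nodes_from(cg.graph.nodes())
        for u, v, data in cg.graph.edges(data=True):
            if out.has_edge(u, v):
                out[u][v]["weight"] += data["weight"]
                out[u][v]["channels"][cg.channel_id] = data["weight"]
            else:
                out.add_edge(u, v, weight=data["weight"], channels={cg.channel_id: data["weight"]})
    return ChannelGraph(channel_id=channel_id, graph=out, level=graphs[0].level)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _no_selfloops(g: nx.DiGraph) -> nx.DiGraph:
    h = g.copy()
    h.remove_edges_from(nx.selfloop_edges(h))
    return h


def graph_density(graph: ChannelGraph) -> float | None:
    """E / (N*(N-1)) over ordered pairs, self-loops excluded; None for N < 2."""
    n = graph.n_nodes
    if n < 2:
        return None
    e = sum(1 for u, v in graph.graph.edges() if u != v)
    return e / (n * (n - 1))


def degree_stats(graph: ChannelGraph) -> tuple[dict[str, float], dict[str, float]]:
    """Weighted in- and out-degree per node (self-loops count once each way)."""
    win = {n: 0.0 for n in graph.graph.nodes()}
    wout = {n: 0.0 for n in graph.graph.nodes()}
    for u, v, data in graph.graph.edges(data=True):
        wout[u] += data["weight"]
        win[v] += data["weight"]
    return win, wout


def hits_authority(
    graph: ChannelGraph,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[dict[str, float], dict[str, float]]:
    """HITS authority and hub scores by power iteration on the weighted
    adjacency matrix, sum-normalized to 1.

    Edgeless graphs return all-zero scores with a warning.
    """
    nodes = list(graph.graph.nodes())
    n = len(nodes)
    if graph.n_edges == 0:
        warnings.warn("HITS on an edgeless graph: all scores zero", stacklevel=2)
        zero = {node: 0.0 for node in nodes}
        return dict(zero), dict(zero)
    a = nx.to_numpy_array(graph.graph, nodelist=nodes, weight="weight")
    auth = np.full(n, 1.0 / n)
    hub = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new_auth = a.T @ hub
        new_hub = a @ new_auth
        sa, sh = new_auth.sum(), new_hub.sum()
        if sa > 0:
            new_auth /= sa
        if sh > 0:
            new_hub /= sh
        if np.abs(new_auth - auth).sum() < tol and np.abs(new_hub - hub).sum() < tol:
            auth, hub = new_auth, new_hub
            break
        auth, hub = new_auth, new_hub
    return (
        {node: float(v) for node, v in zip(nodes, auth)},
        {node: float(v) for node, v in zip(nodes, hub)},
    )


def clustering_and_paths(graph: ChannelGraph) -> tuple[float, float, float | None, int]:
    """(avg_clustering_directed, avg_clustering_undirected, avg_path_length,
    n_components) on the unweighted graph, self-loops removed.

    avg_path_length averages unweighted shortest-path hops over all
    ordered reachable pairs s != t (None when no such pair exists);
    components are weakly connected.
    """
    g = _no_selfloops(graph.graph)
    if g.number_of_nodes() == 0:
        return 0.0, 0.0, None, 0
    cdir = float(np.mean(list(nx.clustering(g).values())))
    cund = float(np.mean(list(nx.clustering(g.to_undirected()).values())))
    total, count = 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for dist in lengths.values():
            if dist > 0:
                total += dist
                count += 1
    apl = total / count if count else None
    ncomp = nx.number_weakly_connected_components(g)
    return cdir, cund, apl, ncomp


def detect_communities(
    graph: ChannelGraph,
    resolution: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, int], float]:
    """Louvain communities on the weighted undirected projection.

    Deterministic for a given seed; returns (node -> community label,
    modularity of that partition).
    """
    if graph.n_edges == 0:
        raise ValueError("community detection needs at least one edge")
    und = nx.Graph()
    und.add_nodes_from(graph.graph.nodes())
    for u, v, data in graph.graph.edges(data=True):
        if u == v:
            continue
        w = data["weight"] + (und[u][v]["weight"] if und.has_edge(u, v) else 0.0)
        und.add_edge(u, v, weight=w)
    comms = nx.community.louvain_communities(und, weight="weight", resolution=resolution, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = {node: i for i, comm in enumerate(comms) for node in comm}
    mod = nx.community.modularity(und, comms, weight="weight", resolution=resolution)
    return labels, float(mod)


def small_world_sigma(
    graph: ChannelGraph,
    n_random: int = 100,
    seed: int = 0,
) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    C and L are the average clustering coefficient and characteristic
    path length of the undirected projection; the null values average
    over ``n_random`` degree-preserving edge rewirings. sigma > 1 flags a
    small-world topology (clustering well above, path length comparable
    to, degree-matched random graphs). Disconnected graphs are reduced to
    their largest component with a warning.
    """
    und = _no_selfloops(graph.graph).to_undirected()
    if not nx.is_connected(und):
        warnings.warn("graph disconnected: sigma computed on largest component", stacklevel=2)
        und = und.subgraph(max(nx.connected_components(und), key=len)).copy()
    if und.number_of_nodes() < 4:
        raise ValueError("sigma needs >= 4 nodes in the largest component")
    c = nx.average_clustering(und)
    length = nx.average_shortest_path_length(und)
    rng = np.random.default_rng(seed)
    cr, lr = [], []
    for _ in range(n_random):
        rand = nx.random_reference(und, niter=5, seed=int(rng.integers(2**31 - 1)))
        if not nx.is_connected(rand):
            rand = rand.subgraph(max(nx.connected_components(rand), key=len)).copy()
        cr.append(nx.average_clustering(rand))
        lr.append(nx.average_shortest_path_length(rand))
    c_rand, l_rand = float(np.mean(cr)), float(np.mean(lr))
    if c_rand == 0 or l_rand == 0:
        raise ValueError("degenerate randomized reference (zero clustering or path length)")
    return (c / c_rand) / (length / l_rand)


def network_stats(
    graph: ChannelGraph,
    seed: int = 0,
    resolution: float = 1.0,
    with_sigma: bool = False,
    n_random: int = 100,
) -> NetworkStats:
    """All summary statistics for one graph, bundled."""
    win, wout = degree_stats(graph)
    auth, hub = hits_authority(graph) if graph.n_edges else ({n: 0.0 for n in graph.graph}, {n: 0.0 for n in graph.graph})
    cdir, cund, apl, ncomp = clustering_and_paths(graph)
    labels: dict[str, int] | None = None
    mod: float | None = None
    if graph.n_edges and any(u != v for u, v in graph.graph.edges()):
        labels, mod = detect_communities(graph, resolution=resolution, seed=seed)
    sigma = None
    if with_sigma:
        try:
            sigma = small_world_sigma(graph, n_random=n_random, seed=seed)
        except ValueError:
            logger.warning("sigma not computable for %s", graph.channel_id)
    return NetworkStats(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        graph_density=graph_density(graph),
        weighted_in_degree=win,
        weighted_out_degree=wout,
        authority=auth,
        hub=hub,
        avg_clustering_directed=cdir,
        avg_clustering_undirected=cund,
        avg_path_length=apl,
        n_components=ncomp,
        modularity=mod,
        communities=labels,
        small_world_sigma=sigma,
    )
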