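"""Independent oracles used by the walktrap and acceptance tests.

Kept deliberately naive: literal double-sum modularity, exhaustive
enumeration of set partitions, and the igraph reference implementation.
"""

import igraph
import networkx as nx
import numpy as np
from sympy.utilities.iterables import multiset_partitions


def brute_modularity(graph: nx.Graph, membership) -> float:
    """Literal (1/2m) sum_ij (w_ij - s_i s_j / 2m) delta(c_i, c_j)."""
    nodes = sorted(graph.nodes())
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        W[pos[u], pos[v]] = w
        W[pos[v], pos[u]] = w
    s = W.sum(axis=1)
    two_m = s.sum()
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if membership[u] == membership[v]:
                q += W[i, j] - s[i] * s[j] / two_m
    return q / two_m


def exhaustive_best_partition(graph: nx.Graph):
    """Maximum-modularity partition by enumerating all set partitions."""
    nodes = sorted(graph.nodes())
    best_q, best = -np.inf, None
    for blocks in multiset_partitions(nodes):
        membership = {v: k for k, block in enumerate(blocks) for v in block}
        q = brute_modularity(graph, membership)
        if q > best_q:
            best_q, best = q, blocks
    return best_q, frozenset(frozenset(b) for b in best)


def igraph_walktrap_membership(graph: nx.Graph, steps: int = 4):
    """Reference implementation: igraph's walktrap + modularity cut."""
    nodes = sorted(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    g = igraph.Graph(n=len(nodes))
    edges, weights = [], []
    for u, v, d in graph.edges(data=True):
        edges.append((idx[u], idx[v]))
        weights.append(float(d.get("weight", 1.0)))
    g.add_edges(edges)
    g.es["weight"] = weights
    cl = g.community_walktrap(weights="weight", steps=steps).as_clustering()
    return {nodes[i]: m for i, m in enumerate(cl.membership)}, cl.modularity


def partition_signature(membership) -> frozenset:
    """Label-invariant signature of a node -> community mapping."""
    groups = {}
    for node, c in membership.items():
        groups.setdefault(c, set()).add(node)
    return frozenset(frozenset(s) for s in groups.values())


def random_modular_graph(rng: np.random.Generator) -> tuple[nx.Graph, list]:
    """Random planted-block weighted graph: random block count/sizes,
    strong generic within-block weights, weak between-block weights."""
    n_blocks = int(rng.integers(2, 4))
    sizes = rng.integers(3, 7, size=n_blocks)
    block = np.repeat(np.arange(n_blocks), sizes)
    n = len(block)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if block[i] == block[j]:
                w = float(rng.uniform(0.6, 1.0))
            else:
                w = float(rng.uniform(0.01, 0.08))
            g.add_edge(i, j, weight=w)
    return g, block.tolist()
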