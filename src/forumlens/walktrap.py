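"""Walktrap community detection on weighted undirected graphs.

Short random walks tend to stay trapped inside densely connected groups of
nodes, so the distribution of a t-step walk started at a node characterizes
the node's community. The algorithm:

1. transition probabilities ``P[i, j] = w_ij / s_i`` (``s_i`` = weighted
   degree), made lazy (``(I + P) / 2``: the walker stays put with
   probability one half, which keeps the chain aperiodic on near-bipartite
   structures), raised to the ``t``-th power to give each node's t-step
   walk distribution;
2. the distance between nodes (or communities) i and j is the
   degree-normalized Euclidean distance between their walk distributions,
   ``r_ij^2 = sum_k (P^t[i,k] - P^t[j,k])^2 / s_k``;
3. agglomeration from singletons: at each step merge the *adjacent* pair of
   communities whose merge minimally increases the mean squared
   node-community distance (the Ward-style cost
   ``(1/n) * |C1||C2| / (|C1|+|C2|) * r^2``), with the merged community's
   walk distribution the member-average of its nodes' distributions;
4. the merge history is a dendrogram; the returned partition is the cut
   with maximum weighted modularity.

Cost ties are broken on the smallest (lexicographic) community-id pair so
runs are reproducible across platforms. Disconnected graphs are handled
per connected component and the component dendrograms concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Tuple

import networkx as nx
import numpy as np

DEFAULT_WALK_LENGTH = 4


@dataclass(frozen=True, slots=True)
class Merge:
    """One agglomeration step: communities ``a`` and ``b`` -> ``new_id``."""

    a: int
    b: int
    new_id: int
    cost: float


@dataclass
class Dendrogram:
    """Walktrap merge history.

    Leaves are numbered 0..n-1 in sorted node-label order; merged
    communities get consecutive ids from n. For a connected n-node graph
    there are exactly n-1 merges; for a disconnected graph the
    per-component merge lists are concatenated (in order of each
    component's smallest leaf id) and ``n_components`` records the split.
    """

    nodes: List[Hashable]
    merges: List[Merge]
    n_components: int = 1

    @property
    def leaf_id(self) -> Dict[Hashable, int]:
        return {v: i for i, v in enumerate(self.nodes)}

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["community_a", "community_b", "new_id", "cost"])
            for m in self.merges:
                w.writerow([m.a, m.b, m.new_id, repr(m.cost)])


@dataclass
class Partition:
    """Node -> community assignment with its modularity score.

    Labels are contiguous integers from 1, ordered by each community's
    smallest node in sorted label order.
    """

    membership: Dict[Hashable, int]
    n_communities: int
    modularity: float

    def communities(self) -> Dict[int, List[Hashable]]:
        out: Dict[int, List[Hashable]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, []).append(node)
        return {c: sorted(v) for c, v in out.items()}

    def write_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["node", "community"])
            for node in sorted(self.membership):
                w.writerow([node, self.membership[node]])


def _check_weights(graph: nx.Graph) -> None:
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u!r}, {v!r}): {w}")


def _component_merges(
    graph: nx.Graph,
    comp_nodes: List[Hashable],
    leaf_id: Mapping[Hashable, int],
    t: int,
    next_id: int,
) -> Tuple[List[Merge], int]:
    """Run the agglomeration on one connected component."""
    k = len(comp_nodes)
    if k == 1:
        return [], next_id
    pos = {v: i for i, v in enumerate(comp_nodes)}
    W = np.zeros((k, k))
    for u, v, d in graph.subgraph(comp_nodes).edges(data=True):
        w = float(d.get("weight", 1.0))
        W[pos[u], pos[v]] = w
        W[pos[v], pos[u]] = w
    s = W.sum(axis=1)  # weighted degrees; > 0 in a connected k>=2 component
    # lazy walk: stay put with probability 1/2 each step. Keeps the chain
    # aperiodic — without it, near-bipartite blocks (e.g. two forums tied
    # by one strong edge) make even-step distributions oscillate and
    # cross-block distances collapse below within-block ones.
    P = (W / s[:, None] + np.eye(k)) / 2.0
    Pt = np.linalg.matrix_power(P, t)

    # community state, keyed by community id
    members: Dict[int, int] = {}  # id -> size
    dist: Dict[int, np.ndarray] = {}  # id -> member-averaged walk distribution
    nbrs: Dict[int, set] = {}  # id -> adjacent community ids
    for v in comp_nodes:
        cid = leaf_id[v]
        members[cid] = 1
        dist[cid] = Pt[pos[v]]
        nbrs[cid] = set()
    for u, v in graph.subgraph(comp_nodes).edges():
        a, b = leaf_id[u], leaf_id[v]
        if a != b:
            nbrs[a].add(b)
            nbrs[b].add(a)

    inv_s = 1.0 / s

    def cost(a: int, b: int) -> float:
        diff = dist[a] - dist[b]
        r2 = float(np.dot(diff * diff, inv_s))
        na, nb = members[a], members[b]
        return (na * nb) / (na + nb) / k * r2

    pair_cost: Dict[Tuple[int, int], float] = {}
    for a in members:
        for b in nbrs[a]:
            if a < b:
                pair_cost[(a, b)] = cost(a, b)

    merges: List[Merge] = []
    while len(members) > 1:
        # min over (cost, a, b): float ties fall through to the id pair
        (a, b), c = min(pair_cost.items(), key=lambda kv: (kv[1], kv[0]))
        new = next_id
        next_id += 1
        na, nb = members[a], members[b]
        members[new] = na + nb
        dist[new] = (na * dist[a] + nb * dist[b]) / (na + nb)
        new_nbrs = (nbrs[a] | nbrs[b]) - {a, b}
        nbrs[new] = new_nbrs
        for old in (a, b):
            for d in nbrs[old]:
                nbrs[d].discard(old)
                pair_cost.pop((min(old, d), max(old, d)), None)
            del members[old], dist[old], nbrs[old]
        for d in new_nbrs:
            nbrs[d].add(new)
            pair_cost[(min(d, new), max(d, new))] = cost(d, new)
        merges.append(Merge(a, b, new, c))
    return merges, next_id


def walktrap_dendrogram(
    graph: nx.Graph, walk_length_t: int = DEFAULT_WALK_LENGTH
) -> Dendrogram:
    """Agglomerate a weighted undirected graph by t-step walk distances.

    Components of a disconnected graph are processed independently and
    their merge lists concatenated (``n_components`` flags this).
    """
    if walk_length_t < 1:
        raise ValueError("walk length t must be >= 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    _check_weights(graph)
    nodes = sorted(graph.nodes())
    leaf_id = {v: i for i, v in enumerate(nodes)}
    comps = sorted(
        (sorted(c, key=lambda v: leaf_id[v]) for c in nx.connected_components(graph)),
        key=lambda c: leaf_id[c[0]],
    )
    merges: List[Merge] = []
    next_id = len(nodes)
    for comp in comps:
        cm, next_id = _component_merges(graph, comp, leaf_id, walk_length_t, next_id)
        merges.extend(cm)
    return Dendrogram(nodes=nodes, merges=merges, n_components=len(comps))


def modularity(graph: nx.Graph, partition: Mapping[Hashable, Hashable]) -> float:
    """Weighted Newman modularity of a node -> community mapping.

    Q = (1/2m) sum_ij (w_ij - s_i s_j / 2m) delta(c_i, c_j), with s the
    weighted degree and m the total edge weight. Returns 0 for an edgeless
    graph.
    """
    for v in graph.nodes():
        if v not in partition:
            raise KeyError(f"node {v!r} missing from partition")
    m = graph.size(weight="weight")
    if m == 0:
        return 0.0
    intra: Dict[Hashable, float] = {}
    deg: Dict[Hashable, float] = {}
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        deg[partition[u]] = deg.get(partition[u], 0.0) + w
        deg[partition[v]] = deg.get(partition[v], 0.0) + w
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    q = 0.0
    for c in deg:
        q += intra.get(c, 0.0) / m - (deg[c] / (2.0 * m)) ** 2
    return q


def _memberships_at_levels(dendrogram: Dendrogram):
    """Yield (level, membership dict) for every cut, singletons first."""
    parent: Dict[int, int] = {}
    id_nodes: Dict[int, List[Hashable]] = {
        i: [v] for v, i in dendrogram.leaf_id.items()
    }

    def snapshot():
        return {
            v: cid for cid, vs in id_nodes.items() for v in vs
        }

    yield 0, snapshot()
    for lvl, mg in enumerate(dendrogram.merges, 1):
        id_nodes[mg.new_id] = id_nodes.pop(mg.a) + id_nodes.pop(mg.b)
        yield lvl, snapshot()


def best_partition(dendrogram: Dendrogram, graph: nx.Graph) -> Partition:
    """Cut the dendrogram at the level of maximum modularity.

    Every cut level (from all-singletons to the final merge) is scored;
    ties go to the cut with fewer communities.
    """
    best_q = -np.inf
    best_membership = None
    for _, membership in _memberships_at_levels(dendrogram):
        q = modularity(graph, membership)
        n_comm = len(set(membership.values()))
        if q > best_q or (q == best_q and best_membership is not None
                          and n_comm < len(set(best_membership.values()))):
            best_q = q
            best_membership = membership
    # relabel contiguously from 1, ordered by smallest member node
    groups: Dict[Hashable, List[Hashable]] = {}
    for v, c in best_membership.items():
        groups.setdefault(c, []).append(v)
    order = sorted(groups.values(), key=lambda vs: min(vs))
    membership = {}
    for label, vs in enumerate(order, 1):
        for v in vs:
            membership[v] = label
    return Partition(
        membership=membership,
        n_communities=len(order),
        modularity=float(best_q),
    )


def detect_communities(
    graph: nx.Graph, walk_length_t: int = DEFAULT_WALK_LENGTH
) -> Partition:
    """Walktrap dendrogram + modularity-optimal cut in one call."""
    return best_partition(walktrap_dendrogram(graph, walk_length_t), graph)


def modularity_curve(dendrogram: Dendrogram, graph: nx.Graph):
    """(cut level, n_communities, Q) for every cut; for CSV export."""
    rows = []
    for lvl, membership in _memberships_at_levels(dendrogram):
        rows.append(
            (lvl, len(set(membership.values())), modularity(graph, membership))
        )
    return rows
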