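"""Mean commenter-overlap statistic and the weighted forum network.

For forums A and B with commenter sets :math:`S_A`, :math:`S_B`, the edge
weight is the mean of the two directed proportions,

.. math::

    w(A, B) = \\tfrac12\\left(\\frac{|S_A \\cap S_B|}{|S_A|}
              + \\frac{|S_A \\cap S_B|}{|S_B|}\\right) \\in [0, 1],

which symmetrizes the overlap between forums of very different sizes
(e.g. 40 shared commenters out of 100 and out of 50 gives
(0.4 + 0.8) / 2 = 0.6). The matrix of all pairwise weights is the
adjacency of a weighted undirected network; the diagonal is zero by
convention (a forum has no self-edge).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, List, Mapping, Sequence, Set

import networkx as nx
import numpy as np


def pairwise_mean_overlap(set_a: AbstractSet, set_b: AbstractSet) -> float:
    """Mean of the two directed commenter-overlap proportions.

    Symmetric in its arguments; raises on an empty set, for which the
    proportion is undefined.
    """
    if not set_a or not set_b:
        raise ValueError("commenter overlap undefined for an empty set")
    inter = len(set_a & set_b)
    return (inter / len(set_a) + inter / len(set_b)) / 2.0


@dataclass
class OverlapMatrix:
    """Symmetric matrix of mean commenter overlaps over an ordered forum list."""

    forums: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.forums)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match forum list")

    def weight(self, a: str, b: str) -> float:
        return float(self.values[self.forums.index(a), self.forums.index(b)])

    def to_csv(self, path: str | Path) -> None:
        """Write with a header row/column of forum names."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow([""] + self.forums)
            for name, row in zip(self.forums, self.values):
                w.writerow([name] + [repr(float(v)) for v in row])


def build_overlap_matrix(
    commenter_index: Mapping[str, Set[str]], forums: Sequence[str]
) -> OverlapMatrix:
    """All-pairs mean overlap over ``forums``; symmetric, zero diagonal."""
    for f in forums:
        if f not in commenter_index:
            raise KeyError(f"forum {f!r} missing from commenter index")
        if not commenter_index[f]:
            raise ValueError(f"forum {f!r} has an empty commenter set")
    n = len(forums)
    m = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            w = pairwise_mean_overlap(
                commenter_index[forums[i]], commenter_index[forums[j]]
            )
            m[i, j] = m[j, i] = w
    return OverlapMatrix(list(forums), m)


def matrix_to_graph(matrix: OverlapMatrix, min_weight: float = 0.0) -> nx.Graph:
    """Weighted undirected graph with an edge per cell strictly above
    ``min_weight``; all forums kept as nodes even when isolated.

    ``min_weight`` defaults to 0 (every positive overlap is an edge); a
    display threshold such as 0.25 is a rendering choice, not an analysis
    default.
    """
    g = nx.Graph()
    g.add_nodes_from(matrix.forums)
    n = len(matrix.forums)
    for i in range(n):
        for j in range(i + 1, n):
            w = float(matrix.values[i, j])
            if w > min_weight:
                g.add_edge(matrix.forums[i], matrix.forums[j], weight=w)
    return g


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))
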