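"""Undirected, unweighted networks used as substrates for the coupled dynamics.

All generators return a :class:`Network`, a thin immutable wrapper around a
:class:`networkx.Graph` that exposes the 0/1 adjacency matrix ``w_ij`` in a
fixed node order.  Three random-graph models are provided:

* an Erdős–Rényi variant with an exact, fixed number of edges,
* a Barabási–Albert model grown from a complete triangle with ``m`` distinct
  degree-proportional attachments per new node (so the edge count is exactly
  ``3 + m (N - 3)``), and
* a static node-fitness model in which pair ``(i, j)`` is connected with
  probability ``f_i f_j / (sum_l f_l)**2``.

Plain two-column edge-list files can be read and written; duplicate edges and
self-loops are dropped on input.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "EdgeListParseError",
    "generate_er_fixed_edges",
    "generate_ba",
    "generate_fitness",
    "fitness_scores",
    "fitness_edge_probabilities",
    "read_edge_list",
    "write_edge_list",
    "largest_component",
    "average_degree",
]


class EdgeListParseError(ValueError):
    """A malformed line was encountered while parsing an edge-list file."""


@dataclass(frozen=True)
class Network:
    """An undirected simple graph with a fixed node ordering.

    The adjacency matrix is symmetric with zero diagonal and entries in
    {0, 1}.  Node labels keep whatever hashable identifiers the source graph
    used; matrix rows/columns follow ``labels`` order.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed in a Network")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def labels(self) -> tuple:
        return tuple(self.graph.nodes)

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix in ``labels`` order."""
        return nx.to_numpy_array(self.graph, nodelist=self.labels, dtype=float)

    @property
    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


def generate_er_fixed_edges(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> Network:
    """Erdős–Rényi graph with exactly ``n_edges`` edges.

    Uniformly randomly selected non-adjacent pairs are connected one by one
    until the requested edge count is reached, i.e. the graph is uniform over
    all simple graphs with ``n_nodes`` nodes and ``n_edges`` edges.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges={n_edges} out of range [0, {max_edges}] for {n_nodes} nodes"
        )
    pairs = list(itertools.combinations(range(n_nodes), 2))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(pairs[i] for i in chosen)
    return Network(g)


def generate_ba(n_nodes: int, m: int, rng: np.random.Generator) -> Network:
    """Barabási–Albert graph grown from a complete triangle.

    Each new node attaches to ``m`` *distinct* existing nodes chosen with
    probability proportional to their current degree (sampling without
    replacement, so no multi-edges arise).  For ``m = 2`` the edge count is
    exactly ``3 + 2 (n_nodes - 3)``.
    """
    if n_nodes < 3:
        raise ValueError("the BA model needs at least the 3-node seed triangle")
    if m < 1:
        raise ValueError("m must be >= 1")
    g = nx.complete_graph(3)
    degree = np.zeros(n_nodes)
    degree[:3] = 2.0
    for new in range(3, n_nodes):
        k = min(m, new)
        existing = np.arange(new)
        p = degree[:new] / degree[:new].sum()
        targets = rng.choice(existing, size=k, replace=False, p=p)
        for t in targets:
            g.add_edge(new, int(t))
            degree[t] += 1.0
        degree[new] = float(k)
    return Network(g)


def fitness_scores(n_nodes: int, alpha: float) -> np.ndarray:
    """Node fitness scores ``f_i = (i + i0 - 1)**(-alpha)`` for i = 1..N.

    The offset ``i0 = N**(1 - 1/alpha) * (10 sqrt(2) |1 - alpha|)**(1/alpha)``
    constrains the maximum degree.  The absolute value keeps the expression
    real for alpha > 1 (for alpha = 1 the bracket degenerates to zero and an
    offset of zero is used).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    bracket = 10.0 * math.sqrt(2.0) * abs(1.0 - alpha)
    i0 = n_nodes ** (1.0 - 1.0 / alpha) * bracket ** (1.0 / alpha)
    i = np.arange(1, n_nodes + 1, dtype=float)
    return (i + i0 - 1.0) ** (-alpha)


def fitness_edge_probabilities(
    n_nodes: int, alpha: float, mean_degree: float = 5.0
) -> np.ndarray:
    """Pairwise connection probabilities of the fitness model (zero diagonal).

    Pair ``(i, j)`` is connected with probability
    ``2 M f_i f_j / (sum_l f_l)**2`` clipped at 1, where ``M = mean_degree N / 2``
    is the target edge count, so the expected number of edges is close to M.
    """
    f = fitness_scores(n_nodes, alpha)
    m = mean_degree * n_nodes / 2.0
    p = 2.0 * m * np.outer(f, f) / f.sum() ** 2
    np.fill_diagonal(p, 0.0)
    return np.clip(p, 0.0, 1.0)


def generate_fitness(
    n_nodes: int,
    alpha: float,
    rng: np.random.Generator,
    *,
    mean_degree: float = 5.0,
    keep_largest_component: bool = True,
) -> Network:
    """Static fitness-model graph; by default the largest connected component.

    Each pair ``(i, j)`` is connected independently with probability
    ``2 M f_i f_j / (sum_l f_l)**2`` (clipped at 1, ``M = mean_degree N / 2``),
    yielding a right-skewed degree distribution controlled by ``alpha``.
    """
    p = fitness_edge_probabilities(n_nodes, alpha, mean_degree)
    u = rng.random((n_nodes, n_nodes))
    rows, cols = np.nonzero(np.triu(u < p, k=1))
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from((int(a), int(b)) for a, b in zip(rows, cols))
    net = Network(g)
    return largest_component(net) if keep_largest_component else net


def read_edge_list(path: str | Path) -> Network:
    """Read a whitespace-delimited two-column undirected edge list.

    Lines starting with ``#`` and blank lines are skipped.  Duplicate edges
    and self-loops are dropped.  A line without exactly two tokens raises
    :class:`EdgeListParseError` naming the line number.
    """
    path = Path(path)
    g = nx.Graph()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two node labels, got {len(tokens)}"
                )
            a, b = tokens
            if a != b:
                g.add_edge(a, b)
    return Network(g)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write one undirected edge per line, two whitespace-separated labels."""
    with Path(path).open("w") as fh:
        fh.write(f"# nodes={net.n_nodes} edges={net.n_edges}\n")
        for u, v in net.graph.edges:
            fh.write(f"{u} {v}\n")


def largest_component(net: Network) -> Network:
    """The subgraph induced by the largest connected component."""
    if net.n_nodes == 0:
        return net
    nodes = max(nx.connected_components(net.graph), key=len)
    return Network(net.graph.subgraph(nodes).copy())


def average_degree(net: Network) -> float:
    """Mean degree 2 E / N."""
    if net.n_nodes == 0:
        raise ValueError("average degree of an empty network is undefined")
    return 2.0 * net.n_edges / net.n_nodes
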