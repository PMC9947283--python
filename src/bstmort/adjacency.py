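"""Spatial neighbourhood structure for the intrinsic CAR prior.

The adjacency graph is the binary, symmetric W matrix of the iCAR
prior: w_ij = 1 when two areal units are first-order queen-contiguous
neighbours, 0 otherwise.  Weights are never row-standardised.  Isolated
units ("islands") are allowed; the model fixes their structured effects
at zero because the iCAR full conditional is undefined without
neighbours.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .panel_io import MortalityPanel, _atomic_write_text


@dataclass
class AdjacencyGraph:
    """Symmetric binary neighbour structure over ordered node ids."""

    node_ids: list[str]
    neighbors: list[np.ndarray]  # per node, sorted array of neighbour indices

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            dups = sorted({x for x in self.node_ids if self.node_ids.count(x) > 1})
            raise ValueError(f"duplicate node ids: {dups}")
        if len(self.neighbors) != n:
            raise ValueError("neighbors list length does not match node count")
        self.neighbors = [np.asarray(sorted(set(int(j) for j in nb)), dtype=int)
                          for nb in self.neighbors]
        bad_pairs = []
        for i, nb in enumerate(self.neighbors):
            if np.any(nb < 0) or np.any(nb >= n):
                raise ValueError(f"neighbour index out of range for node {self.node_ids[i]}")
            if i in nb:
                raise ValueError(f"self-loop at node {self.node_ids[i]}")
            for j in nb:
                if i not in self.neighbors[j]:
                    bad_pairs.append((self.node_ids[i], self.node_ids[int(j)]))
        if bad_pairs:
            raise ValueError(f"asymmetric adjacency; offending pairs: {bad_pairs}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def num_neighbors(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=int)

    @property
    def n_edges(self) -> int:
        return int(self.num_neighbors.sum()) // 2

    def adjacency_matrix(self) -> np.ndarray:
        """Dense binary W."""
        n = self.n_nodes
        W = np.zeros((n, n))
        for i, nb in enumerate(self.neighbors):
            W[i, nb] = 1.0
        return W

    def laplacian(self) -> np.ndarray:
        """Graph Laplacian D - W, the unscaled iCAR precision."""
        W = self.adjacency_matrix()
        return np.diag(W.sum(axis=1)) - W

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, nb in enumerate(self.neighbors):
            g.add_edges_from((i, int(j)) for j in nb if j > i)
        return g


def from_edges(node_ids: Sequence[str], edges: Sequence[tuple[int, int]]) -> AdjacencyGraph:
    """Build a graph from an undirected edge list over node indices."""
    nbs: list[set[int]] = [set() for _ in node_ids]
    for i, j in edges:
        if i == j:
            raise ValueError(f"self-loop edge ({i},{j})")
        nbs[i].add(j)
        nbs[j].add(i)
    return AdjacencyGraph(list(node_ids), [np.array(sorted(s), dtype=int) for s in nbs])


def read_gal(path: str | os.PathLike) -> AdjacencyGraph:
    """Read a GAL neighbour-list file.

    Format: a header line whose last-but-one token (or only token) is the
    node count, then per node one line ``id m`` followed by one line of m
    neighbour ids.  Symmetry is enforced; isolated nodes are accepted with
    a warning.
    """
    with open(path, "r", encoding="utf-8") as fh:
        tokens_lines = [ln.split() for ln in fh if ln.strip()]
    if not tokens_lines:
        raise ValueError("empty GAL file")
    header = tokens_lines[0]
    # plain "n" header or the 4-token "0 n shapefile idvar" variant
    if len(header) == 1:
        n = int(header[0])
    elif len(header) == 4:
        n = int(header[1])
    else:
        raise ValueError(f"unrecognised GAL header: {' '.join(header)}")
    ids: list[str] = []
    raw_neighbors: list[list[str]] = []
    pos = 1
    for _ in range(n):
        if pos >= len(tokens_lines):
            raise ValueError("truncated GAL file")
        node_id, m = tokens_lines[pos][0], int(tokens_lines[pos][1])
        pos += 1
        if m > 0:
            if pos >= len(tokens_lines):
                raise ValueError(f"missing neighbour line for node {node_id}")
            nb = tokens_lines[pos]
            pos += 1
            if len(nb) != m:
                raise ValueError(f"node {node_id}: expected {m} neighbours, found {len(nb)}")
        else:
            nb = []
        if node_id in ids:
            raise ValueError(f"duplicate node id {node_id!r}")
        ids.append(node_id)
        raw_neighbors.append(nb)
    index = {c: i for i, c in enumerate(ids)}
    neighbors = []
    for node_id, nb in zip(ids, raw_neighbors):
        unknown = [x for x in nb if x not in index]
        if unknown:
            raise ValueError(f"node {node_id} lists unknown neighbours {unknown}")
        neighbors.append(np.array(sorted(index[x] for x in nb), dtype=int))
    graph = AdjacencyGraph(ids, neighbors)
    islands = [ids[i] for i in range(n) if len(neighbors[i]) == 0]
    if islands:
        warnings.warn(
            f"GAL file contains {len(islands)} island node(s) with no neighbours: "
            f"{islands}; their structured spatial effects will be fixed at 0",
            stacklevel=2,
        )
    return graph


def write_gal(graph: AdjacencyGraph, path: str | os.PathLike) -> None:
    """Write a graph in GAL neighbour-list format."""
    lines = [str(graph.n_nodes)]
    for i, node_id in enumerate(graph.node_ids):
        nb = graph.neighbors[i]
        lines.append(f"{node_id} {len(nb)}")
        if len(nb):
            lines.append(" ".join(graph.node_ids[int(j)] for j in nb))
    _atomic_write_text(path, "\n".join(lines) + "\n")


def connected_components(graph: AdjacencyGraph) -> list[set[int]]:
    """Maximal connected node-index sets, isolated nodes as singletons.

    Components are ordered by their smallest member for determinism.
    """
    comps = list(nx.connected_components(graph.to_networkx()))
    return sorted((set(c) for c in comps), key=min)


def bind_order(graph: AdjacencyGraph, panel: MortalityPanel) -> AdjacencyGraph:
    """Reindex the graph to the panel's country order.

    Nodes absent from the panel are dropped together with their edges.
    Every panel country must be present in the graph.
    """
    countries = panel.countries
    index = {c: i for i, c in enumerate(graph.node_ids)}
    missing = [c for c in countries if c not in index]
    if missing:
        raise ValueError(f"panel countries missing from adjacency graph: {missing}")
    keep = {index[c] for c in countries}
    new_pos = {index[c]: k for k, c in enumerate(countries)}
    neighbors = []
    for c in countries:
        old = graph.neighbors[index[c]]
        neighbors.append(np.array(sorted(new_pos[int(j)] for j in old if int(j) in keep),
                                  dtype=int))
    return AdjacencyGraph(list(countries), neighbors)
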