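"""Health-network construction and structural statistics.

The aging process runs on an undirected graph whose nodes are health
indicators. Two designated *mortality nodes* — the two most highly
connected nodes — define death: the process stops when both are damaged.
The remaining nodes are *aging nodes*. The generator produces a
scale-free graph by preferential attachment and then makes it
disassortative (degrees negatively correlated at edge endpoints) by
degree-preserving edge rewiring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np


@dataclass(frozen=True)
class HealthNetwork:
    """Undirected health network in CSR adjacency form.

    ``indptr``/``indices`` hold the symmetric adjacency (each undirected
    edge appears in both directions). ``mortality_nodes`` is the ordered
    pair of hub nodes whose joint damage defines death; all other nodes
    are aging nodes.
    """

    n: int
    indptr: np.ndarray
    indices: np.ndarray
    mortality_nodes: tuple[int, int]
    aging_nodes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a health network needs at least 2 nodes")
        m1, m2 = self.mortality_nodes
        if m1 == m2 or not (0 <= m1 < self.n and 0 <= m2 < self.n):
            raise ValueError("mortality nodes must be two distinct valid nodes")
        degrees = np.diff(self.indptr)
        if (degrees == 0).any():
            bad = int(np.flatnonzero(degrees == 0)[0])
            raise ValueError(f"node {bad} has no neighbours")

    # --- basic accessors ------------------------------------------------

    def neighbours(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def n_edges(self) -> int:
        return int(self.indices.size // 2)

    def edges(self) -> Iterable[tuple[int, int]]:
        """Each undirected edge once, as (u, v) with u < v."""
        for u in range(self.n):
            for v in self.neighbours(u):
                if u < v:
                    yield u, int(v)

    # --- constructors ---------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Sequence[tuple[int, int]],
        mortality_nodes: tuple[int, int] | None = None,
    ) -> "HealthNetwork":
        """Build from an undirected edge list; validates simple-graph structure.

        If ``mortality_nodes`` is not given, the two highest-degree nodes are
        used (ties broken by lowest node id).
        """
        seen: set[tuple[int, int]] = set()
        adj: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) outside node range")
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            adj[u].append(v)
            adj[v].append(u)
        indptr = np.zeros(n + 1, dtype=np.int64)
        for i in range(n):
            indptr[i + 1] = indptr[i] + len(adj[i])
        indices = np.concatenate([np.sort(a) for a in adj if a]).astype(np.int64) \
            if seen else np.empty(0, dtype=np.int64)
        if indices.size != indptr[-1]:  # some node had no neighbours
            raise ValueError("every node must have at least one neighbour")
        degrees = np.diff(indptr)
        if mortality_nodes is None:
            order = np.lexsort((np.arange(n), -degrees))
            mortality_nodes = (int(order[0]), int(order[1]))
        aging = np.setdiff1d(np.arange(n), np.asarray(mortality_nodes))
        return cls(n, indptr, indices, tuple(mortality_nodes), aging)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "HealthNetwork":
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
        return cls.from_edges(g.number_of_nodes(), edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        return g

    # --- I/O --------------------------------------------------------------

    def to_edgelist(self, path: str | Path) -> None:
        """Write "u v" pairs, one per line, with a header naming the mortality nodes."""
        with open(path, "w") as fh:
            fh.write(f"# mortality_nodes {self.mortality_nodes[0]} {self.mortality_nodes[1]}\n")
            for u, v in self.edges():
                fh.write(f"{u} {v}\n")

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "HealthNetwork":
        mortality: tuple[int, int] | None = None
        edges: list[tuple[int, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split()
                    if parts and parts[0] == "mortality_nodes":
                        mortality = (int(parts[1]), int(parts[2]))
                    continue
                u, v = line.split()
                edges.append((int(u), int(v)))
        n = max(max(u, v) for u, v in edges) + 1
        return cls.from_edges(n, edges, mortality_nodes=mortality)


def degree_assortativity(net: HealthNetwork) -> float:
    """Pearson correlation of degrees at edge endpoints.

    Each undirected edge is counted in both orientations. Returns NaN when
    the endpoint-degree variance vanishes (e.g. regular graphs); raises on
    an edgeless network.
    """
    if net.n_edges == 0:
        raise ValueError("degree assortativity is undefined without edges")
    deg = net.degrees.astype(float)
    # degree of the source endpoint for every directed edge
    src = np.repeat(np.arange(net.n), net.degrees)
    x = deg[src]
    y = deg[net.indices]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / np.sqrt(vx * vy))


def generate_network(
    n: int,
    attachment: int,
    rewiring_steps: int | None = None,
    seed: int = 0,
) -> HealthNetwork:
    """Scale-free disassortative health network.

    Barabási–Albert preferential attachment (``attachment`` edges per new
    node) followed by degree-preserving double-edge swaps accepted iff they
    strictly decrease the degree-assortativity coefficient. With the degree
    sequence fixed, assortativity is monotone in sum(d_u * d_v) over edges,
    so a swap replacing (a,b),(c,d) with (a,d),(c,b) is accepted iff
    (d_a - d_c)(d_b - d_d) > 0. ``rewiring_steps`` counts proposals and
    defaults to 10x the edge count. Mortality nodes are the two
    highest-degree nodes (ties broken by lowest node id).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if attachment < 1 or attachment >= n:
        raise ValueError("attachment must satisfy 1 <= attachment < n")
    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, attachment, seed=int(rng.integers(2**31)))

    edges = np.array(g.edges(), dtype=np.int64)
    deg = np.zeros(n, dtype=np.int64)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    edge_set = {(min(u, v), max(u, v)) for u, v in map(tuple, edges)}
    n_e = len(edges)
    if rewiring_steps is None:
        rewiring_steps = 10 * n_e

    for _ in range(rewiring_steps):
        i, j = rng.integers(n_e), rng.integers(n_e)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # orientation of the second edge
            c, d = d, c
        # proposed: (a,d), (c,b)
        if a == d or c == b:
            continue
        if (deg[a] - deg[c]) * (deg[b] - deg[d]) <= 0:
            continue  # would not strictly decrease assortativity
        e1 = (min(a, d), max(a, d))
        e2 = (min(c, b), max(c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.discard((min(c, d), max(c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2

    return HealthNetwork.from_edges(n, [tuple(e) for e in edges])
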