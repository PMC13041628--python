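"""Two-layer contact structure: degree-targeted offline graph plus a
Watts-Strogatz small-world online graph on the same node set.

Social influence in the simulation acts on the union neighborhood of the two
layers. Both layers are simple undirected graphs over nodes 0..n-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

# survey social-activity frequency (ordinal 1..5) -> offline degree target
DEGREE_MAP = {1: 2, 2: 4, 3: 6, 4: 8, 5: 10}


def degree_from_social_activity(freq: int) -> int:
    """Map ordinal social-activity frequency (1..5) to an offline degree
    target; linear and monotone, mean near the online layer's degree 6."""
    if freq not in DEGREE_MAP:
        raise ValueError(f"social activity frequency {freq!r} not in 1..5")
    return DEGREE_MAP[freq]


@dataclass
class LayeredNetwork:
    """Fixed-node offline + online layers with a lazy union adjacency view."""

    n: int
    offline_edges: set[tuple[int, int]]
    online_edges: set[tuple[int, int]]
    _adj: list[set] | None = field(default=None, repr=False, compare=False)
    _csr: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for layer in (self.offline_edges, self.online_edges):
            for u, v in layer:
                if u == v:
                    raise ValueError("self-loop in layer")
                if not (0 <= u < self.n and 0 <= v < self.n):
                    raise ValueError("edge endpoint out of range")

    def _build_adj(self) -> list[set]:
        adj = [set() for _ in range(self.n)]
        for layer in (self.offline_edges, self.online_edges):
            for u, v in layer:
                adj[u].add(v)
                adj[v].add(u)
        return adj

    def union_neighbors(self, i: int) -> set[int]:
        """Union of the offline and online neighbor sets of node i."""
        if not 0 <= i < self.n:
            raise ValueError(f"node {i} out of range")
        if self._adj is None:
            self._adj = self._build_adj()
        return self._adj[i]

    def union_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Union adjacency in CSR form (indptr, indices) for the simulator."""
        if self._csr is not None:
            return self._csr
        if self._adj is None:
            self._adj = self._build_adj()
        degs = np.fromiter((len(s) for s in self._adj), int, self.n)
        indptr = np.zeros(self.n + 1, np.int64)
        indptr[1:] = np.cumsum(degs)
        indices = np.empty(indptr[-1], np.int64)
        for i, s in enumerate(self._adj):
            indices[indptr[i]:indptr[i + 1]] = sorted(s)
        self._csr = (indptr, indices)
        return self._csr

    def to_edge_lists(self) -> dict[str, np.ndarray]:
        return {
            "offline": np.array(sorted(self.offline_edges), int).reshape(-1, 2),
            "online": np.array(sorted(self.online_edges), int).reshape(-1, 2),
        }


def union_neighbors(net: LayeredNetwork, i: int) -> set[int]:
    return net.union_neighbors(i)


# ---------------------------------------------------------------------------
# offline layer: degree-targeted simple graph


def _edge(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


def build_offline(degree_targets, seed: int = 0,
                  max_repair_rounds: int = 50) -> set[tuple[int, int]]:
    """Randomized stub matching toward per-node degree targets.

    Stubs are shuffled and paired; pairs that would form a self-loop or a
    duplicate edge are rejected, and a bounded repair pass rewires leftover
    stubs via edge swaps. An odd total stub count is resolved by decrementing
    one randomly chosen node's target. Realized degrees are within +-1 of the
    target for graphical sequences (checked statistically in the tests).
    """
    targets = np.asarray(degree_targets, int).copy()
    n = targets.size
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if np.any(targets < 0):
        raise ValueError("degree targets must be non-negative")
    rng = np.random.default_rng(seed)
    if targets.sum() == 0:
        warnings.warn("all degree targets are zero: returning an empty graph")
        return set()
    if targets.sum() % 2 == 1:
        pos = np.flatnonzero(targets > 0)
        targets[rng.choice(pos)] -= 1

    stubs = np.repeat(np.arange(n), targets)
    rng.shuffle(stubs)
    edges: set[tuple[int, int]] = set()
    leftover: list[int] = []
    for u, v in stubs.reshape(-1, 2):
        u, v = int(u), int(v)
        if u == v or _edge(u, v) in edges:
            leftover.extend((u, v))
        else:
            edges.add(_edge(u, v))

    # repair: pair leftover stubs; on conflict, swap with a random existing
    # edge (u,v)+(a,b) -> (u,a)+(v,b) when that keeps the graph simple
    for _ in range(max_repair_rounds):
        if len(leftover) < 2:
            break
        rng.shuffle(leftover)
        still = []
        edge_list = None
        for u, v in zip(leftover[::2], leftover[1::2]):
            if u != v and _edge(u, v) not in edges:
                edges.add(_edge(u, v))
                continue
            repaired = False
            if edges:
                if edge_list is None:
                    edge_list = list(edges)
                for _try in range(20):
                    a, b = edge_list[rng.integers(len(edge_list))]
                    if (a, b) not in edges:  # stale after prior swap
                        continue
                    for (p, q) in ((a, b), (b, a)):
                        if (u != p and v != q and _edge(u, p) not in edges
                                and _edge(v, q) not in edges and u != v):
                            edges.discard((a, b))
                            edges.add(_edge(u, p))
                            edges.add(_edge(v, q))
                            edge_list = None
                            repaired = True
                            break
                    if repaired:
                        break
            if not repaired:
                still.extend((u, v))
        if len(leftover) % 2:
            still.append(leftover[-1])
        if len(still) == len(leftover):
            break  # no progress
        leftover = still
    return edges


def build_online_ws(n: int, k: int = 6, p: float = 0.10,
                    seed: int = 0) -> set[tuple[int, int]]:
    """Watts-Strogatz small-world layer: ring lattice with k/2 neighbors per
    side, each lattice edge rewired with probability p; exactly n*k/2 edges."""
    if k % 2 or k < 2:
        raise ValueError("mean degree k must be even and >= 2")
    if k >= n:
        raise ValueError("k must be smaller than n")
    if not 0 <= p <= 1:
        raise ValueError("rewiring probability must be in [0, 1]")
    g = nx.watts_strogatz_graph(n, k, p, seed=int(seed))
    return {_edge(u, v) for u, v in g.edges()}


def build_layered(degree_targets, n: int | None = None, ws_k: int = 6,
                  ws_p: float = 0.10, seed: int = 0,
                  online_active=None) -> LayeredNetwork:
    """Build both layers from one seed (independent sub-streams).

    ``online_active`` optionally restricts the online layer: a boolean mask
    per node, and online edges touching an inactive node (e.g. an agent
    below a digital-use cutoff) are dropped. Default: all agents online.
    """
    targets = np.asarray(degree_targets, int)
    n = targets.size if n is None else n
    s_off, s_on = np.random.SeedSequence(seed).spawn(2)
    offline = build_offline(targets, seed=s_off.generate_state(1)[0] % (2**31))
    online = build_online_ws(n, ws_k, ws_p, seed=int(s_on.generate_state(1)[0] % (2**31)))
    if online_active is not None:
        active = np.asarray(online_active, bool)
        if active.size != n:
            raise ValueError("online_active mask must have one entry per node")
        online = {(u, v) for u, v in online if active[u] and active[v]}
    return LayeredNetwork(n=n, offline_edges=offline, online_edges=online)
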