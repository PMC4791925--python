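"""Contact-network builders and descriptors.

Both games in this package run on undirected contact graphs.  The reference
structure is the Moore-neighborhood square lattice on a torus, where every
individual interacts with its eight nearest neighbors (orthogonal plus
diagonal), giving a mean local clustering coefficient of exactly 3/7.  Two
comparison structures are provided: a uniform random graph matched on mean
degree, and partially rewired lattices that interpolate between the two while
preserving every node's degree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "build_grid_lattice",
    "build_random_network",
    "rewire_network",
    "mean_local_clustering",
    "network_from_edges",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(eq=False)
class Network:
    """An undirected simple graph with provenance metadata.

    Attributes
    ----------
    n_nodes:
        Number of nodes, labelled ``0 .. n_nodes - 1``.
    edges:
        ``(m, 2)`` integer array of unordered edges, canonicalized so that
        ``u < v`` in every row and rows are lexicographically sorted.
    kind:
        One of ``grid``, ``rewired_grid``, ``random``, ``custom``.
    side:
        Grid side length, for grid-derived networks only.
    fraction_rewired:
        Fraction of original lattice edges no longer present, for
        ``rewired_grid`` only.
    """

    n_nodes: int
    edges: np.ndarray
    kind: str = "custom"
    side: Optional[int] = None
    fraction_rewired: Optional[float] = None
    _adj: Optional[sp.csr_matrix] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges = edges[order]
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-loops are not allowed")
            if np.any(np.all(edges[1:] == edges[:-1], axis=1)):
                raise ValueError("duplicate edges are not allowed")
        self.edges = edges

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Boolean-valued CSR adjacency matrix (symmetric, cached)."""
        if self._adj is None:
            u, v = self.edges[:, 0], self.edges[:, 1]
            row = np.concatenate([u, v])
            col = np.concatenate([v, u])
            data = np.ones(row.shape[0], dtype=np.int8)
            adj = sp.coo_matrix(
                (data, (row, col)), shape=(self.n_nodes, self.n_nodes)
            ).tocsr()
            adj.sort_indices()
            self._adj = adj
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel().astype(np.int64)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


def network_from_edges(n_nodes: int, edges, kind: str = "custom") -> Network:
    """Wrap an explicit edge list (iterable of pairs) as a :class:`Network`."""
    return Network(n_nodes=n_nodes, edges=np.asarray(list(edges)), kind=kind)


def build_grid_lattice(side: int) -> Network:
    """Moore-neighborhood square lattice on a torus.

    Every node is adjacent to its eight surrounding cells (N, S, E, W plus the
    four diagonals) with wrap-around, so every node has degree exactly 8 and
    the graph has ``4 * side**2`` edges.

    Parameters
    ----------
    side:
        Grid side length; must be at least 3 (below 3 the wrap-around Moore
        offsets collide, producing self-loops or multi-edges).
    """
    if side < 3:
        raise ValueError(f"side must be >= 3, got {side}")
    n = side * side
    nodes = np.arange(n)
    r, c = nodes // side, nodes % side
    # one representative direction per undirected neighbor pair
    offsets = [(0, 1), (1, 0), (1, 1), (1, -1)]
    chunks = []
    for dr, dc in offsets:
        nbr = ((r + dr) % side) * side + (c + dc) % side
        chunks.append(np.column_stack([nodes, nbr]))
    edges = np.concatenate(chunks)
    return Network(n_nodes=n, edges=edges, kind="grid", side=side)


def build_random_network(
    n_nodes: int,
    mean_degree: float = 8.0,
    rng: np.random.Generator | None = None,
) -> Network:
    """Uniform random simple graph with an exact edge count.

    Draws uniformly from graphs on ``n_nodes`` nodes with exactly
    ``round(n_nodes * mean_degree / 2)`` edges (the G(n, m) model), so the mean
    degree matches ``mean_degree`` up to rounding.  The fixed-edge-count model
    is used rather than independent-edge sampling so that the comparison with
    the lattice is matched exactly on edge count.
    """
    if rng is None:
        rng = np.random.default_rng()
    m = round(n_nodes * mean_degree / 2)
    max_edges = n_nodes * (n_nodes - 1) // 2
    if m > max_edges:
        raise ValueError(
            f"{m} edges requested but a simple graph on {n_nodes} nodes "
            f"holds at most {max_edges}"
        )
    g = nx.gnm_random_graph(n_nodes, m, seed=rng)
    edges = np.array(list(g.edges()), dtype=np.int64).reshape(-1, 2)
    return Network(n_nodes=n_nodes, edges=edges, kind="random")


def _as_edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


class _SampleableSet:
    """Set with O(1) membership, add, remove, and uniform sampling."""

    def __init__(self, items):
        self.items: list = list(items)
        self.pos: dict = {e: i for i, e in enumerate(self.items)}

    def __contains__(self, item) -> bool:
        return item in self.pos

    def __len__(self) -> int:
        return len(self.items)

    def add(self, item) -> None:
        if item not in self.pos:
            self.pos[item] = len(self.items)
            self.items.append(item)

    def remove(self, item) -> None:
        i = self.pos.pop(item)
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def sample(self, rng: np.random.Generator):
        return self.items[rng.integers(len(self.items))]


def rewire_network(
    network: Network,
    n_rewired_edges: int,
    rng: np.random.Generator | None = None,
    method: str = "degree_preserving_swap",
    max_tries_per_step: int = 100,
) -> Network:
    """Rewire a pristine grid lattice until exactly ``n_rewired_edges`` of the
    original lattice edges are gone.

    Two methods are provided:

    ``degree_preserving_swap`` (default)
        Double-edge swaps: pick two current edges a-b, c-d on four distinct
        nodes and replace them with a-d, c-b when the result stays simple.
        The full degree sequence is preserved — every node keeps all eight
        neighbors — which is the defining property of this small-world
        interpolation.
    ``delete_and_replace``
        Literal deletion of a surviving lattice edge followed by insertion of
        a uniformly random new edge.  Preserves the edge count and hence the
        mean degree, but not individual degrees.

    Progress is made by randomized search; if no feasible move is found in
    ``max_tries_per_step`` attempts the function raises, reporting how many
    rewirings were still owed.
    """
    if network.kind != "grid":
        raise ValueError("rewire_network expects a pristine grid lattice")
    if n_rewired_edges < 0 or n_rewired_edges > network.n_edges:
        raise ValueError(
            f"n_rewired_edges must be in [0, {network.n_edges}], got {n_rewired_edges}"
        )
    if rng is None:
        rng = np.random.default_rng()

    lattice = network.edge_set()
    total = network.n_edges
    if n_rewired_edges == 0:
        return Network(
            n_nodes=network.n_nodes,
            edges=network.edges.copy(),
            kind="rewired_grid",
            side=network.side,
            fraction_rewired=0.0,
        )

    current = set(lattice)

    def removed_count() -> int:
        return sum(1 for e in lattice if e not in current)

    if method == "degree_preserving_swap":
        cur = _SampleableSet(current)
        surviving = _SampleableSet(current & lattice)
        nonlattice = _SampleableSet(current - lattice)
        removed = 0
        while removed < n_rewired_edges:
            remaining = n_rewired_edges - removed
            moved = False
            for _ in range(max_tries_per_step):
                if len(surviving) == 0:
                    break
                a, b = surviving.sample(rng)
                # a swap of two lattice edges removes two at once; when only
                # one rewiring is owed the partner edge must be non-lattice
                if remaining == 1 and len(nonlattice) > 0:
                    c, d = nonlattice.sample(rng)
                else:
                    c, d = cur.sample(rng)
                if rng.integers(2):
                    c, d = d, c
                if len({a, b, c, d}) < 4:
                    continue
                new1, new2 = _as_edge_key(a, d), _as_edge_key(c, b)
                if new1 == new2 or new1 in cur or new2 in cur:
                    continue
                old1, old2 = _as_edge_key(a, b), _as_edge_key(c, d)
                delta = (old1 in lattice) + (old2 in lattice)
                delta -= (new1 in lattice) + (new2 in lattice)
                if delta <= 0 or delta > remaining:
                    continue
                for old in (old1, old2):
                    cur.remove(old)
                    if old in lattice:
                        surviving.remove(old)
                    else:
                        nonlattice.remove(old)
                for new in (new1, new2):
                    cur.add(new)
                    if new in lattice:
                        surviving.add(new)
                    else:
                        nonlattice.add(new)
                removed += delta
                moved = True
                break
            if not moved:
                raise RuntimeError(
                    f"no feasible degree-preserving swap found; "
                    f"{n_rewired_edges - removed} rewirings still owed"
                )
        current = set(cur.items)
    elif method == "delete_and_replace":
        n_total_pairs = network.n_nodes
        for _ in range(n_rewired_edges):
            surviving = [e for e in current if e in lattice]
            old = surviving[rng.integers(len(surviving))]
            placed = False
            for _ in range(max_tries_per_step):
                u = int(rng.integers(n_total_pairs))
                v = int(rng.integers(n_total_pairs))
                if u == v:
                    continue
                new = _as_edge_key(u, v)
                if new in current or new == old:
                    continue
                current.discard(old)
                current.add(new)
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    "no feasible replacement edge found; "
                    f"{n_rewired_edges - removed_count()} rewirings still owed"
                )
    else:
        raise ValueError(f"unknown rewiring method: {method!r}")

    edges = np.array(sorted(current), dtype=np.int64)
    return Network(
        n_nodes=network.n_nodes,
        edges=edges,
        kind="rewired_grid",
        side=network.side,
        fraction_rewired=n_rewired_edges / total,
    )


def mean_local_clustering(network: Network) -> float:
    """Mean local clustering coefficient.

    Average over all nodes of (edges among the node's neighbors) / (pairs of
    neighbors); nodes of degree < 2 contribute 0.  For the Moore lattice with
    side >= 5 this is exactly 3/7 (42.9%); for a G(n, m) random graph it is
    close to the edge density, about ``mean_degree / (n - 1)``.
    """
    return float(nx.average_clustering(network.to_networkx(), count_zeros=True))


def write_edge_list(network: Network, path_or_file) -> None:
    """Write a network as a plain-text edge list with a metadata header."""
    header = [f"# kind={network.kind}"]
    if network.side is not None:
        header.append(f"# side={network.side}")
    if network.fraction_rewired is not None:
        header.append(f"# fraction_rewired={network.fraction_rewired!r}")
    header.append(f"# n_nodes={network.n_nodes}")
    lines = header + [f"{u} {v}" for u, v in network.edges]
    text = "\n".join(lines) + "\n"
    if isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__"):
        with open(path_or_file, "w") as fh:
            fh.write(text)
    else:
        path_or_file.write(text)


def read_edge_list(path_or_file) -> Network:
    """Read a network written by :func:`write_edge_list`."""
    if isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__"):
        with open(path_or_file) as fh:
            text = fh.read()
    else:
        text = path_or_file.read()
    meta: dict[str, str] = {}
    edges = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        u, v = line.split()
        edges.append((int(u), int(v)))
    n_nodes = int(meta.get("n_nodes", max(max(e) for e in edges) + 1))
    side = int(meta["side"]) if "side" in meta else None
    frac = float(meta["fraction_rewired"]) if "fraction_rewired" in meta else None
    return Network(
        n_nodes=n_nodes,
        edges=np.asarray(edges, dtype=np.int64),
        kind=meta.get("kind", "custom"),
        side=side,
        fraction_rewired=frac,
    )
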