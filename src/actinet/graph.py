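"""Two-neighbourhood automaton network built from atomic coordinates.

Every atom becomes a node with a *hard* neighbourhood (its covalently bonded
partners) and a *soft* neighbourhood (all non-bonded atoms within Euclidean
distance ``rho``).  Structural statistics over both neighbourhoods are
computed here.
"""

from __future__ import annotations

from typing import IO, Sequence

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .structure_io import AtomSet

__all__ = [
    "FilamentGraph",
    "build_graph",
    "hard_degree_ratios",
    "soft_degree_histogram",
    "mean_bond_length",
    "save_graph",
    "load_graph",
]


def _pairs_to_adjacency(n: int, pairs: np.ndarray) -> list[np.ndarray]:
    """Turn an (m, 2) array of undirected index pairs into sorted adjacency lists."""
    if len(pairs) == 0:
        return [np.empty(0, dtype=np.int64) for _ in range(n)]
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=n)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    return [dst[offsets[i] : offsets[i + 1]].copy() for i in range(n)]


class FilamentGraph:
    """Static network with hard (bonded) and soft (proximity) neighbourhoods.

    Attributes
    ----------
    coords : (n, 3) float array of node coordinates in Å.
    hard : per-node sorted arrays of bonded neighbour indices.
    soft : per-node sorted arrays of non-bonded neighbours within ``rho``.
    rho : soft-neighbourhood radius in Å.
    """

    def __init__(
        self,
        coords: np.ndarray,
        hard_pairs: np.ndarray,
        soft_pairs: np.ndarray,
        rho: float,
    ) -> None:
        self.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        self.hard_pairs = np.asarray(hard_pairs, dtype=np.int64).reshape(-1, 2)
        self.soft_pairs = np.asarray(soft_pairs, dtype=np.int64).reshape(-1, 2)
        self.rho = float(rho)
        self.hard = _pairs_to_adjacency(n, self.hard_pairs)
        self.soft = _pairs_to_adjacency(n, self.soft_pairs)
        self.hard_degrees = np.array([len(a) for a in self.hard], dtype=np.int64)
        self.soft_degrees = np.array([len(a) for a in self.soft], dtype=np.int64)
        self.total_degrees = (self.hard_degrees + self.soft_degrees).astype(np.float64)
        self._weighted_cache: dict[float, sparse.csr_matrix] = {}

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def _pair_matrix(self, pairs: np.ndarray) -> sparse.csr_matrix:
        n = self.n_nodes
        if len(pairs) == 0:
            return sparse.csr_matrix((n, n))
        row = np.concatenate([pairs[:, 0], pairs[:, 1]])
        col = np.concatenate([pairs[:, 1], pairs[:, 0]])
        data = np.ones(len(row), dtype=np.float64)
        return sparse.csr_matrix((data, (row, col)), shape=(n, n))

    def weighted_adjacency(self, mu: float) -> sparse.csr_matrix:
        """CSR matrix ``H + mu * S`` used to count weighted excited neighbours."""
        mu = float(mu)
        if mu not in self._weighted_cache:
            self._weighted_cache[mu] = self._pair_matrix(
                self.hard_pairs
            ) + mu * self._pair_matrix(self.soft_pairs)
        return self._weighted_cache[mu]


def build_graph(
    atoms: AtomSet, bonds: Sequence[tuple[int, int]] | None, rho: float
) -> FilamentGraph:
    """Build the two-neighbourhood network from atoms, bonds and soft radius.

    ``bonds`` are pairs of atom *ids* (defaulting to ``atoms.bonds``); soft
    neighbours are all non-bonded nodes at distance ``d <= rho`` (inclusive).
    The spatial query uses a KD-tree but is contractually identical to an
    all-pairs distance scan.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    if bonds is None:
        bonds = atoms.bonds
    index = atoms.index_of()
    hard_set: set[tuple[int, int]] = set()
    for a, b in bonds:
        if a not in index or b not in index:
            raise ValueError(f"bond ({a}, {b}) references an unknown atom id")
        i, j = index[a], index[b]
        if i == j:
            raise ValueError(f"bond ({a}, {b}) links an atom to itself")
        hard_set.add((min(i, j), max(i, j)))
    hard_pairs = np.array(sorted(hard_set), dtype=np.int64).reshape(-1, 2)

    tree = cKDTree(atoms.coords)
    close = tree.query_pairs(rho, output_type="ndarray")
    if len(close) == 0:
        soft_pairs = np.empty((0, 2), dtype=np.int64)
    else:
        close = np.sort(close, axis=1)
        if hard_set:
            keep = np.fromiter(
                ((int(i), int(j)) not in hard_set for i, j in close),
                dtype=bool,
                count=len(close),
            )
            close = close[keep]
        soft_pairs = close.astype(np.int64)
    return FilamentGraph(atoms.coords, hard_pairs, soft_pairs, rho)


def hard_degree_ratios(graph: FilamentGraph) -> dict[int, float]:
    """Fraction of nodes per hard (bonded) degree; fractions sum to 1."""
    degrees, counts = np.unique(graph.hard_degrees, return_counts=True)
    n = graph.n_nodes
    return {int(d): float(c) / n for d, c in zip(degrees, counts)}


def soft_degree_histogram(
    graph: FilamentGraph, bin_width: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of node fractions per soft-degree bin.

    Returns ``(bin_edges, fractions)`` where bin ``k`` spans
    ``[edges[k], edges[k + 1])`` and fractions sum to 1.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    degrees = graph.soft_degrees
    n_bins = int(degrees.max()) // bin_width + 1 if graph.n_nodes else 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.bincount(degrees // bin_width, minlength=n_bins)
    return edges, counts / max(graph.n_nodes, 1)


def mean_bond_length(graph: FilamentGraph) -> float:
    """Arithmetic mean Euclidean distance over unordered hard edges."""
    if len(graph.hard_pairs) == 0:
        raise ValueError("graph has no hard edges")
    diffs = graph.coords[graph.hard_pairs[:, 0]] - graph.coords[graph.hard_pairs[:, 1]]
    return float(np.mean(np.linalg.norm(diffs, axis=1)))


def save_graph(graph: FilamentGraph, nodes: IO[str], edges: IO[str]) -> None:
    """Write the graph as two delimited-text streams (nodes and typed edges)."""
    nodes.write(f"# rho\t{graph.rho}\n")
    nodes.write("id\tx\ty\tz\n")
    for i, (x, y, z) in enumerate(graph.coords):
        nodes.write(f"{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
    edges.write("id_a\tid_b\tkind\n")
    for a, b in graph.hard_pairs:
        edges.write(f"{a}\t{b}\thard\n")
    for a, b in graph.soft_pairs:
        edges.write(f"{a}\t{b}\tsoft\n")


def load_graph(nodes: IO[str], edges: IO[str]) -> FilamentGraph:
    """Read a graph previously written by :func:`save_graph`."""
    lines = [ln for ln in nodes.read().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# rho"):
        raise ValueError("node file missing '# rho' header")
    rho = float(lines[0].split("\t")[1])
    coords = np.array(
        [[float(v) for v in ln.split("\t")[1:4]] for ln in lines[2:]], dtype=np.float64
    ).reshape(-1, 3)
    hard, soft = [], []
    for ln in edges.read().splitlines()[1:]:
        if not ln.strip():
            continue
        a, b, kind = ln.split("\t")
        (hard if kind == "hard" else soft).append((int(a), int(b)))
    return FilamentGraph(
        coords,
        np.array(hard, dtype=np.int64).reshape(-1, 2),
        np.array(soft, dtype=np.int64).reshape(-1, 2),
        rho,
    )
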