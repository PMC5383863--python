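"""Interaction-network generation and plain-text edge-list I/O.

Games are played on undirected simple graphs with 0-based contiguous node
ids.  The main generator is the uncorrelated configuration model (UCM):
degrees are drawn from a truncated power law P(k) ~ k^-gamma on
{kmin..kmax} and stubs are matched at random, rejecting matchings that
produce self-loops or multi-edges.  The structural cutoff kmax = floor(sqrt(N))
keeps the resulting scale-free networks free of degree correlations.

Deterministic topologies (ring, wheel, complete graph) are provided as
exactly solvable substrates for the game dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "DegreeSequence",
    "Graph",
    "sample_powerlaw_degree_sequence",
    "truncated_powerlaw_mean",
    "build_ucm_graph",
    "make_wheel",
    "make_ring",
    "make_complete",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class DegreeSequence:
    """A realized degree sequence with its generating parameters.

    ``degrees[i]`` is the desired degree of node ``i``.  The sum of
    degrees is even (a requirement for stub matching) and every degree
    lies in ``[kmin, kmax]``.
    """

    degrees: np.ndarray
    gamma: float
    kmin: int
    kmax: int

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=np.int64)
        object.__setattr__(self, "degrees", d)
        if d.size < 3:
            raise ValueError("need at least 3 nodes")
        if d.sum() % 2 != 0:
            raise ValueError("sum of degrees must be even")
        if d.min() < self.kmin or d.max() > self.kmax:
            raise ValueError("degrees outside [kmin, kmax]")

    @property
    def N(self) -> int:
        return int(self.degrees.size)


class Graph:
    """Undirected simple graph on nodes ``0..N-1``.

    Stores the edge set canonically (u < v, lexicographically sorted) and
    caches the adjacency structure in CSR form, plus the *participation*
    layout used by the game engine: node i takes part in the k_i + 1 games
    centred on the members of its closed neighbourhood nu_i = {i} u N(i).
    """

    def __init__(self, n: int, edges) -> None:
        if n < 1:
            raise ValueError("graph needs at least one node")
        e = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                       dtype=np.int64)
        if e.size == 0:
            e = e.reshape(0, 2)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be pairs")
        if e.size and (e.min() < 0 or e.max() >= n):
            raise ValueError("edge endpoint out of range")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loops not allowed")
        e = np.sort(e, axis=1)
        order = np.lexsort((e[:, 1], e[:, 0]))
        e = e[order]
        if e.shape[0] > 1 and np.any(np.all(np.diff(e, axis=0) == 0, axis=1)):
            raise ValueError("duplicate edges not allowed")
        self.N = int(n)
        self.edges = e
        self._adj: tuple[np.ndarray, np.ndarray] | None = None
        self._games: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._degrees: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        if self._degrees is None:
            self._degrees = np.bincount(self.edges.ravel(), minlength=self.N)
        return self._degrees

    def degree(self, i: int) -> int:
        return int(self.degrees[i])

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR neighbour lists: (ptr, idx); neighbours of i are
        idx[ptr[i]:ptr[i+1]], sorted ascending."""
        if self._adj is None:
            deg = self.degrees
            ptr = np.zeros(self.N + 1, dtype=np.int64)
            np.cumsum(deg, out=ptr[1:])
            idx = np.empty(2 * self.n_edges, dtype=np.int64)
            # both directions, sorted per row because edges are lexsorted
            src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            order = np.lexsort((dst, src))
            idx[:] = dst[order]
            self._adj = (ptr, idx)
        return self._adj

    def neighbors(self, i: int) -> np.ndarray:
        ptr, idx = self.adjacency()
        return idx[ptr[i]:ptr[i + 1]]

    def neighborhood(self, i: int) -> np.ndarray:
        """Closed neighbourhood nu_i = {i} plus neighbours, sorted."""
        return np.sort(np.append(self.neighbors(i), i))

    def games(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Participation layout (row_ptr, row, col).

        Flat index p runs over all ordered pairs (i, j) with j in nu_i;
        row[p] = i (the investor), col[p] = j (the focal player).  Row i
        occupies the contiguous slice row_ptr[i]:row_ptr[i+1] of length
        k_i + 1, with col sorted ascending inside each row.
        """
        if self._games is None:
            sizes = self.degrees + 1
            row_ptr = np.zeros(self.N + 1, dtype=np.int64)
            np.cumsum(sizes, out=row_ptr[1:])
            row = np.repeat(np.arange(self.N, dtype=np.int64), sizes)
            _, idx = self.adjacency()
            nodes = np.arange(self.N, dtype=np.int64)
            src = np.concatenate([np.repeat(nodes, self.degrees), nodes])
            dst = np.concatenate([idx, nodes])
            order = np.lexsort((dst, src))
            self._games = (row_ptr, row, dst[order])
        return self._games

    def edge_key_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(v)) for u, v in self.edges}

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.N == other.N and np.array_equal(self.edges, other.edges)

    def __repr__(self) -> str:
        return f"Graph(N={self.N}, E={self.n_edges})"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        mapping = {u: i for i, u in enumerate(sorted(g.nodes()))}
        edges = [(mapping[u], mapping[v]) for u, v in g.edges()]
        return cls(g.number_of_nodes(), edges)


# -- degree sequences ------------------------------------------------------

def _powerlaw_pmf(gamma: float, kmin: int, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    ks = np.arange(kmin, kmax + 1, dtype=np.int64)
    w = ks.astype(float) ** (-gamma)
    return ks, w / w.sum()


def truncated_powerlaw_mean(gamma: float, kmin: int, kmax: int) -> float:
    """Exact mean of the truncated power law P(k) ~ k^-gamma on {kmin..kmax}."""
    ks, p = _powerlaw_pmf(gamma, kmin, kmax)
    return float(np.dot(ks, p))


def _validate_bounds(N: int, gamma: float, kmin: int, kmax: int) -> None:
    if N < 3:
        raise ValueError("N must be >= 3")
    if gamma <= 1:
        raise ValueError("gamma must be > 1")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if kmin > kmax:
        raise ValueError(f"kmin ({kmin}) > kmax ({kmax})")
    if kmax >= N:
        raise ValueError(f"kmax ({kmax}) must be < N ({N})")


def sample_powerlaw_degree_sequence(
    N: int,
    gamma: float = 2.5,
    kmin: int = 2,
    kmax: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> DegreeSequence:
    """Draw N i.i.d. degrees from the truncated power law on {kmin..kmax}.

    ``kmax`` defaults to the structural cutoff floor(sqrt(N)).  If the
    total is odd, one uniformly chosen node's degree is resampled from the
    same law (repeatedly if needed) until the sum is even, which leaves the
    marginal distribution intact.
    """
    if kmax is None:
        kmax = int(np.floor(np.sqrt(N)))
    _validate_bounds(N, gamma, kmin, kmax)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks, p = _powerlaw_pmf(gamma, kmin, kmax)
    degrees = rng.choice(ks, size=N, p=p)
    while degrees.sum() % 2 != 0:
        i = int(rng.integers(N))
        degrees[i] = rng.choice(ks, p=p)
    return DegreeSequence(degrees=degrees, gamma=float(gamma), kmin=int(kmin),
                          kmax=int(kmax))


# -- uncorrelated configuration model --------------------------------------

def _matching_is_simple(u: np.ndarray, v: np.ndarray) -> bool:
    if np.any(u == v):
        return False
    lo = np.minimum(u, v)
    hi = np.maximum(u, v)
    key = lo * (hi.max() + 1) + hi
    return np.unique(key).size == key.size


def _repair_multigraph(u: np.ndarray, v: np.ndarray, rng: np.random.Generator,
                       max_trials: int) -> np.ndarray | None:
    """Remove self-loops/multi-edges by degree-preserving double-edge swaps."""
    edges = [(int(a), int(b)) for a, b in zip(u, v)]
    from collections import Counter

    def canon(a, b):
        return (a, b) if a <= b else (b, a)

    counts = Counter(canon(a, b) for a, b in edges)

    def is_bad(a, b):
        return a == b or counts[canon(a, b)] > 1

    bad = [i for i, (a, b) in enumerate(edges) if is_bad(a, b)]
    m = len(edges)
    for _ in range(max_trials):
        if not bad:
            return np.array(edges, dtype=np.int64)
        ei = bad[int(rng.integers(len(bad)))]
        ej = int(rng.integers(m))
        if ei == ej:
            continue
        a, b = edges[ei]
        x, y = edges[ej]
        if int(rng.integers(2)):
            x, y = y, x
        # propose (a, x), (b, y)
        if a == x or b == y:
            continue
        if counts[canon(a, x)] >= 1 or counts[canon(b, y)] >= 1:
            continue
        counts[canon(a, b)] -= 1
        counts[canon(x, y)] -= 1
        counts[canon(a, x)] += 1
        counts[canon(b, y)] += 1
        edges[ei] = (a, x)
        edges[ej] = (b, y)
        bad = [i for i, (p, q) in enumerate(edges) if is_bad(p, q)]
    return None


def build_ucm_graph(
    ds: DegreeSequence | np.ndarray | list,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> Graph:
    """Random stub matching realizing ``ds`` exactly as a simple graph.

    ``ds`` may be a :class:`DegreeSequence` or any sequence of degrees.
    Each node gets a number of stubs equal to its degree; stubs are paired
    uniformly at random.  A matching containing a self-loop or multi-edge
    is discarded and redrawn; after ``max_retries`` failed matchings the
    last one is repaired with degree-preserving double-edge swaps (this
    preserves the degree sequence exactly and perturbs the uniform stub
    pairing only on the offending edges).
    """
    degrees = (ds.degrees if isinstance(ds, DegreeSequence)
               else np.asarray(ds, dtype=np.int64))
    N = degrees.size
    if degrees.sum() % 2 != 0:
        raise ValueError("sum of degrees must be even")
    if not nx.is_graphical(degrees.tolist()):
        raise ValueError("degree sequence is not graphical (Erdos-Gallai)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stubs = np.repeat(np.arange(N, dtype=np.int64), degrees)
    last = None
    for _ in range(max(1, max_retries)):
        perm = rng.permutation(stubs)
        u, v = perm[0::2], perm[1::2]
        if _matching_is_simple(u, v):
            g = Graph(N, np.column_stack([u, v]))
            assert np.array_equal(g.degrees, degrees)
            return g
        last = (u, v)
    repaired = _repair_multigraph(last[0], last[1], rng,
                                  max_trials=100 * len(last[0]))
    if repaired is None:
        raise RuntimeError("UCM matching failed: retries and swap repair exhausted")
    g = Graph(N, repaired)
    if not np.array_equal(g.degrees, degrees):
        raise RuntimeError("repair changed the degree sequence")
    return g


# -- deterministic test topologies -----------------------------------------

def make_ring(n: int) -> Graph:
    """Cycle graph on n nodes; every degree is 2."""
    if n < 3:
        raise ValueError("ring needs n >= 3")
    edges = [(i, (i + 1) % n) for i in range(n)]
    return Graph(n, edges)


def make_wheel(n: int) -> Graph:
    """Ring of n nodes plus a central hub (node index n) joined to all.

    Ring nodes have degree 3, the hub degree n; 2n edges in total.
    """
    if n < 3:
        raise ValueError("wheel needs a ring of n >= 3")
    edges = [(i, (i + 1) % n) for i in range(n)]
    edges += [(i, n) for i in range(n)]
    return Graph(n + 1, edges)


def make_complete(n: int) -> Graph:
    if n < 3:
        raise ValueError("complete graph fixture needs n >= 3")
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return Graph(n, edges)


# -- edge-list I/O ---------------------------------------------------------

def read_edge_list(path: str | Path) -> Graph:
    """Read a whitespace-separated edge list (one edge per line, 0-based ids,
    '#' comments).  Self-loops, duplicate edges and malformed lines are
    rejected with the offending line number."""
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected two integers, got {text!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer token in {text!r}") from None
            if u < 0 or v < 0:
                raise ValueError(f"line {lineno}: negative node id")
            if u == v:
                raise ValueError(f"line {lineno}: self-loop {u} {v}")
            key = (min(u, v), max(u, v))
            if key in seen:
                raise ValueError(f"line {lineno}: duplicate edge {u} {v}")
            seen.add(key)
            edges.append((u, v))
    if not edges:
        raise ValueError("empty edge list")
    n = max(max(u, v) for u, v in edges) + 1
    return Graph(n, edges)


def write_edge_list(g: Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# N={g.N} E={g.n_edges}\n")
        for u, v in g.edges:
            fh.write(f"{u} {v}\n")
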