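"""Steady-state observables: investment shares, game production, wealth
concentration and the positive/negative link decomposition.

The production of the game centred on node j is W_j = (r - 1) * pool_j
where pool_j = sum_{l in nu_j} I[l,j] s_l is the capital actually invested
in the game; the normalized production w_j = W_j / (k_j + 1) is bounded by
c (r - 1) and reaches the bound only when every participant is a
cooperator committing her entire capital to that game.  Wealth
concentration is summarized by q80, the fraction of games (ranked from
most to least productive) needed to accumulate 80% of the total normalized
production — the Pareto "80/20" reading gives q80 ~ 0.2.

A directed participation of player i in the game centred on j is classified
*negative* when the game's per-capita return with i present is below what
the remaining participants would earn without i:

    r/(k_j+1) * sum_{l in nu_j} I[l,j] s_l  <  r/k_j * sum_{l in nu_j \\ i} I[l,j] s_l

i.e. when i's contribution falls below the game's mean contribution; the
other players would then be better off if the link did not exist, so a
formal cooperator can act as an effective defector on that link.  Equality
counts as positive.  Projecting the directed classification onto
undirected edges splits the network into a positive layer (empirically a
sparse, near-tree backbone covering most nodes) and a negative layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .game import GameParams, GameState, capital_per_node
from .netgen import Graph
from .simulate import Snapshot

__all__ = [
    "fraction_cooperators",
    "investment_shares",
    "game_production",
    "game_productions",
    "production_by_degree",
    "pareto_q",
    "LinkSignTable",
    "classify_links",
    "split_by_sign",
    "backbone_metrics",
]


def _contrib(state, g: Graph) -> np.ndarray:
    """Effective contributions I[i,j] s_i on the flat pair layout.

    Snapshots carry the measurement-window time average directly; a live
    GameState uses its instantaneous investments and strategies.
    """
    if isinstance(state, Snapshot):
        return state.contrib
    return state.effective_contrib(g)


def _pools(state, g: Graph) -> np.ndarray:
    _, _, col = g.games()
    return np.bincount(col, weights=_contrib(state, g), minlength=g.N)


def fraction_cooperators(state) -> float:
    """f_c = (number of cooperators) / N."""
    return float(np.mean(state.s))


def investment_shares(
    state,
    g: Graph,
    p: GameParams,
    cooperators_only: bool = True,
    bins: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shares I[i,j] / cap_i over ordered pairs, with a histogram on [0, 1].

    By default only cooperators' rows enter the distribution (defectors'
    rows are notional: they invest nothing while defecting).  Returns
    (shares, counts, bin_edges).
    """
    _, row, _ = g.games()
    cap = capital_per_node(g, p)
    shares = state.I / cap[row]
    if cooperators_only:
        shares = shares[state.s[row] == 1]
    counts, edges = np.histogram(shares, bins=bins, range=(0.0, 1.0))
    return shares, counts, edges


def game_productions(state, g: Graph, p: GameParams) -> tuple[np.ndarray, np.ndarray]:
    """(W, w): per-game production and normalized production for all games."""
    pool = _pools(state, g)
    W = (p.r - 1.0) * pool
    return W, W / (g.degrees + 1)


def game_production(state, g: Graph, p: GameParams, j: int) -> tuple[float, float]:
    """Production of the single game centred on node j."""
    W, w = game_productions(state, g, p)
    return float(W[j]), float(w[j])


def production_by_degree(state, g: Graph, p: GameParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw (node, degree, w) points and a per-degree mean/std/count table."""
    _, w = game_productions(state, g, p)
    raw = pd.DataFrame({"node": np.arange(g.N), "degree": g.degrees, "w": w})
    grouped = (raw.groupby("degree")["w"]
               .agg(["mean", "std", "count"])
               .reset_index())
    return raw, grouped


def pareto_q(productions, q: float = 0.8) -> float:
    """Fraction of games, ranked most-productive first, needed to reach a
    share q of the total production.  Ties are broken by node index."""
    w = np.asarray(productions, dtype=float)
    if w.size == 0 or not np.any(w > 0):
        raise ValueError("pareto_q needs at least one strictly positive production")
    if np.any(w < 0):
        raise ValueError("productions must be non-negative")
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    order = np.lexsort((np.arange(w.size), -w))
    csum = np.cumsum(w[order])
    total = csum[-1]
    # tolerate rounding in q*total when the cumulative sum hits it exactly
    thresh = q * total * (1.0 - 1e-12)
    m = int(np.searchsorted(csum, thresh, side="left")) + 1
    return m / w.size


@dataclass
class LinkSignTable:
    """Sign of every directed participation (participant, focal), i != j.

    ``negative[k]`` is True when participant[k]'s contribution to the game
    centred on focal[k] makes the other players worse off than her absence
    would.
    """

    participant: np.ndarray
    focal: np.ndarray
    negative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant,
            "focal": self.focal,
            "sign": np.where(self.negative, "negative", "positive"),
        })


def classify_links(state, g: Graph, p: GameParams) -> LinkSignTable:
    """Classify every directed participation as positive or negative.

    Uses the measurement-window time-averaged contributions when given a
    Snapshot (single instants are noisy under the stochastic dynamics);
    pass a live GameState to classify an instantaneous configuration.
    Self-participations (i = j) are excluded — the criterion concerns a
    participant's effect on the *other* players.  Equality is positive.
    """
    _, row, col = g.games()
    contrib = _contrib(state, g)
    pool = np.bincount(col, weights=contrib, minlength=g.N)
    deg = g.degrees
    off = row != col
    i, j, cij = row[off], col[off], contrib[off]
    kj = deg[j]
    with_i = p.r * pool[j] / (kj + 1)
    without_i = p.r * (pool[j] - cij) / kj
    return LinkSignTable(participant=i, focal=j, negative=with_i < without_i)


def split_by_sign(g: Graph, table: LinkSignTable) -> tuple[Graph, Graph]:
    """Project the directed sign table onto undirected subgraphs.

    An edge {i, j} enters the positive subgraph if EITHER directed
    participation across it is positive, and the negative subgraph if
    either is negative (an edge can appear in both).  Node sets are
    preserved.
    """
    lo = np.minimum(table.participant, table.focal)
    hi = np.maximum(table.participant, table.focal)
    key = lo * g.N + hi
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    neg_s = table.negative[order]
    uniq, start = np.unique(key_s, return_index=True)
    any_neg = np.logical_or.reduceat(neg_s, start)
    any_pos = np.logical_or.reduceat(~neg_s, start)
    edges = np.column_stack([uniq // g.N, uniq % g.N])
    pos = Graph(g.N, edges[any_pos])
    neg = Graph(g.N, edges[any_neg])
    return pos, neg


def backbone_metrics(subgraph: Graph, g: Graph | None = None) -> dict:
    """Coverage and tree-likeness summary of a sign layer.

    coverage   : fraction of nodes incident to at least one edge;
    edge_ratio : edge count over N - 1 (1.0 for a spanning tree);
    n_components counts isolated nodes as their own component.
    """
    n = subgraph.N
    deg = subgraph.degrees
    e = subgraph.n_edges
    if e:
        m = coo_matrix((np.ones(e), (subgraph.edges[:, 0], subgraph.edges[:, 1])),
                       shape=(n, n))
        ncomp = int(connected_components(m, directed=False)[0])
    else:
        ncomp = n
    return {
        "n_nodes": n,
        "n_edges": e,
        "coverage": float(np.mean(deg > 0)),
        "edge_ratio": e / (n - 1) if n > 1 else float("nan"),
        "n_components": ncomp,
        "mean_degree": float(deg.mean()),
    }
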