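"""Public goods game engine with payoff-driven investment allocation.

Every node i of the interaction network plays the k_i + 1 games centred on
the members of its closed neighbourhood nu_i (itself plus its neighbours).
A cooperator's per-round capital — c under the fixed-cost-per-player (FCP)
scheme, (k_i + 1) c under fixed-cost-per-game (FCG) — is redistributed
across those games each round through an exponential (softmax) weighting of
the payoffs the games returned in the previous round:

    I[i,j](t+1) = cap_i * exp(alpha * Pi[i,j](t)) / sum_l exp(alpha * Pi[i,l](t))

with l running over nu_i.  alpha = 0 recovers the classical even split.
The payoff of player i in the game centred on j is

    Pi[i,j] = r/(k_j+1) * sum_{l in nu_j} I[l,j] s_l  -  I[i,j] s_i

with s_l = 1 for cooperators, 0 for defectors, and r the synergy factor.
Strategies evolve synchronously under one of three imitation rules:
replicator-like (copy a random neighbour with probability proportional to
the payoff difference, normalized by the maximum attainable difference M),
unconditional imitation (copy the best neighbour), or the Fermi rule.

All per-pair quantities are stored flat over the participation layout of
:meth:`pggalloc.netgen.Graph.games`, so every operation is a vectorized
pass over ordered pairs (investor, focal game).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .netgen import Graph

__all__ = [
    "GameParams",
    "GameState",
    "capital_per_node",
    "initial_state",
    "allocate_investments",
    "compute_payoffs",
    "normalization_constant",
    "update_strategies_replicator",
    "update_strategies_unconditional_imitation",
    "update_strategies_fermi",
    "step",
    "pair_index",
]

SCHEMES = ("FCP", "FCG")
UPDATE_RULES = ("replicator", "unconditional_imitation", "fermi")


@dataclass(frozen=True)
class GameParams:
    """Game parameters.

    r      : synergy factor applied to the pooled investments of a game.
    c      : capital per round (FCP) or per game (FCG).
    alpha  : allocation intensity; 0 is the classical even split.
    scheme : "FCP" (fixed cost per player) or "FCG" (fixed cost per game).
    update_rule : "replicator", "unconditional_imitation" or "fermi".
    beta   : selection intensity of the Fermi rule (ignored otherwise).
    """

    r: float
    c: float = 1.0
    alpha: float = 0.0
    scheme: str = "FCP"
    update_rule: str = "replicator"
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.update_rule not in UPDATE_RULES:
            raise ValueError(
                f"update_rule must be one of {UPDATE_RULES}, got {self.update_rule!r}")
        if self.update_rule == "fermi" and not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")


@dataclass
class GameState:
    """Dynamic state at round t.

    s        : per-node strategies (1 cooperate, 0 defect), shape (N,).
    I        : investments over ordered pairs (i, j in nu_i), flat shape (P,).
    Pi_pair  : per-pair payoffs Pi[i,j], same layout.
    Pi_tot   : per-node total payoffs, shape (N,).
    """

    t: int
    s: np.ndarray
    I: np.ndarray
    Pi_pair: np.ndarray
    Pi_tot: np.ndarray

    def copy(self) -> "GameState":
        return GameState(self.t, self.s.copy(), self.I.copy(),
                         self.Pi_pair.copy(), self.Pi_tot.copy())

    def effective_contrib(self, g: Graph) -> np.ndarray:
        """I[i,j] * s_i over the flat pair layout (what actually enters pools)."""
        _, row, _ = g.games()
        return self.I * self.s[row]


def capital_per_node(g: Graph, p: GameParams) -> np.ndarray:
    """Per-round capital cap_i: c under FCP, (k_i+1)c under FCG."""
    if p.scheme == "FCP":
        return np.full(g.N, p.c)
    return (g.degrees + 1) * float(p.c)


def initial_state(
    g: Graph,
    p: GameParams,
    seed: int | np.random.Generator | None = None,
    coop_prob: float = 0.5,
) -> GameState:
    """Random 50/50 strategies (by default) and even investment split.

    With all previous payoffs at zero the softmax is flat, so each player's
    capital is divided evenly over her k_i + 1 games.
    """
    if not 0 <= coop_prob <= 1:
        raise ValueError("coop_prob must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row_ptr, row, _ = g.games()
    s = (rng.random(g.N) < coop_prob).astype(np.int8)
    cap = capital_per_node(g, p)
    I = (cap / (g.degrees + 1))[row]
    P = row.size
    return GameState(t=0, s=s, I=I,
                     Pi_pair=np.zeros(P), Pi_tot=np.zeros(g.N))


def allocate_investments(state: GameState, g: Graph, p: GameParams) -> GameState:
    """Softmax reallocation of every player's capital from her last payoffs.

    Rows are shifted by their maximum before exponentiation, so the result
    is invariant under adding a constant to all of a player's payoffs and
    never overflows.  Defectors' rows are updated too: a defector who turns
    cooperator immediately invests according to her last payoff profile.
    Updates ``state.I`` in place and returns the state.
    """
    row_ptr, row, _ = g.games()
    x = p.alpha * state.Pi_pair
    m = np.maximum.reduceat(x, row_ptr[:-1])
    w = np.exp(x - m[row])
    z = np.add.reduceat(w, row_ptr[:-1])
    cap = capital_per_node(g, p)
    state.I = w * (cap / z)[row]
    return state


def compute_payoffs(state: GameState, g: Graph, p: GameParams) -> GameState:
    """Per-pair and total payoffs from the current investments and strategies.

    The pool of game j is sum_{l in nu_j} I[l,j] s_l; each participant
    receives r/(k_j+1) of it and pays in her own contribution.  Updates
    ``Pi_pair`` and ``Pi_tot`` in place and returns the state.
    """
    row_ptr, row, col = g.games()
    contrib = state.I * state.s[row]
    pool = np.bincount(col, weights=contrib, minlength=g.N)
    share = p.r * pool / (g.degrees + 1)
    state.Pi_pair = share[col] - contrib
    state.Pi_tot = np.add.reduceat(state.Pi_pair, row_ptr[:-1])
    return state


def normalization_constant(g: Graph, p: GameParams) -> float:
    """Upper bound M on |Pi_j - Pi_i| for the replicator-like rule.

    FCP: a defector of maximal degree whose every co-player commits full
    capital c to each shared game earns at most r*c*(k_max+1); a cooperator
    who recoups nothing loses c.  FCG: c is replaced by (k_max+1)c in the
    upper bound and the worst loss is (k_max+1)c.  Any valid bound keeps
    the imitation probability in [0, 1]; a loose one only rescales rates
    uniformly.
    """
    kmax = int(g.degrees.max())
    if p.scheme == "FCP":
        upper = p.r * p.c * (kmax + 1)
        lower = -p.c
    else:
        upper = p.r * ((kmax + 1) * p.c) * (kmax + 1)
        lower = -(kmax + 1) * p.c
    return float(upper - lower)


def _pick_random_neighbors(g: Graph, rng: np.random.Generator) -> np.ndarray:
    """One uniformly chosen neighbour per node (self excluded); -1 if isolated."""
    ptr, idx = g.adjacency()
    deg = g.degrees
    u = rng.random(g.N)
    choice = ptr[:-1] + np.floor(u * deg).astype(np.int64)
    j = np.where(deg > 0, idx[np.minimum(choice, ptr[1:] - 1)], -1)
    return j


def update_strategies_replicator(
    state: GameState, g: Graph, M: float, rng: np.random.Generator
) -> GameState:
    """Finite-population replicator-like imitation, synchronous.

    Every player compares with one uniformly random neighbour j and, if
    Pi_j > Pi_i, copies s_j with probability (Pi_j - Pi_i)/M.  Copies read
    the pre-update strategies.  Random draws are consumed in fixed node
    order (neighbour choices first, then acceptance draws).
    """
    j = _pick_random_neighbors(g, rng)
    u = rng.random(g.N)
    valid = j >= 0
    jj = np.where(valid, j, 0)
    dPi = state.Pi_tot[jj] - state.Pi_tot
    copy = valid & (dPi > 0) & (u < dPi / M)
    state.s = np.where(copy, state.s[jj], state.s).astype(np.int8)
    return state


def update_strategies_fermi(
    state: GameState, g: Graph, beta: float, rng: np.random.Generator
) -> GameState:
    """Fermi rule: copy a random neighbour with logistic probability
    1/(1 + exp(-beta (Pi_j - Pi_i))), synchronous."""
    j = _pick_random_neighbors(g, rng)
    u = rng.random(g.N)
    valid = j >= 0
    jj = np.where(valid, j, 0)
    dPi = state.Pi_tot[jj] - state.Pi_tot
    prob = expit(beta * dPi)
    copy = valid & (u < prob)
    state.s = np.where(copy, state.s[jj], state.s).astype(np.int8)
    return state


def update_strategies_unconditional_imitation(
    state: GameState, g: Graph, rng: np.random.Generator
) -> GameState:
    """Copy the strategy of the highest-earning member of nu_i (self included).

    If the player's own payoff ties the maximum she keeps her strategy;
    otherwise ties among neighbours are broken uniformly at random.
    """
    row_ptr, row, col = g.games()
    pay = state.Pi_tot[col]
    best = np.maximum.reduceat(pay, row_ptr[:-1])
    keep = state.Pi_tot >= best
    # uniformly pick among maximizing neighbours for the rest
    mask = (pay == best[row]) & (col != row)
    cnt = np.add.reduceat(mask.astype(np.int64), row_ptr[:-1])
    u = rng.random(g.N)
    rank = np.floor(u * np.maximum(cnt, 1)).astype(np.int64)
    rank = np.minimum(rank, np.maximum(cnt - 1, 0))
    cs = np.cumsum(mask.astype(np.int64))
    before = np.concatenate([[0], cs])[row_ptr[:-1]]
    target = before + rank + 1
    flat = np.searchsorted(cs, target, side="left")
    chosen = col[np.minimum(flat, col.size - 1)]
    new_s = np.where(keep | (cnt == 0), state.s, state.s[chosen])
    state.s = new_s.astype(np.int8)
    return state


def step(
    state: GameState,
    g: Graph,
    p: GameParams,
    M: float | None = None,
    rng: np.random.Generator | None = None,
) -> GameState:
    """Advance one round in place: payoffs, synchronous strategy update,
    then reallocation of next-round investments from this round's per-game
    payoffs (each player reallocates from her OWN payoffs, even if she has
    just copied a neighbour's strategy)."""
    if rng is None:
        rng = np.random.default_rng()
    if M is None:
        M = normalization_constant(g, p)
    compute_payoffs(state, g, p)
    if p.update_rule == "replicator":
        update_strategies_replicator(state, g, M, rng)
    elif p.update_rule == "fermi":
        update_strategies_fermi(state, g, p.beta, rng)
    else:
        update_strategies_unconditional_imitation(state, g, rng)
    allocate_investments(state, g, p)
    state.t += 1
    return state


def pair_index(g: Graph, i: int, j: int) -> int:
    """Flat index of the ordered pair (investor i, focal j), j in nu_i."""
    row_ptr, _, col = g.games()
    sl = col[row_ptr[i]:row_ptr[i + 1]]
    pos = np.searchsorted(sl, j)
    if pos >= sl.size or sl[pos] != j:
        raise KeyError(f"{j} is not in the closed neighbourhood of {i}")
    return int(row_ptr[i] + pos)
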