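"""Experiment orchestration: single runs, ensembles and parameter sweeps.

A run builds a fresh network realization (unless an explicit edge list is
given), relaxes the dynamics for ``t_relax`` rounds and then accumulates
time averages over a ``t_measure``-round measurement window.  Ensembles
repeat this over independently seeded runs; per-run seeds are derived from
the master seed with :class:`numpy.random.SeedSequence` spawning, so the
same master seed always reproduces the same ensemble bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import game, netgen
from .game import GameParams, GameState
from .netgen import Graph

__all__ = [
    "SimConfig",
    "Snapshot",
    "RunResult",
    "EnsembleResult",
    "build_network",
    "run_single",
    "run_ensemble",
    "sweep",
    "save_snapshot",
    "load_snapshot",
    "write_sweep_tsv",
]


@dataclass(frozen=True)
class SimConfig:
    """Full description of an experiment.

    The network is either an uncorrelated configuration model draw
    (``topology="ucm"``, parameters N, gamma, kmin, kmax with kmax
    defaulting to floor(sqrt(N))), a deterministic fixture
    ("wheel"/"ring"/"complete", sized by N), or an external edge list.
    A new UCM realization is drawn for every run of an ensemble.
    """

    params: GameParams
    N: int = 2000
    gamma: float = 2.5
    kmin: int = 2
    kmax: int | None = None
    topology: str = "ucm"
    edge_list: str | None = None
    t_relax: int = 10_000
    t_measure: int = 1000
    n_runs: int = 10
    master_seed: int = 0
    coop_prob: float = 0.5
    record_fc: bool = True

    def __post_init__(self) -> None:
        if self.t_relax < 0:
            raise ValueError("t_relax must be >= 0")
        if self.t_measure < 1:
            raise ValueError("t_measure must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.topology not in ("ucm", "wheel", "ring", "complete"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 <= self.coop_prob <= 1:
            raise ValueError("coop_prob must lie in [0, 1]")


@dataclass
class Snapshot:
    """Steady-state summary of one run.

    ``I``, ``contrib``, ``Pi_pair`` are time averages over the measurement
    window on the flat pair layout; ``contrib`` is the averaged effective
    contribution I[i,j] * s_i, the quantity that actually enters the game
    pools (it already accounts for strategy flips during the window).
    ``s`` is the final instantaneous strategy vector; ``I_final`` the final
    instantaneous investments for analyses that prefer an unaveraged state.
    """

    s: np.ndarray
    I: np.ndarray
    contrib: np.ndarray
    Pi_pair: np.ndarray
    Pi_tot: np.ndarray
    I_final: np.ndarray
    fc_mean: float


@dataclass
class RunResult:
    graph: Graph
    snapshot: Snapshot
    fc_traj: np.ndarray
    metadata: dict


@dataclass
class EnsembleResult:
    runs: list[RunResult]
    fc_mean: float
    fc_se: float
    config: SimConfig

    @property
    def fc_per_run(self) -> np.ndarray:
        return np.array([r.snapshot.fc_mean for r in self.runs])


def build_network(config: SimConfig, rng: np.random.Generator) -> Graph:
    if config.edge_list is not None:
        return netgen.read_edge_list(config.edge_list)
    if config.topology == "wheel":
        return netgen.make_wheel(config.N - 1)
    if config.topology == "ring":
        return netgen.make_ring(config.N)
    if config.topology == "complete":
        return netgen.make_complete(config.N)
    ds = netgen.sample_powerlaw_degree_sequence(
        config.N, config.gamma, config.kmin, config.kmax, seed=rng)
    return netgen.build_ucm_graph(ds, seed=rng)


def run_single(config: SimConfig, run_seed: int | np.random.SeedSequence) -> RunResult:
    """One relaxation + measurement run.

    The measurement window accumulates time averages of the investments,
    effective contributions, per-pair and total payoffs and the cooperator
    fraction.  A population absorbed in all-defection is left early (its
    state is exactly stationary: zero payoffs and an even investment split
    after one further round); the absorbed values fill the window.  An
    all-cooperator population keeps evolving — strategies are frozen but
    investments still move — so it is simulated to the end.
    """
    ss = (run_seed if isinstance(run_seed, np.random.SeedSequence)
          else np.random.SeedSequence(run_seed))
    net_ss, dyn_ss = ss.spawn(2)
    g = build_network(config, np.random.default_rng(net_ss))
    rng = np.random.default_rng(dyn_ss)
    p = config.params
    M = game.normalization_constant(g, p)
    state = game.initial_state(g, p, seed=rng, coop_prob=config.coop_prob)

    fc = []
    absorbed_at = None
    for t in range(config.t_relax):
        if config.record_fc:
            fc.append(state.s.mean())
        if not state.s.any():
            absorbed_at = t
            break
        game.step(state, g, p, M, rng)

    P = state.I.size
    acc_I = np.zeros(P)
    acc_contrib = np.zeros(P)
    acc_pi = np.zeros(P)
    acc_pit = np.zeros(g.N)
    acc_fc = 0.0
    steps_done = 0
    if absorbed_at is None:
        for t in range(config.t_measure):
            # averages are over the pre-step states of the window
            game.compute_payoffs(state, g, p)
            acc_I += state.I
            acc_contrib += state.I * state.s[g.games()[1]]
            acc_pi += state.Pi_pair
            acc_pit += state.Pi_tot
            acc_fc += state.s.mean()
            if config.record_fc:
                fc.append(state.s.mean())
            steps_done += 1
            if p.update_rule == "replicator":
                game.update_strategies_replicator(state, g, M, rng)
            elif p.update_rule == "fermi":
                game.update_strategies_fermi(state, g, p.beta, rng)
            else:
                game.update_strategies_unconditional_imitation(state, g, rng)
            game.allocate_investments(state, g, p)
            state.t += 1
    if steps_done == 0:
        # absorbed in all-D during relaxation: one more allocation from the
        # all-zero payoffs brings I to the even split, after which the state
        # is exactly stationary and stands in for the whole window
        game.compute_payoffs(state, g, p)
        game.allocate_investments(state, g, p)
        game.compute_payoffs(state, g, p)
        acc_I = state.I.copy()
        acc_contrib = state.I * state.s[g.games()[1]]
        acc_pi = state.Pi_pair.copy()
        acc_pit = state.Pi_tot.copy()
        acc_fc = state.s.mean()
        steps_done = 1
    snap = Snapshot(
        s=state.s.copy(),
        I=acc_I / steps_done,
        contrib=acc_contrib / steps_done,
        Pi_pair=acc_pi / steps_done,
        Pi_tot=acc_pit / steps_done,
        I_final=state.I.copy(),
        fc_mean=float(acc_fc / steps_done),
    )
    meta = {
        "seed_entropy": ss.entropy,
        "M": M,
        "absorbed_at": absorbed_at,
        "N": g.N,
        "E": g.n_edges,
        "params": dataclasses.asdict(p),
    }
    return RunResult(graph=g, snapshot=snap,
                     fc_traj=np.asarray(fc), metadata=meta)


def run_ensemble(config: SimConfig) -> EnsembleResult:
    """``n_runs`` independent runs with per-run seeds spawned from the
    master seed; returns per-run results plus the ensemble mean and
    standard error of the steady-state cooperator fraction."""
    master = np.random.SeedSequence(config.master_seed)
    children = master.spawn(config.n_runs)
    runs = [run_single(config, child) for child in children]
    fc = np.array([r.snapshot.fc_mean for r in runs])
    se = float(fc.std(ddof=1) / np.sqrt(len(fc))) if len(fc) > 1 else 0.0
    return EnsembleResult(runs=runs, fc_mean=float(fc.mean()), fc_se=se,
                          config=config)


def sweep(config: SimConfig, parameter: str, values) -> pd.DataFrame:
    """One ensemble per parameter value (parameter in {"r", "alpha"});
    returns a table sorted by value with columns value, f_c_mean, f_c_se,
    n_runs."""
    if parameter not in ("r", "alpha"):
        raise ValueError(f"sweep parameter must be 'r' or 'alpha', got {parameter!r}")
    values = list(values)
    if not values:
        raise ValueError("empty value list")
    rows = []
    for v in sorted(values):
        p = dataclasses.replace(config.params, **{parameter: float(v)})
        cfg = dataclasses.replace(config, params=p)
        res = run_ensemble(cfg)
        rows.append({"value": float(v), "f_c_mean": res.fc_mean,
                     "f_c_se": res.fc_se, "n_runs": cfg.n_runs})
    return pd.DataFrame(rows)


def write_sweep_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -- snapshot persistence (plain text) -------------------------------------

def save_snapshot(result: RunResult, out_dir: str | Path) -> None:
    """Write a run's graph and steady-state snapshot as TSV + edge list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = result.graph
    netgen.write_edge_list(g, out / "graph.edges")
    snap = result.snapshot
    nodes = pd.DataFrame({
        "node": np.arange(g.N),
        "degree": g.degrees,
        "strategy": snap.s,
        "Pi_tot": snap.Pi_tot,
    })
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False, float_format="%.12g")
    _, row, col = g.games()
    pairs = pd.DataFrame({
        "i": row, "j": col,
        "I": snap.I, "contrib": snap.contrib, "Pi_pair": snap.Pi_pair,
        "I_final": snap.I_final,
    })
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.12g")
    meta = dict(result.metadata)
    meta["fc_mean"] = snap.fc_mean
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_snapshot(in_dir: str | Path) -> tuple[Graph, Snapshot, dict]:
    in_dir = Path(in_dir)
    for name in ("graph.edges", "nodes.tsv", "pairs.tsv", "meta.json"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"snapshot is missing {name} in {in_dir}")
    g = netgen.read_edge_list(in_dir / "graph.edges")
    nodes = pd.read_csv(in_dir / "nodes.tsv", sep="\t")
    pairs = pd.read_csv(in_dir / "pairs.tsv", sep="\t")
    _, row, col = g.games()
    if len(pairs) != row.size or not (np.array_equal(pairs["i"].to_numpy(), row)
                                      and np.array_equal(pairs["j"].to_numpy(), col)):
        raise ValueError("pairs.tsv does not match the graph's participation layout")
    with open(in_dir / "meta.json") as fh:
        meta = json.load(fh)
    snap = Snapshot(
        s=nodes["strategy"].to_numpy().astype(np.int8),
        I=pairs["I"].to_numpy(float),
        contrib=pairs["contrib"].to_numpy(float),
        Pi_pair=pairs["Pi_pair"].to_numpy(float),
        Pi_tot=nodes["Pi_tot"].to_numpy(float),
        I_final=pairs["I_final"].to_numpy(float),
        fc_mean=float(meta.get("fc_mean", nodes["strategy"].mean())),
    )
    return g, snap, meta
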