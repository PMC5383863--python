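# pggalloc

Simulation and analysis of **public goods games (PGGs) on networks with
payoff-driven resource allocation**.

In the classical networked PGG, every node i plays one game per member of
its closed neighbourhood ν_i (itself plus its k_i neighbours) and, if it
cooperates, splits its per-round capital *c* evenly over those k_i + 1
games. `pggalloc` implements the adaptive variant in which players instead
redistribute their capital each round toward the games that paid them best:

    I_ij(t+1) = cap_i · exp(α Π_ij(t)) / Σ_{l∈ν_i} exp(α Π_il(t))

where cap_i = c under the fixed-cost-per-player (FCP) scheme or (k_i+1)c
under fixed-cost-per-game (FCG), and α ≥ 0 modulates how aggressively
investments chase past profits (α = 0 recovers the classical even split).
Payoffs follow the standard N-person Prisoner's Dilemma form with synergy
factor r,

    Π_ij(t) = r/(k_j+1) · Σ_{l∈ν_j} I_lj(t) s_l(t) − I_ij(t) s_i(t),

with s = 1 for cooperators and 0 for defectors, and strategies evolve
synchronously under a finite-population replicator-like rule (alternatives:
unconditional imitation, Fermi rule). Substrates are uncorrelated
scale-free networks (configuration model with P(k) ~ k^−γ, structural
cutoff k_max = √N) or any user-supplied edge list.

The analysis suite measures the emergent observables this reallocation
produces:

- cooperation level f_c versus r and α;
- the bimodal distribution of investment shares I_ij/cap_i (one dominant
  game per player, crumbs elsewhere);
- degree-resolved normalized game production w_j = (r−1)·pool_j/(k_j+1),
  bounded by c(r−1);
- wealth concentration via q80 — the fraction of games, ranked by
  production, needed to accumulate 80% of the total (a Pareto "80/20"
  economy has q80 ≈ 0.2);
- the positive/negative link decomposition: a participant whose
  contribution to a game falls below the game's mean contribution lowers
  the other players' payoffs relative to her absence — her link is
  *negative* even though she is formally a cooperator. The positive links
  form a sparse, near-tree backbone covering most of the network.

Intended users: researchers in evolutionary game theory and complex
networks who want a fast, reproducible, scriptable implementation of this
model family.

## Worked example

```bash
cat > demo.json <<'EOF'
{"N": 1000, "gamma": 2.5, "kmin": 2, "kmax": 31,
 "r": 4.0, "alpha": 2.0, "seed": 7, "n_runs": 5,
 "t_relax": 5000, "t_measure": 500}
EOF
pggalloc simulate --config demo.json --out-dir demo_out
pggalloc analyze demo_out
```

prints

```
simulate: N=1000 r=4.0 alpha=2.0 runs=5 (5000+500 steps)
f_c = 0.9592 +- 0.0039 -> demo_out/summary.tsv
  f_c   q80  mean_w  positive_coverage  positive_edges  positive_edge_ratio  positive_components  negative_edges
0.964 0.213 0.70622              0.987            1087             1.088088                   66            1662
```

Reading: with aggressive reallocation (α = 2) at r = 4, 96% of players
cooperate; only 21% of the games produce 80% of the total wealth (the
Pareto law emerging from the dynamics — at α = 0 the same quantity is
about 70%); and the positive-link layer touches 98.7% of the nodes with
barely more edges than a spanning tree (edge ratio 1.09 versus 1.0 for a
tree), while the negative layer keeps the bulk of the edges. The `analyze`
command also writes the share histogram, the production-by-degree table,
the per-link sign table and both sign-layer edge lists next to the stored
snapshot.

The same machinery is available as a library:

```python
from pggalloc import SimConfig, GameParams, simulate, analysis

cfg = SimConfig(params=GameParams(r=4.0, alpha=2.0), N=2000, n_runs=10,
                t_relax=10_000, t_measure=1000, master_seed=1)
res = simulate.run_ensemble(cfg)
run = res.runs[0]
_, w = analysis.game_productions(run.snapshot, run.graph, cfg.params)
print(res.fc_mean, analysis.pareto_q(w, 0.8))
```

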