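# Methods

## Model

Each node i of an undirected simple graph is a player participating in the
k_i + 1 public goods games centred on the members of its closed
neighbourhood ν_i = {i} ∪ N(i). A round proceeds in three synchronous
stages:

1. **Payoffs.** Game j pools the contributions of its k_j + 1
   participants, multiplies them by the synergy factor r and shares the
   result equally: Π_ij = r/(k_j+1) · Σ_{l∈ν_j} I_lj s_l − I_ij s_i, with
   s_l ∈ {0, 1} the defect/cooperate strategy. Player totals are
   Π_i = Σ_{j∈ν_i} Π_ij. Because each game returns r·pool and collects
   pool, the bookkeeping identity Σ_i Π_i = (r−1) × (total capital
   invested by cooperators) holds exactly each round; it is asserted in
   the test suite to 1e−6·N.

2. **Strategy update** (synchronous, from the pre-update payoff totals):
   - *replicator-like* (default): player i picks one neighbour j uniformly
     at random; if Π_j > Π_i she copies s_j with probability
     (Π_j − Π_i)/M, otherwise keeps her strategy. M is an upper bound on
     the payoff difference (below).
   - *unconditional imitation*: copy the strategy of the highest-earning
     member of ν_i; own payoff at the maximum means keep, ties among
     neighbours are broken uniformly.
   - *Fermi*: copy a random neighbour with probability
     1/(1 + exp(−β(Π_j − Π_i))); β defaults to 1.0 and is configurable.

3. **Reallocation.** Every player redistributes next round's capital over
   her games by a softmax of this round's per-game payoffs,
   I_ij(t+1) = cap_i · e^{αΠ_ij} / Σ_{l∈ν_i} e^{αΠ_il}, where cap_i = c
   (FCP) or (k_i+1)c (FCG). The row is shifted by its maximum before
   exponentiation, which makes the computation overflow-free and exactly
   invariant under adding a constant to a player's payoffs (a tested
   property). Defectors' rows are updated too — a defector's (received)
   payoffs keep steering her notional allocation, so a defector who turns
   cooperator immediately invests according to her latest payoff profile.
   At t = 0 all payoffs are zero and the split is even. Strategy imitation
   copies only the strategy bit, never the neighbour's allocation profile.

Capital does not accumulate across rounds; each round starts from cap_i.
All-cooperator and all-defector populations are absorbing for strategies
under all three rules (no dissimilar neighbour to copy).

### The normalization constant M

The replicator-like rule needs M ≥ max |Π_j − Π_i|. We use the loose
analytic bound M = r·c·(k_max+1) + c under FCP (a defector of maximal
degree whose every co-player pours full capital into each shared game,
minus the worst case of a cooperator who recoups nothing); under FCG, c is
replaced by (k_max+1)c in the first term and the loss bound is (k_max+1)c.
Any valid bound keeps the imitation probability in [0, 1]; a looser one
only rescales all imitation rates by a common factor, which stretches
relaxation time but not the stationary state. The value used is recorded
in every run's metadata.

## Networks

The default substrate is the uncorrelated configuration model: degrees are
i.i.d. from the normalized truncated power law P(k) ∝ k^−γ on
{kmin..kmax}, with defaults γ = 2.5, kmin = 2 (every game has at least
3 players) and the structural cutoff kmax = ⌊√N⌋, which keeps the expected
degree-degree correlations of the matching negligible. For these defaults
the exact truncated-law mean degree is ≈ 4.15 at N = 10⁴ (⟨k⟩ ≃ 4). If
the sampled degree total is odd, one uniformly chosen node's degree is
resampled from the same law until the total is even — resampling rather
than incrementing keeps the marginal distribution intact.

Stub matching is rejection-sampled: a matching containing a self-loop or
multi-edge is discarded wholesale and redrawn (up to `max_retries`,
default 100); if retries are exhausted the last matching is repaired by
degree-preserving double-edge swaps applied only to the offending edges.
In practice the γ = 2.5, kmax = √N sequences almost always accept within a
few draws; the repair path exists to guarantee termination. Realized
degree sequences always equal the sampled ones exactly.

Deterministic substrates (ring, wheel = ring plus hub, complete graph) are
first-class: they admit closed-form payoffs (k-regular all-cooperator even
split gives Π_i = c(r−1) exactly) and the wheel exhibits the canonical
negative-link situation (below).

## Numerical protocol

A run draws a fresh network realization, assigns strategies i.i.d.
Bernoulli(0.5), relaxes for `t_relax` rounds and then accumulates time
averages over a `t_measure`-round window: investments, effective
contributions I·s, per-pair and total payoffs, and f_c. A population
absorbed in all-defection is left early — after one further reallocation
from the all-zero payoffs its state is exactly stationary (zero payoffs,
even split) and stands in for the whole window. An all-cooperator
population is *not* left early: strategies are frozen but the investment
field keeps evolving, and the steady-state investment pattern is what the
wealth observables measure.

Ensembles run `n_runs` independent runs whose seeds are spawned from the
master seed via `numpy.random.SeedSequence` (each run further splits into
a network stream and a dynamics stream); identical master seeds give
bit-identical ensembles, including the TSV output bytes.

Default desk-scale conditions — used by the end-to-end tests — are
N = 2000, γ = 2.5, kmin = 2, kmax = 44 = ⌊√2000⌋, t_relax = 10⁴,
t_measure = 10³, n_runs = 10. The qualitative observables are
size-robust, and at this scale a full ensemble takes well under a minute
on one core; the full protocol (N = 10⁴, t_relax = 5×10⁴, ≥500 runs) is
reachable through the same configuration fields.

## Observables

- **Investment shares** I_ij/cap_i, by default over cooperators' rows only
  (defectors' rows are notional while they defect); histogrammed on 100
  uniform bins of [0, 1]. For α ≳ 2 at r = 4 the distribution is bimodal:
  a peak above 0.95 (each player's one dominant game) and a large peak
  below 0.05 (the crumbs spread over her remaining games).
- **Game production** W_j = (r−1)·pool_j and its normalization
  w_j = W_j/(k_j+1) ≤ c(r−1), with equality iff every participant is a
  cooperator committing her full capital to game j (FCP). Σ_j W_j equals
  Σ_i Π_i identically.
- **Pareto fraction** q_q: games are ranked by production (ties broken by
  node index) and q80 is the smallest fraction m/N whose cumulative
  production reaches 80% of the total. The threshold comparison tolerates
  a 1e−12 relative slack so that exact hits (uniform productions) land on
  ⌈0.8N⌉/N rather than one past it. All-zero production vectors are
  rejected rather than defaulted.
- **Link signs.** Participant i's directed link into game j (i ≠ j; the
  self-participation is never classified, since the criterion concerns
  i's effect on the *other* players) is negative iff
  r/(k_j+1)·Σ_{l∈ν_j} I_lj s_l < r/k_j·Σ_{l∈ν_j∖i} I_lj s_l, i.e. iff i's
  effective contribution is below the game's mean contribution; equality
  counts as positive (the link's absence is not strictly beneficial).
  Signs are computed from the measurement-window time-averaged effective
  contributions (averaging I·s jointly, so strategy flips inside the
  window are handled consistently); a single-instant variant is available
  by passing a live `GameState`, and every snapshot retains the final
  instantaneous investments so alternatives are recomputable.
- **Sign layers.** An undirected edge joins the positive layer if either
  of its two directed participations is positive, the negative layer if
  either is negative (an edge can carry both). Backbone structure is
  summarized by node coverage, edge count relative to N−1, connected
  components (isolated nodes count) and mean degree, rather than a full
  minimum-spanning-tree comparison.

The wheel (ring of n leaves plus hub) is the analytic anchor for link
signs: under an even split the hub invests c/(n+1) in each leaf game where
ring members invest c/4, so the inequality reduces to 3/(n+1) < 3/4 — the
hub→leaf links are negative for every r and c whenever n > 3 (r cancels;
the package's tests assert the n ≥ 5 regime).

## What the generated data do and do not show

The generator reproduces the study conditions themselves (the model *is*
the data-generating process; there is no external data). Passing tests
therefore demonstrate the internal consistency of the dynamics and the
robustness of the emergent observables at N = 2000, not statements about
empirical economic networks: real systems have degree correlations,
clustering, weighted and time-varying ties, and agents far richer than a
one-bit strategy with softmax reallocation. The scaled-down ensembles also
carry finite-size effects — e.g. at N = 300 the cooperation level at
r = 6 plateaus near 0.9 rather than saturating at 1, because a small
population keeps a fluctuating defector minority alive.

## Numerical choices

- Double precision throughout; allocation rows sum to cap_i within 1e−9,
  payoff conservation within 1e−6·N, analytic identities asserted at
  1e−9 or tighter.
- Random draws are consumed in fixed node order within each round
  (neighbour choices, then acceptance draws), so trajectories are
  bit-reproducible given seeds.
- Unconditional-imitation ties among maximizing neighbours are resolved by
  a uniform draw implemented with a cumulative-count search (O(P) per
  round, deterministic given the stream).
- TSVs are written with '.' decimals and %.10g–%.12g floats; manifests are
  written atomically (temp file + rename).

## Known limitations

- The stationarity criterion is a fixed step count, not a convergence
  test; strongly bistable regions near the cooperation transition may need
  longer relaxation than the defaults.
- The exact normalization M of the replicator-like rule is a loose bound;
  absolute time scales of imitation are therefore only defined up to the
  corresponding rescaling.
- The edge-list reader infers N as (max node id + 1), so trailing isolated
  nodes do not survive a write/read round trip (irrelevant for kmin ≥ 2
  networks).
- The FCG scheme and the unconditional-imitation/Fermi rules are
  implemented and unit-tested, but the ensemble-level observables are
  routinely exercised only under FCP + replicator.
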