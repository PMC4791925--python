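# Methods

## Models

### Public health game

A population of N individuals occupies the nodes of an undirected contact
network. Each individual carries a behavior (protect / defect) and an
infection counter `remaining ∈ {0, …, D}`; the individual is *infected*
while the counter is positive and *healthy and susceptible* at zero (SIS —
no immunity is ever acquired).

One round consists of four synchronous phases, in this fixed order:

1. **Transmission.** Every currently infected individual — including
   infected protectors, since the shield blocks incoming but not outgoing
   transmission — independently infects each healthy, defecting neighbor
   with probability β per contact, so a defector with k infected neighbors
   escapes with (1−β)^k. Protectors are never newly infected. Newly
   infected individuals receive a full counter D and transmit only from the
   next round on.
2. **Recovery.** Everyone infected before this round decrements their
   counter by one; at zero they are healthy and fully susceptible again.
3. **Payoffs.** `payoff_i = b · h(i) − c · deg(i) · 1[i protects]`, where
   h(i) counts healthy members of i's closed neighborhood. Being infected
   does not gate *receipt* of benefit — an infected individual still earns
   b per healthy local contact; it merely never counts itself.
4. **Imitation.** Each individual switches to the opposite behavior iff
   some closed-neighborhood holder of the *other* behavior strictly
   out-earns every closed-neighborhood holder of its *own* behavior (self
   included). Ties favor the incumbent behavior. Behavior change never
   alters infection state.

Computing payoffs after recovery means decisions reflect the newest health
information. The alternative — imitating on the previous round's payoffs —
was examined and destroys protection entirely at any benefit level that
should sustain it, so the information-current ordering is the one that
produces the documented threshold behavior. The incumbent-tie rule is
likewise load-bearing: breaking cross-behavior payoff ties at random
collapses protection at benefit-to-cost ratio 4 on the lattice, where it
must survive.

Initial conditions: exactly `round(N/2)` protectors (round-half-up) and
exactly `round(N/10)` infected individuals, both placed uniformly at random
and independently of each other, the infected starting with a full counter.
Exact counts rather than per-node coin flips keep initial conditions
comparable across seeds.

Defaults: c = 1 (so b doubles as the benefit-to-cost ratio), β = 1,
D = 5 steps, 500 rounds, run-level means taken over all recorded steps
(including the initial state; a burn-in knob exists and defaults to 0).

### Three-strain cyclic dominance game

Each node holds one of three strains: producer beats grower, resister
beats producer, grower beats resister. Per round, every cell scores one
point per beaten neighbor — except producer-vs-grower encounters, which
succeed independently with probability `attack_rate` (a fresh Bernoulli
draw per directed encounter per round) — and pays a flat per-round cost for
its strain. Everyone then synchronously adopts the strain of the
highest-scoring member of its closed neighborhood; if the maximum is
attained by the node's own strain it keeps it, and when two *other* strains
tie strictly above all own-strain locals the node picks one uniformly at
random.

Costs are flat per round rather than per neighbor. Two observations fix
this choice: (i) equal flat costs shift every payoff identically, so the
dynamics with all costs equal reproduce the zero-cost dynamics exactly
(verified trajectory-for-trajectory in the tests), which is required for
the equal-cost baseline to sit at one third per strain; (ii) per-neighbor
costs make a 50% producer-cost reduction an 4-point payoff advantage that
drives the grower extinct and hands the producer the whole lattice,
destroying the three-way coexistence the cost experiments depend on. With
flat unit costs, any producer reduction strictly between 0 and 100% changes
exactly the same set of payoff comparisons (a fractional advantage only
breaks integer ties), so all intermediate reductions produce identical
dynamics — the full (100%) reduction is the only stronger treatment.

Initialization: strains in counts as equal as possible (difference ≤ 1),
randomly permuted across nodes. Defaults: attack rate 1, costs 0, 500
rounds.

## Networks

- **Grid lattice**: side×side Moore-neighborhood torus; every node has
  exactly 8 neighbors, |E| = 4N, mean local clustering exactly 3/7. The
  boundary wraps because the model assumes every individual has eight
  neighbors without exception; side ≥ 3 is required (below that the
  wrap-around offsets collide).
- **Random network**: uniform G(n, m) with m = round(n·k̄/2), so the edge
  count — and hence mean degree — matches the lattice exactly. Degrees are
  not individually constrained; isolated nodes occur with probability
  ≈ e^-8 per node and are retained (they never change behavior, having no
  locals to imitate).
- **Rewired lattice**: degree-preserving double-edge swaps (pick edges a–b,
  c–d on four distinct nodes, replace with a–d, c–b when the result stays
  simple), applied until exactly x original lattice edges are absent. Every
  node keeps all eight neighbors. Swaps that would overshoot the lattice-
  edge budget are rejected; when exactly one rewiring is still owed the
  partner edge is drawn from the non-lattice edges, since a swap of two
  lattice edges removes two at once. Feasibility search is bounded (100
  candidate swaps per step) and failure raises with the owed shortfall —
  x = 1 from a pristine lattice is genuinely infeasible for this method. A
  literal `delete_and_replace` method (remove a surviving lattice edge,
  insert a uniform random new edge; preserves only the mean degree) is
  provided for sensitivity analysis.
- `fraction_rewired` = rewired lattice edges / total edges (4N).

## Experiments

Every sweep runs one fresh, independently initialized simulation per
(parameter value, replicate). Per-run seeds derive from
`SeedSequence([master, crc32(sweep name), value index, replicate])`,
giving reproducible yet independent streams; the recorded 31-bit seed in
each table row regenerates that run exactly.

- **Threshold detection**: smallest parameter value at which the outcome
  holds in a strict majority of replicates, with flags for non-monotone
  majority patterns and for degenerate sweeps where every level qualifies.
- **Bimodality**: run-level means are sorted and split at the largest
  adjacent gap if it exceeds 0.2 (the two regimes of interest sit near 0.8
  and below 0.5, so any qualifying gap separates them); otherwise a single
  mode is reported.
- Replicate defaults follow the experiment being reproduced: 5 for
  threshold sweeps, 3 for the infectivity curve's levels, 10 for run-mean
  averages, 20 for the bimodality sample.

## What the defaults emulate, and known limitations

The default scale (61×61 = 3721 individuals, 500 rounds) and the default
initial conditions are the study conditions of the phenomena this package
targets; the vectorized engine runs one such game in well under a second,
so all experiments run at that full scale, including in the test suite.

The models are deliberately stylized: no immunity (SIR/SIRS), no
heterogeneous per-agent parameters, no mortality, no empty sites or
nutrient dynamics, no mutation. Synchronous updating is a modeling choice;
serial (agent-at-a-time) updating was explored and degrades the lattice
survival threshold, so it is not offered. Conclusions about real
populations should rest on the qualitative phenomena — threshold behavior,
oscillating coexistence, bimodal collapse, hydra effects — not on the
specific numeric values, which are sensitive to the update-rule details
documented above.

Quantitative behaviors the implementation is known to exhibit, for
calibration of expectations:

- Grid survival threshold at b/c = 4; below it infection takes over at a
  mean of ~0.83.
- At b = 5, β = 1 the surviving-branch mean infection is ~0.10–0.16; runs
  at b = 4 oscillate around ~0.25–0.29.
- The infectivity response at b = 5 is hill-shaped with its peak near 20%
  infectivity and a bimodal regime (collapse mode near 0.80–0.83) from
  about 25% infectivity upward, the collapse probability shrinking as
  infectivity grows.
- On G(n, m) random networks small protector pockets persist at every
  b ≥ 3, so the binary "any protector at the final step" survival flag is
  degenerate there; protection takes over outright between b = 5.5 and 6.
- The three-strain game coexists at one third per strain on the lattice;
  degree-preserving rewiring tips it to single-strain dominance (majority
  of replicates) at roughly 9% of edges rewired, with first single-run
  tips from ~4.5%.
- Producers are the most abundant strain for attack rates in [0.15, 0.20];
  at still lower rates the grower sweeps the lattice instead.
- Producer cost reductions (flat costs, others at 1): intermediate
  reductions move resisters to ~0.34; the full reduction moves resisters
  to ~0.44 and growers to ~0.23.
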