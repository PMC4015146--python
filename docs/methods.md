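# Methods

## Model

`netprio` ranks entities of a target network by the strength of their
association with a query set living in another network of a heterogeneous
global graph G = (D, R).  D is a set of weighted undirected intra-domain
networks with pairwise-disjoint node vocabularies; R is a set of bipartite
relation networks, at most one per pair of domains.  A meta-graph with one
vertex per domain and one edge per relation defines the *paths* along which
evidence flows.

Three propagation primitives compose the pipeline:

1. **Within-network flow propagation.**  With M the degree-normalized
   adjacency (each entry divided by the square root of the product of its
   row and column sums) and x₀ a prior normalized to unit sum over its
   support, the diffused state is the minimizer of a smoothness term
   Σ M_jk (x_j − x_k)² balanced against prior fidelity with weight
   (1−α)/α, i.e. x̂ = (1−α)(I − αM)⁻¹x₀.  The iterative form
   x ← αMx + (1−α)x₀ converges geometrically because the symmetric
   normalization keeps the spectral radius of M at or below 1.
2. **Between-network transfer.**  Each node of the next network receives
   the *unweighted arithmetic mean* of its cross-network neighbors' values
   (nodes without cross-neighbors receive 0).  Relation weights do not
   enter this step; they act only through the normalized adjacency used in
   the final projection.  This is deliberate fidelity to the transfer rule
   as defined; see Open choices below.
3. **Survival thresholding.**  After a transfer, the ⌈|V|(1−γ)⌉ lowest
   values are zeroed (ties broken toward lower canonical node index), so
   only a fraction γ of nodes — the strongest — carry evidence onward.

A full run diffuses the query indicator within the query network once,
pushes the result along every simple meta-graph path toward the target
network with the sequence *transfer → threshold → renormalize prior →
diffuse* at each intermediate network, and projects each path's penultimate
state onto target nodes through the last relation's normalized adjacency.
Candidates e are scored by the Pearson correlation between the concatenated
projections and the candidate's own within-target diffusion (target set
{e}) tiled once per path; ranking is by descending score with index-order
tie-breaks.

Because the target-side diffusion for {e} is column e of
(1−α)(I − αM_t)⁻¹, the per-candidate loop reuses one dense factorization;
this is algebraically identical to diffusing each candidate separately and
is covered by a dedicated equivalence test against a scalar reference
implementation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.9 | weight of network smoothing vs. the prior; must be < 1 for the closed form |
| κ | 1e-5 | stopping tolerance of the iterative solver (max-norm of successive residuals) |
| γ | 0.00375 | surviving fraction after a between-network transfer |
| max_iters | 1000 | safety cap; exceeding it is an error, never a silent return |

The defaults are tuned for graphs with thousands of nodes per network,
where γ = 0.00375 keeps a few dozen carriers alive.  On small graphs
(tens of nodes) that γ zeroes *every* node — ⌈|V|(1−γ)⌉ = |V| once
|V| < 1/γ ≈ 267 — so benchmarks on synthetic toy fixtures use γ = 0.1
(a handful of survivors at |V| ≈ 40), which plays the same role at the
smaller scale.  A state thresholded to all zeros skips the within-network
diffusion and carries zeros forward: a legitimately signal-free path
contributes a zero projection rather than an error.

Numerical conventions: the residual norm for the stopping rule is the
max-norm (strictest common choice; the iterative/closed-form agreement is
pinned by tests regardless); Pearson correlation with a zero-variance side
is defined as 0, so uncorrelatable candidates rank below any positively
correlated one and NaN never reaches a ranking; tiny negative values from
floating-point roundoff in the solvers are clamped to 0; isolated rows or
columns get normalization factor 0 (no flow in or out) instead of a
division by zero; self-loops are accepted as ordinary weights.

## Leave-one-out benchmark

For each known (query entity, true target) arc, the arc is removed from the
relation in both orientations, the relation's normalized matrix and
adjacency sets recomputed (stale normalization would leak the removed arc),
the full prioritization run with the single query entity, and the rank of
the true target recorded; the original relation object is restored before
the next trial.  With one positive among n−1 negatives per trial, the AUC
is the mean Mann–Whitney score (n − rank)/(n − 1); the pooled ROC points
average, over trials, the per-trial step curves on the cutoff grid
r = 0..n.  The trapezoid under those points equals the Mann–Whitney mean,
which the tests verify.  Scoring pairs that are absent from the graph by
construction (newly curated associations, shuffled controls) uses the same
machinery with removal disabled.  The normalized mean rank is
mean(rank)/n with its standard deviation (population form, so a single
trial is well-defined).

## Synthetic fixtures

The generator emulates the *shape* of integrated prioritization inputs —
a few similarity networks coupled by sparse bipartite relations, weights in
(0, 1] — with planted ground-truth associations whose recovery can be
measured.  Design, in its default three-domain form (query domain d0,
intermediate d1, target d2; meta-graph chain d0–d1–d2 closed by the direct
d0–d2 relation, so exactly two evidence paths exist and removing a direct
arc leaves an indirect route):

* Background intra-domain graphs are Erdős–Rényi with U(0,1] weights and
  density 0.05 (average degree 2–3 at the default 40–60 node sizes).  The
  sparsity is deliberate: α = 0.9 diffusion on a small dense graph mixes to
  near-uniformity within a few steps, which no real similarity network at
  this method's operating scale exhibits.
* Each planted pair gets a *satellite clique* (the query entity strongly
  tied to two reserved neighbors) and, per path and intermediate domain,
  two reserved *relays* that hear every clique member; clique members and
  relays are wired to the planted target through the respective relations.
  Satellites and relays are dedicated carriers: their background arcs are
  withheld so the unweighted neighbor-mean is not diluted and routes of
  different pairs stay separate.  Removing the direct query–target arc
  (the leave-one-out trial) leaves the satellite and relay routes intact.
* Every non-planted target receives three strong arcs per neighboring
  domain from random non-carrier sources ("decoys").  Real association
  networks annotate every candidate; without decoys the planted targets
  would be the only hubs of strong arcs and any query would rank them
  high for structural reasons alone — the shuffled-label control exposes
  exactly this failure mode.
* Planted arc weights are U(0.5, 1] scaled by `signal_strength` and capped
  at 1; `noise` adds unrestricted spurious relation arcs that may hit
  carriers and planted entities.

What the fixtures do **not** emulate: scale-free degree distributions, the
correlated similarity structure of curated phenotype networks, weighted
annotation confidence, or realistic network sizes.  Passing benchmarks on
these fixtures therefore shows that the machinery recovers planted signal
and is calibrated against a matched null — not that any particular
performance level transfers to curated data.

## Benchmark study conditions

The planted-association benchmark runs 10 independent graphs × 10 planted
pairs (100 leave-one-out trials, 50 candidates each) at α = 0.9, κ = 1e-5,
γ = 0.1, signal_strength = 4, noise = 0, and the same 100 trials with
target labels shuffled within each graph (fixed points permitted) scored
without arc removal.  The sizes keep a full run of the benchmark and the
property suite in the tens of seconds on one CPU.  Other recomputed
quantities: solver agreement and residual contraction on 100 random
symmetric networks of 5–100 nodes; path enumeration against networkx's
exhaustive `all_simple_paths` on 200 random meta-graphs of up to 6 domains;
the two-network base case against an independently coded dense
implementation on 50 random graphs of 6–20 nodes per side.

## Open choices

* The between-network transfer uses the unweighted mean over adjacency
  sets even though relation arcs carry weights; weights enter only through
  the final projection.  A weighted mean is a plausible variant but is not
  what the transfer rule specifies.
* Prior renormalization is re-applied at every intermediate network: the
  prior set is defined as the nodes with nonzero value, which after
  thresholding is the survivor set.
* Ranking continues into the target network only through correlation;
  propagating straight into the target network is a known alternative that
  this package intentionally does not implement.
* Query entities that are also relation endpoints into the target network
  are not masked outside of leave-one-out trials; only the validated arc is
  ever removed.

## Limitations

* Per-candidate scoring builds one dense (I − αM_t)⁻¹, so target networks
  beyond ~10⁴ nodes need an iterative per-candidate path (cubic memory and
  time in |V_t| otherwise).
* Directed networks and multiple parallel relations per domain pair are
  unsupported.
* The normalization is recomputed from scratch on arc removal; incremental
  updates would be needed for very large leave-one-out campaigns.
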