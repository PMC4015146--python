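# netprio

Generic prioritization of biological entities by label propagation across a
heterogeneous network-of-networks.

## The problem

Guilt-by-association methods rank candidate entities (genes, diseases,
protein domains, drugs, ...) by how strongly they connect to a query set
through networks of known interactions and similarities.  Most network
rankers are hard-wired to one pair of entity types — a gene network coupled
to a disease network, say.  `netprio` works on an arbitrary *global graph*
G = (D, R): any number of intra-domain networks D (one entity type each,
weighted undirected similarity/interaction edges) coupled by bipartite
relation networks R.  Given a query set Q in one network, it ranks every
entity of a chosen target network by its inferred degree of association
with Q.  The intended users are computational biologists who have pairwise
association data in simple edge-list form and want cross-domain candidate
rankings with a leave-one-out benchmark to validate them.

## The method

Every adjacency matrix N (square or bipartite) is degree-normalized,

    norm(N)_jk = N_jk / sqrt(Σ_k N_jk · Σ_j N_jk),

which bounds the spectral radius by 1.  Labels diffuse within a network by
flow propagation: starting from the prior x₀ (the query indicator,
normalized to sum 1), iterate

    x_{i+1} = α M x_i + (1 − α) x₀,

which converges (residual ≤ κ) to the closed form
x̂ = (1 − α)(I − αM)⁻¹ x₀; α ∈ [0,1) weighs network smoothing against the
prior.  Between networks, each node receives the unweighted mean of its
cross-network neighbors' values, after which only the top fraction γ of
nodes keep their value (the lowest ⌈|V|(1−γ)⌉ are zeroed) to stop weak
noise from spreading.

For each simple path of networks from the query network to the target
network, the diffused query state is pushed along the path (never entering
the target network) and the state on the last non-target network is
projected onto target nodes through the final relation's normalized
adjacency Sₐ, giving a vector x̄ᵢ per path.  Each candidate e of the target
network is then scored by

    s_e = corr( concat(x̄₁, ..., x̄_|P|),  concat(x̂_t, ..., x̂_t) ),

the Pearson correlation between the concatenated query-side projections and
the candidate's own diffusion profile x̂_t (target set T = {e}) repeated once
per path.  Candidates are returned sorted by decreasing s_e.

The `benchmark` module implements leave-one-out validation: each known
query–target arc is removed (with renormalization), the true target's rank
recorded, and ranks aggregated into a Mann–Whitney AUC, pooled ROC points,
and a normalized mean rank.  The `synthetic` module generates deterministic
multi-domain graphs with planted associations so the whole pipeline can be
exercised and benchmarked without any external dataset.

## Worked example

`examples/prioritize_minimal.py` builds a toy gene/domain/disease graph and
ranks diseases for the query {BRCA1}:

```
evidence paths: ['gene -> disease', 'gene -> domain -> disease']

rank  disease          score
   1  breast_cancer    +0.9359
   2  li_fraumeni      +0.9036
   3  diabetes         -0.9235
```

Two paths carry evidence (direct, and through protein domains).
`breast_cancer` ranks first: its neighborhood — RAD51 via the direct
relation and the PF00533 domain on the indirect path — is exactly where the
propagated BRCA1 signal concentrates, so its diffusion profile correlates
most with the projected evidence.  `diabetes` anti-correlates: its
neighborhood (INS) receives none of the query signal.

`examples/planted_benchmark.py` runs the leave-one-out benchmark on a
synthetic graph with 10 planted associations (50 disease-side candidates):

```
planted-association benchmark (arc hidden per trial)
AUC: 1.000000
normalized mean rank: 0.020000 (std 0.000000)

label-shuffled null control
AUC: 0.491837
```

Every hidden association is re-ranked first through the surviving indirect
routes (normalized mean rank 1/50 = 0.02), while the shuffled control sits
at chance — the ranking responds to propagated signal, not to graph
structure alone.

## Command line

```sh
netprio simulate --spec fixture.yaml --out data/     # synthetic TSV graph
netprio prioritize --config run.yaml                 # ranking TSV
netprio benchmark --config run.yaml --pairs pairs.tsv
```

Networks are TSV edge lists (`node_a<TAB>node_b<TAB>weight`, undirected,
`#` comments, optional header); the YAML config names the network files,
query/target networks, query set and parameters (defaults α = 0.9,
κ = 1e-5, γ = 0.00375).

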