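# Methods

This note documents the models, statistics and numerical choices behind
`hubtrace`, the assumptions they make, and what the synthetic test-bed
does and does not establish about real protein–protein interaction (PPI)
networks.

## The analysis model

The pipeline treats a disease PPI network as a simple undirected graph
over gene symbols (self-loops and duplicate edges are dropped at parse
time; identifiers are opaque, case-sensitive strings — no gene-symbol
normalisation is attempted). Five stages are chained:

**Topology.** Six degree-dependent measures: degree distribution
p(k) = n_k/N; local clustering c_i = 2m_i/(k_i(k_i−1)) averaged per
degree class (nodes of degree < 2, where the coefficient is undefined,
are reported as 0 but excluded from the profile); neighbourhood
connectivity C_N(k) (mean degree of a node's neighbours, averaged per
degree class); and closeness, eigenvector and betweenness centralities.
Closeness of m is n/Σ_j d_mj over the n other nodes of m's connected
component; betweenness excludes endpoints and, when normalised, divides
by (n−1)(n−2)/2 with n the component size; eigenvector centrality is the
unit-L2 principal adjacency eigenvector of the largest component with
zeros elsewhere. Computing per component matters only for degenerate
inputs — post-knockout residues — and avoids cross-component
infinities. Degree binning uses exact degree classes, which keeps
small-graph tests crisp; no logarithmic binning is applied before
fitting.

**Scaling.** Two fitting routes, matching what each quantity is. The
degree *sample* (per-node degrees ≥ 1) is fitted by discrete maximum
likelihood, p(x) ∝ x^(−α) for x ≥ x_min with Hurwitz-zeta
normalisation; x_min is chosen to minimise the Kolmogorov–Smirnov
distance between the empirical and fitted tails, with candidates capped
at the sample's 80th percentile so the fitted tail keeps support. The
goodness-of-fit p-value is a semi-parametric bootstrap (default 2,500
replicates; tests and the knockout loop use 250 or skip it): each
replicate draws from the fitted model above x_min and resamples the
empirical body below it, is refitted from scratch, and the p-value is
the fraction of replicates whose KS distance reaches the observed one.
Samples from the fitted model are drawn by exact inverse transform on
the zeta-normalised CDF (a cumulative table for the bulk, doubling +
bisection for the deep tail), and the sampler's mean matches direct pmf
summation to < 0.5%. Calibration: on datasets drawn from a true power
law the p-value is approximately uniform with a slight conservative
bias; the measured fraction with p > 0.1 is ~0.93. The five
measure-vs-degree *profiles* are fitted by ordinary least squares of
log(value) on log(k) (KS bootstrapping is defined only for
distributions); zero-valued bins are dropped, the reported `ks_stat` is
the maximum absolute log-space residual, and `stderr` is the slope's
standard error. Sign convention throughout: the reported exponent is
the positive γ of y ~ k^(−γ), so negative exponents mean an increasing
relation.

**Classification.** `hierarchical_scale_free` requires a decaying p(k)
and a clustering exponent ≥ `c_hier_min` = 0.5 — the c(k) ~ k^(−1)-type
signature of nested modules. The 0.5 threshold, rather than a mere
flatness band, is deliberate: finite preferential-attachment networks
with no modular hierarchy still show a mild residual c(k) decay
(measured 0.12–0.24 at n = 5,000, m = 3), while genuinely hierarchical
constructions measure ≈ 1; a 0.05 band would call the former
hierarchical. `scale_free` is a decaying p(k) with c(k) below 0.5.
Assortativity is read from the C_N(k) slope sign with a ±`flat_band`
(0.05) neutrality zone: an increasing profile (exponent < −0.05) is
assortative. Fit-quality thresholds (`gof_max` = 0.33 on the KS
statistic, `p_min` = 0.1 on the bootstrap p) annotate the summary as
warnings rather than forcing `unclassified`: the class is a statement
about exponent signs, and heavy-tailed but imperfect power laws (again,
finite preferential attachment is the canonical example) would
otherwise be unclassifiable despite an unambiguous signature.

**Hierarchy.** Louvain modularity maximisation is applied recursively:
hubs are nodes whose degree in the root network reaches the hub floor
(explicit threshold, or a top-quantile rule); every community containing
a hub is split again on its induced subgraph until it is a triangle
motif G(3,3) — read strictly: 3 nodes *and* 3 edges; a 3-node path is a
terminal leaf but not a motif — or has < 3 nodes/edges, or Louvain
proposes no split, or the level cap is reached. Hub-free communities
are retained but not decomposed (a flag enables full decomposition).
Louvain is greedy and sweep-order dependent, so each partition is the
best of 20 seeded restarts (sub-seeds derived from the user seed; ties
keep the earliest), which empirically reaches the exhaustive-search
modularity optimum within 0.02 on all tested ≤ 8-node graphs and
reduces hierarchy-recovery noise markedly. Resolution is fixed at 1.
Key regulators are the motif-localized hubs whose motifs lie at the
deepest *hub-trace* motif level; triangle-shaped hub-free leaves do not
shift that level. Level numbering is root = 0. P_KR(s) = x[s]/N[s]
uses the gene's intra-community degree and the community's edge count.
Mean modularity per split level is reported with motif leaves excluded
(a triangle's trivial partition has Q = 0 and is never "split").

**MCODE.** Vertex weight = (highest k-core number of the closed
neighbourhood) × (density of that core); nodes under the degree cutoff
weigh 0. Complexes grow breadth-first from the highest-weight unvisited
seed (ties broken lexicographically, making the node-disjoint assignment
deterministic), including neighbours whose weight is within
`node_score_cutoff` of the seed's, to at most `max_depth` BFS layers.
Post-processing discards complexes without a `k_core`-core and, with
`haircut`, iteratively trims members with < 2 intra-complex connections
(a fixpoint, hence idempotent); fluff is off by default. Score =
density × size; the drug-gene filter keeps flagged genes inside
complexes scoring ≥ 10 by default and is monotone in that threshold.

**Knockout.** Motif-localized hubs are grouped by deepest-motif level
and removed cumulatively, one group per step, shallow-to-deep by default
(deep-to-shallow and a levels ≥ 3 variant are available; the grouping
policy is explicit configuration recorded in the trajectory). After
each elimination all six measures are recomputed on the surviving graph
and refitted. Nodes isolated by a removal stay in the graph — network
size stays unambiguous — but never enter fits (k = 0 carries no
information for any of the six measures); fits that lose support are
recorded as absent, never extrapolated.

**Resultant network.** The induced subgraph on motif-localized hubs
plus noise-filtered drug genes, restricted to its largest component.
This is a deliberate, self-contained reading: re-growing the subnetwork
through fresh database queries is out of scope, so the resultant network
here can only contain interactions already present in the input. Hubs
are ranked by normalised betweenness rounded to 3 decimals before the
≥ 0.010 cutoff, then degree, then identifier.

## The synthetic test-bed

`planted_hub_hierarchy` manufactures networks on which every stage has a
known answer. Per planted triangle the construction nests, inward: a
background of 45 Erdős–Rényi communities (p = 0.35, size 12) plus 6
clique "protein complexes" (size 12) that host the drug-associated
genes; `depth − 2` shells of small dense blocks (inner to outer:
12×5 @ 0.70, 20×6 @ 0.60, 22×7 @ 0.55) with weak lateral and
inward-growing radial couplings; a "sanctuary" of 4 dense blocks
(6 @ 0.9) that every hub wires into exactly once; and the hub triangle
itself. Default scale is ~700 nodes (one depth-3 triangle) or ~950
(the `pdn_synthetic` preset, triangles at depths 2, 3 and 4), chosen so
the full suite runs in minutes while hubs still tower over the bulk
degree distribution.

The wiring rules are what make Louvain provably-in-practice recover the
planted structure, and each exists to neutralise one failure mode
observed during design: at most one hub edge per target node (a node
wired to two hubs follows the triangle to the deepest level and spoils
the motif); at most ~1 triangle edge per block anywhere (more, and the
triangle gets absorbed by that block); each hub target reinforced inside
its own block (otherwise it may defect from its block and cling to the
hub); thin hub wiring spread across the whole background (raw degree
without giving any single community a grip); sanctuary blocks with
balanced modularity mass (one dominant dense block would be carved up by
Louvain with the hubs mixed in, several small ones expel the triangle
cleanly at the final split, where the merge penalty d_T·d_B/2m is
largest). The declared hub-degree floor is the midpoint between the
lowest hub and highest non-hub degree; generation fails loudly if the
two overlap. Measured with defaults: key regulators recovered exactly
in ≥ 48/50 seeds; P_KR strictly increasing along every recovered KR
path; emitted networks classify assortative (C_N exponent ≈ −0.25);
two-depth plantings resolve to the deeper triple in ~95% of seeds (the
residue: both triangles isolating at the same observed level).

What passing these tests shows: the pipeline's logic — tracing,
motif calls, KR selection, filtering, elimination bookkeeping, exponent
fitting — is correct on networks whose modular structure is real but
idealised. What it does not show: that Louvain recovers the "true"
hierarchy of a real interactome (no planted truth exists there; shells
here are cleanly separated in coupling strength, which real networks
are not), nor that database-derived networks meet the generators'
independence assumptions (edge noise is Bernoulli here; experimental
interactomes carry correlated, study-driven noise), nor anything about
literature-validated biology. Drug-gene "complexes" are cliques —
MCODE's idealised target; with looser ER blocks (p ≤ 0.8) MCODE's
seed-and-grow covers only 80–95% of a block, so exact-recovery tests
are statements about near-clique complexes specifically.

## Numerical choices and degenerate inputs

- All randomness flows through seeded `numpy` generators or seeded
  networkx calls; graph construction inserts nodes and edges in sorted
  order so runs are byte-identical across processes (Python's hash
  randomisation would otherwise reorder Louvain sweeps).
- MLE optimisation: bounded scalar minimisation of the negative
  log-likelihood on α ∈ [1.01, 8], tolerance 1e-6; KS distances compare
  both sides of each empirical step.
- Eigenvector centrality: power iteration, tolerance 1e-10, explicit
  failure carrying the iteration count on non-convergence.
- OLS fits require ≥ 3 usable bins ("insufficient support" otherwise);
  the knockout trajectory stores absent fits as nulls.
- Empty member sets, victims covering the whole graph, edgeless Louvain
  inputs, motif-free KR calls and annotation lookups of unknown nodes
  all raise or return explicit sentinels — never silent defaults.
- Problem sizes in the test suite (ER oracle graphs ≤ 30 nodes,
  eigen-oracle graphs ≤ 50, 5,000-node preferential attachment, 250-
  replicate bootstraps, ~700–950-node planted networks) were chosen as
  the smallest scales at which each property is comfortably measurable.

## Known limitations

- Louvain with restarts is still a heuristic; on adversarial graphs the
  recovered hierarchy (and hence KR set) can differ from the planted
  one in a few percent of seeds, and the *number* of levels is an
  emergent quantity, not a controlled one.
- The MLE route fits the raw degree sample; the OLS route fits binned
  means. For profiles whose per-degree scatter is strongly skewed the
  binned-mean slope is a biased estimate of the per-node relation (a
  per-node OLS flag exists on `summarize_topology` via the profile
  functions if needed).
- Exact-degree binning leaves single-node bins in the tail; fits on
  small or shattered graphs therefore carry wide `stderr`, which the
  knockout analysis treats as the significance band for exponent
  shifts.
- The resultant network is bounded by the input edge set by
  construction; its size statistics are not comparable to resultant
  networks grown by querying external databases.
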