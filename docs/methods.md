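# Methods

## Model

A multilayer network is a tuple of layers L, per-layer node sets V_k and
intra-layer edge sets E_intra^k, plus one set E_inter of undirected edges
whose endpoints lie in two different layers. Nodes are namespaced per
layer: the id `n03` in layer `L1` and in layer `L2` are distinct nodes, and
no replica relationship across layers is assumed (the gene/disease setting
has disjoint per-layer vocabularies; a multiplex with shared actors simply
reuses ids). Input graphs are undirected and unweighted; a weight column in
an input file is parsed and discarded with a warning. Layers of the two
input networks correspond by identifier string equality — the least
surprising rule given that the method aligns "corresponding layers" without
further qualification; layers present in only one input are skipped with a
warning.

## Alignment-graph construction

Pair nodes are selected by greedy maximum-similarity one-to-one matching of
the seed entries within each layer: entries sorted by similarity
descending, ties broken by (id1, id2) ascending, accepted iff neither
endpoint is already matched. Greedy selection is the direct reading of
"each node is matched with the most similar node"; the lexicographic tie
rule exists only to make the output deterministic.

Intra-layer edge classification uses hop distances d₁, d₂ between the two
pair nodes' members in each input layer graph:

| d₁, d₂                         | kind      | default weight |
|--------------------------------|-----------|----------------|
| both = 1                       | match     | 1.0            |
| one = 1, other in [2, Δ]       | gap       | 0.2            |
| one = 1, other > Δ or ∞        | mismatch  | 0.5            |
| neither = 1                    | no edge   | —              |

Δ ≥ 2 (default 2). The boundary between gap and mismatch is the one
reading under which Δ actually "discriminates between gaps and mismatches";
the alternative literal phrasing ("distance less than Δ" with Δ = 2) is
vacuous, since distance < 2 means adjacency and hence a match. Note the
mismatch weight (0.5) deliberately exceeds the gap weight (0.2): these are
the published operating weights, kept verbatim although a gap (a nearby
pair) might intuitively deserve more than a mismatch; both are exposed in
`ScoringConfig` for users who disagree.

Distances are computed by per-source BFS truncated at Δ: for
classification, every distance beyond Δ is equivalent to disconnection, so
no full BFS is ever needed. Candidate enumeration is all pairs of pair
nodes within a layer, O(|V_al|²) — alignment graphs here are small (tens to
a few thousand pair nodes) and this keeps the rule table exact.

Inter-layer classification is purely edge-based: for pair nodes
(u₁,v₁)@k and (u₂,v₂)@h, the inter-layer edge (u₁@k, u₂@h) of network 1 and
(v₁@k, v₂@h) of network 2 are looked up; both present → heterogeneous
match (0.9), exactly one → heterogeneous mismatch (0.4), neither → no
edge. No gap case exists across layers: a hop-2 "near miss" through
another layer has no defined semantics in this model, so none is invented.

## Community mining

Pair nodes are distinct per layer, so the multilayer alignment graph *is* a
simple weighted graph over (layer, u, v) vertices and single-graph
community detection applies without a supra-adjacency construction. The
default backend is the two-level map-equation algorithm (Infomap) run
undirected and weighted through igraph, with igraph's RNG seeded per call
for reproducibility. A seeded weighted Louvain backend (networkx) is
registered as a fallback, and `register_backend` accepts user plug-ins;
the names genlouvain, abacus, clique_percolation and mdlp are reserved in
the registry for the other miners discussed in the local-alignment
literature but are not implemented. Backends must return a partition —
this is checked — and community ids are assigned by each community's
lexicographically smallest member, so output files are byte-stable.

Communities with fewer than `min_community_size` members (default 2) are
dropped when projecting to the node mapping: a local region of similarity
with one node carries no structure. This default is why node coverage can
sit slightly below 1 even at zero noise on sparse inputs.

## Evaluation measures

Node correctness against a true mapping M, per layer: P-NC = |M∩N|/|M|,
R-NC = |M∩N|/|N| (0 for empty N), F-NC their harmonic mean (arithmetic
available as an option). This orientation of P/R follows the source
formulas for these measure names even though it swaps the usual
precision/recall denominators — both raw values are reported, so either
convention can be read off. The multilayer F-NC is the plain mean over
layers; undefined (raises) when M is empty or no layer is shared.

NCV-GS3 per layer: with G₁′, G₂′ the subgraphs induced by the domain and
image of the layer mapping f, NCV = (|V(G₁′)|+|V(G₂′)|)/(|V₁|+|V₂|) with
denominators over the *full original node sets* (degradation never deletes
nodes), conserved edges c = |{(a,b) ∈ E(G₁′) : (f(a),f(b)) ∈ E(G₂′)}|, and
GS3 = c/(|E(G₁′)|+|E(G₂′)|−c), defined as 1 when both induced edge sets
are empty (nothing to conserve, nothing violated; with exactly one side
empty the formula itself yields 0). NCV and GS3 combine as the geometric
mean, the convention of the network-alignment literature this measure
comes from (arithmetic available as an option). The multilayer NCV-GS3 is
the mean over layers.

The inter-layer NCV-GS3 pools all inter-layer edges of all layer pairs
into one conservation computation; coverage counts each aligned node once
over the union of layers. An inter-layer F-NC is also reported: node
correctness pooled over layer-tagged pairs restricted to nodes incident to
at least one inter-layer edge in either input (falling back to all pairs
when neither input has inter-layer edges). The node-correctness literature
defines no inter-layer variant, so this restriction — score only the nodes
that participate in cross-layer structure — is this package's choice.

## Synthetic benchmark and what it does(n't) show

The generator draws each layer as a uniform G(n, m) random graph and each
layer pair's inter-layer edges uniformly from the bipartite pair set, with
exact totals. The benchmark fixes ten two-layer networks of 30 nodes (15
per layer) with total edge counts {90, 96, 84, 78, 95, 88, 93, 83, 94, 96};
the published table states only layer, node and edge totals, so the
15/15 split and the inter-layer fraction are this package's choices — the
fraction defaults to 0.2 and is a visible, sweepable parameter, chosen so
inter-layer conservation is measurable at every noise level. Degradation
removes floor(p·|E|) edges uniformly from the *combined* intra+inter pool
(the simplest faithful reading of "randomly removing edges from the
network"), keeps all nodes, and is applied at p ∈ {0.05, …, 0.25}. All
randomness flows from one master seed through SHA-256-derived sub-streams
keyed by (seed, network, noise, method), so suites and experiments are
bit-reproducible; derived seeds stay below 2³¹.

The default experiment — each network aligned with itself (noise 0) and
with its five degraded copies, identity seeds, identity truth — records
60 runs and finishes in under a second on one CPU; mean intra-layer
multilayer NCV-GS3 sits near 0.93–0.94 and both NCV-GS3 and F-NC decline
monotonically in the noise level, consistent with roughly 90% edge
conservation across the sweep (GS3 ≈ 1−p at full coverage, so the sweep
mean ≈ mean of √(1−p)).

What passing this benchmark does *not* show: uniform random graphs have no
community structure, degree heterogeneity or clustering, so the miner's
job is easy (the alignment graph at low noise is one dense block); real
biological layers are scale-free-ish and modular, seeds are noisy and
incomplete rather than identity, and the true mapping is partial. The
benchmark validates correctness of the pipeline and graceful degradation
under edge loss, not performance on real interactomes.

## Numerical and degenerate-input choices

* All metric values lie in [0, 1]; metrics raise `UndefinedMetricError`
  rather than return a sentinel when their denominator set is empty
  (empty truth, zero layers).
* `degrade(net, 0)` is exactly the identity; `degrade(net, 1)` keeps every
  node and removes every edge.
* Empty seed maps, empty layers and empty alignment graphs flow through:
  no pair nodes → no edges → no communities → empty mapping → R-NC = 0.
* File writers sort everything lexicographically; identical inputs give
  byte-identical outputs, which the tests assert.
* Self-alignment with identity seeds is a fixpoint: the alignment graph is
  isomorphic to the input (match-kind edges only) and, with
  `min_community_size=1`, every metric equals 1.0 exactly.

## Known limitations

* Only edge-removal noise; no edge addition or rewiring.
* One-to-one pair nodes; many-to-many seed resolution is out of scope.
* The heterogeneous (node-coloured) matching mode of the single-layer
  ancestor algorithm is not reproduced.
* Directed, weighted-input and temporal multilayer semantics are not
  modelled.
* Only two mining backends are implemented; the reserved names raise a
  usage error until a plug-in is registered.
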