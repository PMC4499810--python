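# Methods

## The alignment model

An interface-interaction network (IIN) is an undirected bipartite graph
G = (V, E) with V = {D, L}: D holds peptide-recognition domain vertices
(e.g. SH3 domains), L holds short peptide ligand-site vertices, and every
edge joins a domain to a ligand site.  An alignment of two IINs is a
one-to-one set of vertex pairs A = {[u_i, v_i]} restricted so that every
pair is domain–domain or ligand–ligand.

The aligner is greedy with an additive edge bonus.  Each candidate same-side
pair (u, v) carries a working score

    work(u, v) = base(u, v) + EAW * bonus_count(u, v)

where base is a weighted sum of per-feature similarity matrices and
bonus_count is the number of times (u, v) was a pair of still-unaligned
neighbours of a just-aligned pair.  At each step the highest working score
wins (ties: domain side first, then lexicographic ids); after aligning
(u, v), every pair (n1, n2) of currently unaligned same-side neighbours of u
and v gains one bonus increment.  Bonuses accumulate and are never removed;
already-aligned vertices are fixed and receive nothing.  The loop runs until
the smaller side of each partition is exhausted; an optional `min_score`
floor stops earlier.

Limiting behaviour is honoured exactly: EAW = 0 reproduces the plain greedy
baseline (verified trace-for-trace against an independently implemented
sorted sweep), and EAW = infinity is encoded as a two-key selection
(bonus count, then base score) rather than arithmetic infinity, so an
edge-extending candidate always beats a non-extending one while the run
continues past dead frontiers — the behaviour that separates it from
seed-and-extend.

Two baselines are included: plain greedy (descending base score, edges
ignored) and seed-and-extend (seed at the global best pair; thereafter only
pairs adjacent on both sides to an aligned pair are eligible, so every
non-seed step aligns at least one edge pair; the run dead-ends with the
frontier).

### Design choices the sources left open

* **Tie-breaking** is unspecified in the underlying method; we fix it to
  (domain side first, id in network 1, id in network 2), which makes traces
  reproducible byte-for-byte.
* **Bonus recipients**: increments go only to pairs of *currently unaligned*
  neighbours.  Granting them along edges into already-aligned vertices is an
  alternative reading; ours matches the worked example the demo fixture
  reproduces and is stated here as the package's rule.
* **EAW during training** is treated as one more parameter on [0, 1],
  optimised jointly with the feature weights.

## Similarity features

Per-vertex topological scores (degree, average shortest path length,
betweenness, closeness, eccentricity, neighbourhood connectivity, radiality,
stress, topological coefficient) are computed per connected component with
these fixed definitions: closeness(v) = 1 / mean distance to reachable
vertices; avg_shortest_path(v) = that mean; eccentricity(v) = max distance;
radiality(v) = (diam + 1 − aspl(v)) / diam within v's component (0 when the
diameter is 0); betweenness and stress use standard shortest-path counting
over unordered endpoint pairs, unnormalised; neighbourhood_connectivity(v)
= mean neighbour degree; topological_coefficient(v) = mean over partners w
sharing at least one neighbour of |N(v) ∩ N(w)| / deg(v).  Distance-based
features of an isolated vertex are defined as 0.  Clustering coefficient is
excluded: it is identically zero on bipartite graphs.

Two per-vertex score sets are turned into a pairwise similarity by
raw_ij = M − |s_i − s_j| with M the largest absolute cross-network
difference, then adj_ij = log(raw_ij + 1) / log(M + 1).  The absolute value
and the +1 shift are deliberate repairs of the bare difference formulation:
without them the raw score can leave [0, M] and the logarithm is undefined
at raw = 0.  Flat score sets (M = 0) map to all ones.  The normalization is
invariant to shifting or negating all scores.

Ligand peptides are too short for BLAST, so ligand-side sequence similarity
is Smith–Waterman with BLOSUM62 (affine gaps, defaults open 10 / extend 0.5:
a gap of length k costs 10 + 0.5(k − 1)), computed through Biopython's
`PairwiseAligner` and clamped at the empty-alignment score 0.  Protein- and
domain-level BLAST and functional (GO semantic similarity) scores are
consumed as imported tables, never computed.  Imported non-negative scores
are scaled to [0, 1] either by the global maximum (`linear_max`, the
default) or by log(s + 1)/log(max + 1); whether the original study used the
log scheme for sequence features is not recoverable, so both are provided.

The assembled base score is base = Σ_f w_f · adj_f per side, with weights on
[0, 1].

## Graphlet signatures

The catalogue of connected graphs on 3–5 vertices is generated by exhaustive
edge-subset enumeration with minimum-certificate canonicalisation (29
graphs; 20 contain an odd cycle), ordered by (vertex count, edge count,
descending degree sequence, certificate) — for up to four vertices this
coincides with the conventional published ordering.  Automorphism orbits are
computed by brute-force permutation; with the 2-node edge orbit as index 0
the enumeration yields 73 orbits, of which 23 belong to bipartite graphlets.
A frequently quoted figure for the bipartite signature length is 20 (out of
72); our exhaustive enumeration gives 23 (out of 73 including the edge
orbit), and neither quoted figure is used as an oracle — the package reports
what the enumeration yields.

Counting uses induced subgraphs (standard graphlet semantics) enumerated by
exclusive-neighbourhood extension, each connected set visited exactly once;
orbit identification is cached per labeled adjacency pattern.  This is
deliberate desk-scale counting — sparse IINs with a few hundred vertices —
not an ORCA-style combinatorial scheme.

Signature similarity between count vectors u, v is
1 − Σ_i D_i / Σ_i w_i with
D_i = w_i |log(u_i + 1) − log(v_i + 1)| / log(max(u_i, v_i) + 2).
Default weights are uniform.  A dependency weighting
w_i = 1 − log(o_i)/log(73) is available behind a flag, with o_i computed
programmatically as the number of orbits whose rooted graphlet is a rooted
induced subgraph of orbit i's rooted graphlet; this reconstruction matches
the published weighting qualitatively (edge orbit weight 1, dense 5-node
orbits least) but the published constants are not restated anywhere we can
verify, so uniform stays the default.

## Metrics

For an alignment A and an orthology map O: OVP counts pairs in A whose
parent proteins are in O; RPO counts distinct protein pairs of O represented
by at least one such pair (so RPO ≤ OVP always); EA counts edge pairs whose
endpoint pairs are both in A — unique (domain pair, ligand pair)
decomposition, counted once.  Maxima: max_ea = min(|E1|, |E2|); max_rpo
counts orthologous protein pairs with a same-side vertex pair available;
max_ovp is a maximum bipartite matching (Hopcroft–Karp) on the orthologous
same-side vertex-pair graph.  The matching formalisation of "maximum
possible OVP" is ours; published maxima for the original datasets cannot be
re-derived without those datasets.

## Training and feature reduction

The objective of training is RPO (EA breaks ties).  Each restart draws
uniform [0, 1] weights for every feature and the EAW, then hill-climbs with
step sizes 0.01^(1/4) ≈ 0.32, 0.1, 0.03, 0.01.  Moves of ±step on a single
parameter (random order, random first sign, both signs tried before giving
up on a parameter) are kept unless the previous alignment had strictly more
RPOs — a tie keeps the new value, allowing plateau drift, but only strict
improvement continues stepping the same parameter or extends the pass loop.
A step size is finished when a full pass brings no strict improvement.
Runs are fully reproducible from (seed, restarts, schedule).  The reference
procedure used at least 5,000 restarts; the desk-scale default here is 50,
configurable, and the shipped tests use 25 restarts on 20 + 150-vertex
instances, which recovers the planted weights reliably.

Redundancy reduction removes, while any same-side feature pair lies within a
Euclidean distance threshold (default 0.10 on the vectorized normalized
matrices), the member of the closest pair with the smallest summed distance
to all remaining features.  Iterative reduction retrains, averages weights
over the top-50 parameter sets (mean — whether the original criterion was
mean, median or minimum is unstated), drops the lowest-mean feature, and
stops before any removal that would reduce the best achievable RPO.

## Synthetic data generator

The generator defines the study conditions for every statistical test.
Defaults: 20 domains, 150 ligand sites, mean ligand degree 1.3, rewiring
probability 0.1, vertex-loss probability 0.05, informative-feature mean 0.9
with noise 0.05, three noise features, two ligand sites per ligand protein.
The ancestor is drawn by degree-proportional (deg + 1) attachment, giving
the exaggerated hub-and-spoke, multi-fan topology of real peptide-recognition
data; two descendants then lose vertices and rewire edge ligand-endpoints
independently.  The fraction of ancestor edges surviving identically in both
descendants matches the closed form ((1 − δ)²(1 − ρ))² within Monte-Carlo
tolerance, and planted-pair recovery is non-increasing in both the feature
noise and the rewiring rate (checked over 20 seeds per setting).

What the generator does *not* emulate: correlated domain/ligand loss,
binding-specificity structure in the rewiring (rewiring is uniform over
surviving ligands), realistic sequence evolution (ligand sequences are
i.i.d. random peptides), and protein-level paralogy.  Tests that pass on
this generator therefore demonstrate algorithmic correctness and the
feature-weighting mechanics, not performance on real interactome data.

The packaged demonstration fixture (`eaw_demo_fixture`) is a hand-built
5 + 5-vertex pair with prescribed base scores on which the third alignment
step provably flips between (E, 3) (no bonus) and (C, 3) (bonus applied
twice) — the canonical illustration of the additive edge bonus.

## Numerical notes and problem sizes

* Working scores are dense float matrices; retired rows/columns are masked
  with −inf.  Ties between equal floats resolve by the deterministic order
  above.
* merge-site splitting enumerates all contiguous partitions of an overlap
  run (2^(k−1) for k overlapping sites); runs of predicted 15-mers are short
  in practice.  Ties are broken by fewest vertices, then leftmost cuts.
* Aligning |L| = 500, |E| ≈ 600 networks takes well under a second of CPU in
  this implementation; the test suite bounds it loosely at 30 s.
* Statistical tests and the acceptance script use 20 + 150-vertex instances,
  25 restarts and 10 seeds — sizes chosen so a desk machine reproduces every
  number in minutes while leaving the observed effects far from their
  decision thresholds.

## Known limitations

* One-to-one alignments only; a protein with two domains aligned to a
  single-domain ortholog necessarily mismatches one of them.
* No multigraphs, edge weights, directed interactions or within-side edges;
  the bipartite assumption is structural.
* No BLAST, GO parsing or semantic-similarity computation — those scores are
  inputs.
* Desk-scale graphlet counting; hub degrees in the thousands would need a
  combinatorial counter.
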