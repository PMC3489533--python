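# Methods

## Graph model and counting conventions

The interactome is a directed multigraph.  Nodes are network objects with a
class drawn from {transcription_factor, receptor, ligand, kinase,
phosphatase, protease, enzyme, complex, compound, generic}; edges carry a
mechanism (binding, cleavage, covalent_modification, phosphorylation,
dephosphorylation, transformation, transport, catalysis,
transcription_regulation, microRNA_binding), an effect (positive, negative,
unspecified) and a species.  Rows identical in all five attributes collapse
on load; rows differing in any attribute are kept as parallel edges.

Every connectivity statistic counts **distinct counterpart nodes**, not raw
edges: parallel mechanisms and opposite orientations between the same pair
contribute one connection.  This is forced by the hypergeometric model — the
marked set must be a set of nodes — and by the published report format, in
which a protein's R equals its global degree and its "Actual" count is
bounded by the seed-list size.  Self-loops are stored but excluded from
degree, clustering and all connectivity counts; including them would let a
node be its own neighbor and corrupt the sampling model.

The clustering coefficient C_i = 2 n_i / (k_i (k_i − 1)) is computed on the
undirected projection (k_i distinct neighbors, n_i connected neighbor
pairs), returning 0 when k_i < 2.

Identifier mapping is case-insensitive against ids, then names, then
synonyms, in that priority order; a raw identifier hitting several nodes
maps to all of them, and unmatched identifiers are reported as data, not
errors.  This gives reproducible mapping without a curated thesaurus.

## Hypergeometric core

All tail sums are exact, computed as log-gamma binomials with log-sum-exp
accumulation; tails covering the whole support short-circuit to exactly 1.0.
The normal approximation is never used for p-values; the z-score
(r − μ)/σ with σ² = n q (1 − q) (1 − (n−1)/(N−1)) is reported alongside as a
ranking aid.  The distribution, its tails, μ and σ² are all invariant under
exchanging n and R (subset and marking are symmetric), which the test suite
asserts to 1e−12.  Degenerate nulls (σ = 0, e.g. R = 0 or n = N) yield
z = None rather than an arbitrary number.

Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`; input order is
preserved and ties receive equal q-values.  Default per-test significance
and FDR levels are 0.05, both configurable.

## Enrichment

Per term: r = |list ∩ term ∩ universe|, n = |list ∩ universe|,
R = |term ∩ universe|, N = |universe|.  Terms are always restricted to the
universe — members outside it are invisible — because the test is
competitive and the background must reflect what the assay could detect.
Three universe modes are exposed: every connected graph node, the ontology's
own protein content, or a custom list.  Terms whose overlap falls below
`min_overlap` are dropped **before** FDR so the family contains only
testable terms.  Only over-representation (upper tail) is tested.  The term
hierarchy is carried through GMT parsing but not used for p-value
adjustment; no parent–child decorrelation is applied.

## Over/under-connectivity

For candidate object o against seed list S: r = distinct members of
S \ {o} adjacent to o, n = |S \ {o}|, R = degree(o), N defaults to the
number of connected nodes minus one.  Excluding the tested object from both
the draw and the universe is numerically invisible at interactome scale
(N ≈ 2·10⁴) but makes the small-graph identity exact: the upper-tail
p-value equals the fraction of all C(N, n) seed placements with at least r
neighbors of o, which the suite verifies by exhaustive enumeration on
graphs of ≤ 12 nodes.  When published report rows are re-derived, their
printed integer columns are used verbatim as (r, n, R, N).

Under-connectivity defaults to the exact lower tail P(X ≤ r); the legacy
convention 1 − P(X ≥ r) is available behind `literal_paper_mode` for
compatibility with reports that print it.

The two-list directionality summary counts distinct ordered connected pairs
A→B and B→A.  The attached significance test is one defensible
instantiation (universe = all ordered node pairs, marked = the graph's
connected ordered pairs, draw = the |A|·|B| candidate pairs); the asymmetry
of the two raw counts is the primary readout.

## Hidden nodes

The condition-specific shortest-path network (CSSPN) is the union of all
minimum-length directed paths over all ordered seed pairs, built from
forward/backward breadth-first distance maps (a node v is on a shortest
a→b path iff d(a,v) + d(v,b) = d(a,b)).  Unit edge weights; mechanism and
effect do not affect path length.  "Internal" means strictly between the
endpoints of at least one used path; seeds that are never strictly internal
are classified source / target / source_and_target by the endpoints they
serve.

For candidate i and seed j, a counterpart t counts once when i is strictly
internal to at least one shortest path j→t **or** t→j — orientations
collapse, path multiplicity is ignored.  N_ij counts over all nodes, K_ij
over the other seeds.  p_ij is the upper hypergeometric tail at
(r = K_ij, n = K−1, R = N_ij, N′ = N−2); when the candidate is itself a
seed the selection shrinks to K−2.  The score is min_j p_ij, with BH-FDR
across candidates and ties broken by node id.  The universe is N−2 even
when some pairs are unreachable, matching the printed formula; a
`reachable_only` option substitutes the reachable counterpart count for
badly fragmented graphs (documented deviation).

Candidates default to the internal nodes of the CSSPN — the "hidden"
intermediaries — with an `all_nodes` mode for exploration.  Because the
statistic conditions on the candidate's own global path traffic (N_ij),
hubs earn no automatic advantage; the suite checks that top-decile hubs
appear among top-scored nodes no more often than under a raw betweenness
ranking on the same draws.

## Network generation

* **Direct interactions**: induced subgraph on the roots; isolated roots
  reported, clusters enumerated largest-first.
* **Expand by one**: roots plus first neighbors; a non-root survives only
  if it is interior to a path between two *different* roots whose non-root
  interior has at most two nodes.
* **Shortest paths**: all minimum-length directed paths per ordered pair of
  list members, skipping pairs whose minimum exceeds `max_path_length`.
* **Auto-expand**: synchronized breadth-first territories around each root;
  growth halts at the first radius where two territories share a node;
  expansion nodes not on any shortest root-to-root connecting path are
  removed.  A single root degenerates to its one-step neighborhood.
* **Analyze network**: the super-network is a *continued* auto-expansion
  (growth does not stop at first contact) until all mappable roots are
  mutually connected or a radius cap (default 3) is reached.  Fragments are
  then extracted cyclically: roots are visited in descending root-neighbor
  count (ties by id); each visit grows one breadth-first fragment up to
  `fragment_size` nodes over the remaining edge pool, consumes every pool
  edge inside the fragment, and the cycle repeats until the pool is empty.
  Edges are never reused across fragments; nodes may recur.  The published
  description specifies only "cyclical" division and the reuse rules; the
  greedy order above is this package's deterministic instantiation.
* **AN (TF) / AN (receptors)**: per transcription factor, all shortest
  directed paths from the closest receptor(s) — all receptors tied at the
  minimum distance are retained — and symmetrically per receptor.  Paths
  are directional, so the two modes are not reciprocal.  Optional
  decoration adds the receptors' ligands and the TFs' transcription
  targets.
* **Transcription regulation**: one network per immediate TF (any node
  with a transcription_regulation edge into a root — membership is decided
  by the edge mechanism, not the node's class annotation), containing the
  roots that reach it through root-only intermediaries plus its root
  targets.
* **Model canonical pathways**: per qualifying root, the union of all
  library chains containing it; ranked by seed count, ties by smaller
  total size.

Fragment scores use (r = seed nodes, n = fragment size, R = mapped list
size, N = connected-node count of the source graph).  The g-score is
z + 1.25 × (number of canonical pathways with at least one consecutive
step inside the fragment).  The 1.25-per-pathway bonus is the unique linear
fit to the published ranking table, in which fragments with two pathways
show g − z = 2.50 and zero-pathway fragments show g = z; the bonus is
exposed as a parameter since the original composite rule is unpublished.

## Synthetic data

The background generator orients a Barabási–Albert skeleton edge by edge
with a seeded RNG and assigns classes from a configurable mix (default
approximates a curated signaling database: ~8% TFs, 10% receptors, 16%
enzymes, 30% unannotated).  Preferential attachment is deliberate: curated
interactomes are heavy-tailed (average degree in the tens, hubs above a
thousand), which is the regime the z-score normalization exists for.
Defaults (500 nodes, attachment 3, 30-seed lists) keep unit runs in
milliseconds while preserving hub structure.

`plant_overconnected_hub` wires a low-degree non-seed node to a chosen
number of sampled seeds.  `plant_hidden_regulator` adds bidirectional edges
between a low-degree non-seed node and the routed seeds and removes the
routed seeds' direct mutual edges, so every routed pair sits at distance
exactly 2 with the planted node on a shortest path while all background
wiring is retained.  An earlier design that isolated the routed seeds was
rejected: when a node carries *all* of a seed's paths, its marked fraction
N_ij approaches the universe and the hypergeometric correctly reports no
enrichment — the planted signal must be specific to seed pairs, not to all
traffic.

What a green planted-recovery test establishes: the statistics recover a
strong, specifically planted signal against a preferential-attachment
background.  What it does not establish: performance on real curated
interactomes, whose degree correlations, annotation biases and multi-mapping
identifier structure the generator does not emulate; lists here are pure ID
sets with no abundances.

The 13-node worked-example fixture is engineered to reproduce every
published count of the hidden-nodes illustration (N = 13, K = 7, five
internal nodes, the source/target partition, N_BD = 7, K_BD = 5); the
original edge list is not published, so the fixture is a synthetic
construction verified against those counts, not a copy.

## Numerical and design choices

* Exact log-space tails; whole-support tails return exactly 1.0.
* Published-value comparisons in the tests use a tolerance of one unit in
  the last printed digit of each cell (the published table rounds one
  Expected cell upward by ~2 half-ulps: 0.4191 printed as 0.420).
* All orderings are total and deterministic: p-value ties break by term or
  node id, ratio ties by p then id, fragment ranking ties by p then
  smallest node id.
* The FDR calibration test checks the Monte-Carlo mean of the false
  discovery proportion against its 5% guarantee with a two-standard-error
  allowance, since the guarantee binds the expectation, which equals the
  nominal level exactly for independent all-null uniforms.
* Between-set significance and the AN fragment extraction order are
  documented instantiations of under-specified procedures (see above).
* The toolkit never hard-codes a universe size; N is always a property of
  the loaded graph or an explicit argument (published examples use their
  printed N verbatim).

## Limitations

* No curated interaction content, species orthology mapping or
  tissue-expression filtering; no text mining.
* Enrichment is one-sided and hierarchy-blind.
* Shortest paths are unweighted; mechanism-aware path costs are out of
  scope.
* Whole-profile ("no-cutoff") enrichment statistics in the style of
  GSEA/PAGE are not implemented.
* The canonical g-score bonus is inferred from a single published table;
  alternative calibrations are a parameter away.
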