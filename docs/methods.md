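# Methods

## Data model

A gARG is a tuple `(L, N, S, E)`: genome length `L > 0`, nodes `N`
representing haploid genomes, samples `S ⊆ N`, and edges `E` of tuples
`(c, p, I)` meaning child genome `c` inherits the disjoint interval set `I`
from parent genome `p`.  Coordinates are real-valued, 0-based, half-open
`[left, right)`; integer positions in fixtures are stored as reals.  The
invariants checked by `validate` are:

* node ids unique; samples a subset of the node table;
* the child→parent relation is acyclic, and where both endpoints are dated,
  `time(child) < time(parent)` strictly — ties are violations, zero-length
  generations must be expressed through distinct times or absent times;
* **per-child functional inheritance**: for any child and any position, at
  most one edge of that child covers the position (a genome inherits each
  site from at most one parent).

Node times are optional.  All orderings fall back to a deterministic
topological order (Kahn's algorithm with id tie-breaks) when times are
absent; when all nodes are dated, processing is strictly by `(time, id)`.
Node ids may be integers or strings: the formal definition uses integers,
but the worked examples label genomes with letters, and nothing in the
algorithms needs arithmetic on ids.  Canonical serialization sorts nodes by
id and edges by (child time if present, child id, parent id, first left
endpoint); the TSV writers emit this order, making write∘read and
read∘write identities on canonical tables.

An eARG is the classical event encoding: typed nodes (`sample`,
`common_ancestor`, `recombination` with a breakpoint strictly inside
`(0, L)`), and side-labelled edges.  Side labels (`L`/`R`) are mandatory on
the two out-edges of a recombination node: a breakpoint alone does not
determine the local trees, and this implementation refuses to invent
ordering rules.  Gene conversion is deliberately *not* a third event kind —
on the gARG side it is just an interval set with two or more intervals on
one edge, and on the eARG side it can only be expressed as two
recombination nodes joined by an edge.

## eARG → gARG conversion

The conversion duplicates the topology and annotates: every out-edge of a
sample or common-ancestor node gets `[0, L)`; the left out-edge of a
recombination node with breakpoint `x` gets `[0, x)` and the right out-edge
`[x, L)`.  A position exactly at the breakpoint routes to the right parent,
consistent with the half-open convention.  Node kind and breakpoint are
kept in metadata, so the eARG is recoverable (`recover_earg`), making the
conversion information-preserving.  The independent correctness oracle is
`earg_tree_at`, which recovers a local tree directly from the event
encoding by tracing pastwards from each sample and choosing the left parent
at a recombination node iff the query position is left of the breakpoint;
tests assert its agreement with tree extraction on the converted graph at
every breakpoint midpoint.

## Local trees

Breakpoints are the sorted union of `{0, L}` with all interval endpoints on
edges; between consecutive breakpoints the child→parent map is constant and
forms a forest (regions where samples have not coalesced have several local
roots; no virtual super-root is added).  `trees` maintains the active
parent map across the genome with edge-piece insertions and removals at
breakpoints — an incremental sweep, not per-region reconstruction —
and `tree_at` rebuilds one region independently as its oracle.

Unary suppression produces the conventional local-tree form: keep samples
and nodes with at least two sample-subtending local children; everything
else is bypassed, with survivors re-attached to their nearest surviving
ancestor.  Sample nodes are never suppressed, even when locally unary
(a sample may be an ancestor of another sample; the formal definition does
not forbid it).  `distinct_tree_count` counts maximal runs of adjacent
regions whose suppressed child→parent mappings are identical — node
identity matters, not label-free topology, because shared node identity
across local trees is the defining feature of the encoding.

## Ancestral material and resolution

Ancestral material is propagated pastwards Hudson-style.  Each sample
starts with one segment `[0, L)` carrying count 1.  Processing nodes
children-first, the contributions arriving along a node's child edges are
overlaid; positions covered by two or more contributions are local
coalescences (contributions from distinct children carry disjoint sample
sets at any one position, so counts simply add).  A segment whose count
reaches the full sample size has fully coalesced: it is recorded at the
node where the final merge happens and **not** propagated further.  This
stopping rule is what removes structure above the position-wise MRCA — in
the packaged event-history example, the grand MRCA `Q` disappears because
every segment coalesces in `K` or `P` below it.  The brute-force oracle
used in tests climbs each sample's parent chain position by position and
truncates at the first node shared by all paths.

`resolve` intersects every edge's intervals with the open (not yet fully
coalesced) material of its child, drops empty edges, and drops non-sample
nodes left without incident edges.  It keeps original node ids, is
idempotent, and preserves the samples' local genealogy at every position.

`coalescence_span` is the total length of positions where a node has two or
more child edges carrying ancestral material, divided by `L`.

## The simplification ladder

`simplify` always resolves first, then optionally:

* **prune-diamonds** — remove non-sample nodes with exactly one child edge
  and one parent edge in the graph, splicing child to parent with interval
  intersection.  This is the operationalization chosen for "singly
  connected" structure (e.g. the interiors of diamond motifs in
  forward-simulated graphs): it is the weakest criterion consistent with
  that example, and deliberately leaves recombination pass-through nodes
  (one child edge, two parent edges) alone so the level stays strictly
  weaker than the next one.
* **prune-unary** — remove every non-sample node whose coalescence span is
  zero (unary everywhere), reconnecting each child to each grandparent with
  interval intersection.  An option (`keep_recombination_passthrough`)
  retains two-parent nodes for presentation purposes, mirroring the choice
  of keeping recombination nodes "for clarity".
* **full** — rebuild from scratch: segments carry the youngest surviving
  node subtending them, edges are emitted only where two or more segments
  merge, so surviving nodes appear in local trees only where they are
  coalescent ("fully simplified").

Surviving nodes are renumbered densely in processing order; `node_map`
(old → new, survivors only) is always emitted so identity is recoverable,
and the result carries per-node coalescent intervals.  The binding contract
for every level, asserted on fixtures and simulated graphs, is that every
pairwise sample MRCA at every position is unchanged; node count and total
edge interval length are non-increasing along the ladder (edge *count* can
rise at the full level because edges are rewritten per region).

## Simulators

`sim_wf` is a prospective diploid Wright–Fisher model: `N` individuals per
generation, each non-founder genome picking a parent individual uniformly
with replacement (selfing permitted — the motivating pedigree example is
highly inbred, so no outbreeding constraint is imposed).  One meiosis draws
a Poisson number of crossovers (`crossover_rate` per transmitted genome,
breakpoints uniform), a starting genome, then Poisson gene-conversion
events with uniform starts and exponential tract lengths
(`gc_tract_length` mean), toggling the mosaic within each tract.  Inbound
edge intervals therefore partition `[0, L)` exactly.  Founders are
parentless; final-generation genomes are the samples.  All draws come from
one `numpy` generator in a fixed documented order, so a seed reproduces
bit-identical tables.

`sim_earg` is the backwards full-ARG process: with `k` open lineages,
pairs coalesce at rate `k(k−1)/2` and each lineage splits at rate
`recombination_rate`, with breakpoints uniform on `(0, L)` — over the whole
genome, not just the lineage's ancestral span, so breakpoints can fall in
nonancestral material and resolution later removes those edges, which is
exactly the phenomenon the worked event-history example illustrates.  The
process runs to the grand MRCA; as a termination safeguard, splits are
suppressed while the lineage count is at a (generous, default 200) cap.

What the generators emulate is inheritance topology only: no mutations,
sites, or sequences, no selection, demography or migration, and no
structural variation.  Passing tests therefore say nothing about mutational
processes or about inference from sequence data; they validate the graph
algebra, the local-tree recovery, and the resolution/simplification
contracts on realized inheritance structures.

## Default problem sizes and numerical choices

* Test batches use small graphs chosen for hand-checkability in the style
  of the worked figures: Wright–Fisher runs of 4–5 diploids for 4–6
  generations on `L = 10` with one crossover per meiosis, and three-sample
  event histories on `L = 7` with per-lineage split rate 0.4.  The property
  suite runs 200 event-history replicates and 50 Wright–Fisher replicates;
  the moment check uses 10,000 meioses (3-standard-error band).
* Positions are floats; interval arithmetic is exact for the integer-valued
  fixture coordinates.  The only tolerance in tests is a `1e-9` slack on
  summed interval lengths.
* Ties everywhere (node processing, serialization, Newick child order) are
  broken by node id, type-aware so integer and string ids can coexist.
* Degenerate inputs: empty interval sets on edges are rejected at parse
  time (an edge with no inheritance carries no information); empty sample
  sets are an error for resolution; a single sample node with no edges is a
  valid graph.

## Known limitations

* No binary tree-sequence compatibility, sites/mutations, or ploidy
  bookkeeping beyond free-text metadata.
* The event-encoding reader supports only the explicit side-labelled
  dialect; breakpoint-only files from specific inference tools are out of
  scope, as is any inference from sequence data.
* Whether an input event graph may have several parentless internal nodes
  is not settled; validation warns rather than errors.
* The propagation engine is quadratic in the number of contributions per
  node in the worst case — fine at fixture scale, not tuned for
  biobank-scale graphs.
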