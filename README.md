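# gargkit

Tools for **genome ancestral recombination graphs** (gARGs): the
representation of genetic ancestry under recombination as a directed
acyclic graph of haploid genomes whose edges carry inheritance intervals.

## The problem

Because of recombination, adjacent stretches of a genome can have different
paths of inheritance, so the genealogical tree of a sample of sequences
changes along the genome.  The structure weaving these local trees together
is an ancestral recombination graph.  Classical encodings attach the
history to *event* nodes — common-ancestor events, and recombination events
annotated with a crossover breakpoint — and require replaying those events
to answer any local question.  The genome-centric encoding implemented here
instead lets nodes be haploid genomes and annotates each edge `(c, p, I)`
with the set of genomic intervals `I` over which child genome `c` inherits
from parent genome `p`.  Formally a gARG is `(L, N, S ⊆ N, E)` with edges
`E = {(c, p, I)}`; intervals are half-open `[left, right)` and node times,
when present, increase pastwards.  This single structure captures
crossover, gene conversion, prospective forward-simulation records, and the
heterogeneous outputs of modern inference tools, at graded levels of
precision.

`gargkit` provides, for this data model:

* validation of the graph invariants (acyclicity, time order, and the
  per-child rule that a genome inherits each position from at most one
  parent) — `validate`;
* conversion of the classical event encoding (eARG) to a gARG and a direct
  traversal oracle over the event encoding — `earg_to_garg`,
  `earg_tree_at`;
* recovery of the sequence of local trees by an incremental breakpoint
  sweep — `trees`, `tree_at`, `to_newick`;
* Hudson-style propagation of ancestral material with local-coalescence
  detection, sample resolution, and a four-level simplification ladder
  (resolve → prune singly connected chains → drop everywhere-unary nodes →
  fully simplify) — `ancestral_material`, `resolve`, `simplify`,
  `coalescence_span`;
* synthetic generators: a prospective diploid Wright–Fisher forward
  simulator (pedigree-embedded gARGs) and a backwards
  coalescent-with-recombination generator (eARGs) — `sim_wf`, `sim_earg`;
* a plain-text TSV interchange format and a `gargkit` command-line
  interface (`validate`, `convert`, `trees`, `simplify`, `stats`,
  `simulate`).

It is aimed at population-genetics methods developers who want a small,
readable reference implementation of these operations with worked,
hand-checkable examples.

## Worked example

The packaged fixture `fig1_garg()` is a gARG embedded in a highly inbred
pedigree: 16 genomes `A`–`P` of 8 diploid individuals on a length-10
genome.  Samples `A`–`D` are the current generation; `A` and `C` are
recombinant products of the parental genomes `E` and `F` (crossovers at
positions 2 and 7).

```python
from gargkit import trees, to_newick, coalescence_span
from gargkit.fixtures import fig1_garg

g = fig1_garg()
for f in trees(g, suppress_unary=True):
    print(f.region, "->", to_newick(f))
print("coalescence span of F:", coalescence_span(g)["F"])
```

prints

```text
[0, 2) -> (A,D,(B,C)J)N;
[2, 7) -> (D,(B,(A,C)F)J)N;
[7, 10) -> (C,D,(A,B)J)N;
coalescence span of F: 0.5
```

The two crossovers delimit three local-tree regions.  In the middle region
`A` and `C` have already coalesced in their parent `F` — which is why `F`
appears as an internal node there and nowhere else, giving it a coalescence
span of 0.5 — and every region is rooted in the shared ancestor `N`.  The
same numbers are available from the shell:

```sh
gargkit stats src/gargkit/data/fig1.nodes.tsv src/gargkit/data/fig1.edges.tsv
# ... "distinct_tree_count": 3, "node_count": 16, "breakpoint_count": 2 ...
```

The second packaged example, `fig3_earg()`, is a Wiuf–Hein-style event
history of three samples.  Converting it and resolving against the samples
demonstrates the two classic pruning effects: the out-edge of the
recombination node whose breakpoint (position 5) fell in nonancestral
material is removed, and the grand MRCA `Q` disappears because every
genomic segment has fully coalesced below it.

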