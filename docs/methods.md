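# Methods

## Problem and objective

Given rooted input trees T₁,…,T_l with overlapping taxon sets covering
{1,…,n}, every non-trivial clade (the taxon set below a non-root internal
node) becomes one column of a matrix over {0, 1, ?}: 1 for taxa inside the
clade, 0 for the other taxa of that tree, ? for taxa the tree does not
contain. A collection has a parent tree — a supertree whose restriction to
each input's taxa refines that input — iff this matrix is an incomplete
directed perfect phylogeny. Conflicts are resolved under minimum column
deletion: remove a minimum-weight column set so the remainder is
realizable. Weights come from one of three schemes (unit; bootstrap
support of the clade's node; length of the clade's incoming edge), with a
pluggable transform (default: the raw value) and a `missing_policy` weight
(default 1.0) where a support or length is absent.

Column compatibility over partial columns uses the three-pattern test: two
columns conflict iff taxa witnessing (1,1), (1,0) and (0,1) all exist among
known entries. For complete columns this is the classical nested-or-disjoint
rule on the ones-sets. `conflict_fraction` (the share of columns conflicting
with at least one other) uses this test; it is a descriptive statistic and
deliberately counts duplicated columns separately.

## The top-down construction

Each phase works on a block (S, D) of the current partition. In G(S, D),
taxa and clades are joined where the matrix entry is 1; semiuniversal
clades (entries in {1, ?} over all of S) are removed at zero cost, since
their ?-entries can be resolved to 1. Disconnected blocks split for free.
Connected blocks are split by a minimum vertex-cut on the clade side,
computed by max-flow in the split-vertex network H(S, D′): arcs (c⁻, c⁺)
carry capacity w(c); all other arcs are effectively infinite (total clade
weight + 1), so finite cuts consist of clade arcs only. The source s is
fixed to the smallest taxon of S and the minimum is taken over sinks
t ∈ S∖{s}.

Numerical conventions, applied consistently everywhere:

* cost/weight comparisons use relative tolerance 1e-9 (branch-length
  weights are reals; all other arithmetic is sums of inputs);
* the representative cut for a terminal is the *minimal source side* — the
  residual-reachable set from s, which is the same for every maximum flow;
* ties between equal-weight cuts are broken by the lexicographically
  smallest canonical encoding of the induced taxon partition (parts sorted
  internally and among each other);
* every deletion set is normalized to the exact spanning set of its induced
  partition (clades with taxa in ≥ 2 parts); for positive weights this is
  the unique minimal deletion set inducing that partition;
* zero-weight clades are deleted only when they lie in the chosen cut.

Max-flow is a compact Dinic implementation operating directly on the
network (taxa, split clade vertices, one virtual sink, switchable
constraint arcs). The test suite cross-checks it against networkx minimum
cuts and against exhaustive deletion search on random instances.

## Suboptimal cuts

**Enumeration.** Cuts must appear in non-decreasing weight order,
deduplicated by induced taxon partition, with the minimum vertex-cut first.
The search runs best-first over *taxon bipartitions*: a region of the
search space fixes some taxa to the source or sink side (realized as
infinite constraint arcs) and is solved by one constrained max-flow; the
root regions partition the space by the smallest sink-side taxon, and a
popped region spawns one child per still-unassigned taxon, so every
bipartition is reached exactly once. Since a partition with q > 2 parts is
not the crossing set of any single bipartition, emitted partitions are
lazily *meet-closed*: when a partition is emitted, its common refinements
with previously emitted partitions enter the queue, weighted by their exact
spanning sets. Every achievable partition is the meet of its own
part-vs-rest bipartitions, each of weight no larger than the partition's
own, so the combined stream emits every achievable partition at its minimum
weight in non-decreasing order — verified against exhaustive 2^|D| search.
Enumeration accepts an upper bound and stops once the next weight exceeds
it.

**Sampling.** The bipartite graph is projected to the undirected multigraph
U(S, E): each clade contributes a clique over its incident taxa, colored by
the clade. One contraction step first draws a color proportional to clade
weight among colors still spanning ≥ 2 super-nodes, then one non-loop
clique edge of that color uniformly (super-node pairs weighted by the
product of member counts). Trials share work through recursive contraction
(branch twice at ≈ n/√2 super-nodes). Each resulting bipartition maps back
to the clade set that must be deleted, with identical weight. Low-weight
cuts are sampled more often, but no minimum-cut guarantee exists, so a
flow-computed minimum cut is always added. The default number of sampled
cuts is ⌈|S|²·log₁₀²(|S|+1)⌉ — the |S|² log² |S| shape the recursion can
deliver without changing its asymptotics, with the base-10 constant chosen
so that desk-scale beam runs stay fast; it is overridable per call.
Per-block random generators are derived from the global seed and a stable
hash of the block's canonical signature, so results are independent of
evaluation order and of the cut cache.

## Beam search

A partial solution of order p is (ℳ, T, cost): a partition of taxa and
surviving clades into p blocks, the partial tree whose leaves are the
blocks, and the accumulated deletion cost. Phase p expands every solution
of order exactly p through the cut lists of its multi-taxon blocks;
solutions of higher order (created by q-way cuts or free splits, which
raise the order by q−1 and create a q-ary node directly, without arbitrary
binarization) pass through and count against the beam width. The k
lowest-cost solutions are retained, ordered by (cost, canonical partition
encoding); duplicates — same partial tree and same surviving clades,
reached by different cut orders — are merged. Cut lists are cached per
block and reused across solutions and phases; a cached list truncated by a
cost bound is recomputed if a later phase needs a looser bound. The running
k-th best cost of the phase prunes cut generation (enumeration stops at the
bound; sampling is skipped when even the block's minimum cut cannot enter
the top k). With k = 1 the algorithm is exactly greedy BCD, verified
against an independent implementation. A preprocessing hook on the encoded
system (e.g. for strict consensus merging) is exposed and defaults to the
identity. `finalize` returns the best-scoring tree, or the majority-rule
consensus (strictly > 50% of clades) of all trees tied within tolerance.

## Synthetic data generator

`simulate_model_tree` draws a Yule topology (repeatedly split a uniformly
chosen leaf) with exponential branch lengths (mean 0.1, a typical
substitutions-per-site scale). `sample_source_trees` emulates the structure
of clade-based supertree benchmarks: `n_clade_trees` trees (default 6 at
n = 32, giving overlapping trees of roughly 5–25 taxa), each the model
restricted to a within-clade sample (each taxon kept with probability
`dense_p` = 0.75) of a random model clade with ≥ `min_clade_size` = 4 taxa;
plus one scaffold tree on ⌈scaffold_factor·n⌉ uniformly chosen taxa. Then,
in order: per-tree taxa deletion at `deletion_rate` (fraction of each
tree's taxa removed), `conflict_nni` random rooted NNI moves per tree
(swap a child of an internal node with that node's sibling subtree), and
optional pseudo-supports (uniform on [50, 100]). With zero NNI moves the
collection is compatible by construction.

The default scaffold factor is 1.0 (the benchmark's complete-scaffold
setting): at desk scale a fractional scaffold leaves several taxa uncovered
in almost every draw, so the resample-until-covered rule would rarely
terminate; fractional factors remain available with bounded retries and a
clear error. Everything is reproducible from the seed.

What the generator does *not* emulate: estimation error from sequence
simulation and ML tree inference (conflict is injected as local NNI noise
instead), birth–death model trees, non-uniform taxon sampling, and rogue
taxa. Passing tests on these fixtures therefore demonstrate the
combinatorial correctness and the beam's behaviour under localized,
controllable conflict — not performance on any particular empirical
dataset.

## Evaluation metrics

All split metrics use non-trivial unrooted bipartitions (both sides ≥ 2),
the common practice even for rooted supertrees. F1 = 2TP/(2TP+FP+FN)
against a model tree on the same leaf set (defined as 1.0 when both trees
have no non-trivial splits). Against source trees, SFN rate is the summed
count of source splits missing from the supertree's restrictions divided by
the total source split count; SFP rate is the summed count of extra splits
in the restrictions divided by the total split count of the restrictions
(the restricted tree's splits are the objects counted in the numerator, so
they also form the denominator). Empty denominators yield rate 0.

## Problem sizes

The test suite and `scripts/acceptance.py` use 24–64 taxon instances with
6–12 source trees: large enough that beams of width 25 explore genuinely
different cut sequences, small enough that exhaustive 2^|D| oracles and
repeated full runs remain cheap. The acceptance script summarizes 30
conflicting and 15 conflict-free collections at n = 32.

## Known limitations

* Beam search is a heuristic for an NP-hard objective; no global optimality
  of the MCD score is guaranteed for any finite k.
* The bootstrap/branch-length schemes use the raw support value or edge
  length as the weight; more elaborate reliability transforms can be
  supplied via the `transform` hook.
* Strict consensus merger preprocessing is exposed only as a hook (default
  identity).
* Input trees must be rooted; no rerooting heuristics are provided.
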