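# bcdbeam — Bad Clade Deletion supertrees with beam search

`bcdbeam` reconstructs a rooted **supertree** from a collection of rooted
phylogenetic trees with overlapping, non-identical taxon sets — the everyday
situation when combining gene trees or published phylogenies, and the core
subroutine of divide-and-conquer pipelines for very large phylogenies. It is
aimed at phylogeneticists who need a fast, polynomial-time supertree method
whose output quality is competitive with matrix representation with
parsimony (MRP) on conflicting input.

## The method

The input trees T₁,…,T_l on taxa {1,…,n} are encoded in a matrix M(𝒯) over
{0, 1, ?}: each non-trivial clade c of each tree is one column with weight
w(c) (unit, bootstrap-support, or branch-length weighting). The collection
has a parent tree exactly when M(𝒯) admits an incomplete directed perfect
phylogeny; conflicts are resolved under the **minimum column deletion**
(MCD) objective — delete a minimum-weight set of columns so that the rest
is conflict-free.

Bad Clade Deletion (BCD) builds the supertree top-down. For the current
taxon set S and surviving clades D it forms the bipartite graph G(S, D) with
an edge (t, c) whenever M[t, c] = 1, removes *semiuniversal* clades (no
0-entry inside S) for free, and, if G is connected, disconnects the taxa by
a minimum-weight **vertex-cut** on the clade side. The cut is found by
max-flow in the network H(S, D′), where each clade becomes an arc (c⁻, c⁺)
of capacity w(c) and all taxon-incident arcs are unbounded, minimizing over
s–t cuts for a fixed source taxon s. Each cut resolves one node of the
growing supertree; the recursion's taxon subsets form its hierarchy.

The **beam search** extension keeps the k best partial solutions
(ℳ, T, cost) alive per phase instead of greedily committing to one cut.
Two subroutines supply each block's k best (or k sampled) suboptimal cuts:

* **Enumeration (`enum`)** — exact, emits taxon-separating cuts in
  non-decreasing weight order via best-first search over constrained
  max-flow subproblems (quadratic dependence of total work on k).
* **Cut sampling (`sample`)** — randomized recursive edge contraction on
  the clique projection U(S, E) of G(S, D); an edge is drawn by first
  choosing a clade with probability proportional to its weight, then one of
  its clique edges uniformly. Cheap cuts are sampled more often, and a
  flow-computed minimum cut is always added (linear dependence on k).

With k = 1 both reduce to greedy BCD. Quality is scored by split F1 against
a known model tree, or SFN/SFP rates (summed false negative / false
positive splits of the supertree's restrictions) against the source trees.

## Worked example

```python
from bcdbeam import (encode, run, finalize, parse_newick, write_newick,
                     conflict_fraction, sfn_sfp)

trees = parse_newick("((a,b),c);\n((b,c),d);\n((a,d),(b,c));")
system = encode(trees, weighting="unit")
print("taxa:", system.n, "clades:", system.m)
print("conflict fraction:", round(conflict_fraction(system), 3))
results = run(system, k=25, method="enum")
for t, cost in results:
    print(f"cost {cost:g}  {t.newick()}")
final = finalize(results)
print("final:", write_newick(final), end="")
```

prints

```
taxa: 4 clades: 4
conflict fraction: 0.5
cost 1  ((a,d),(b,c));
cost 2  (a,(b,c),d);
cost 2  ((a,(b,c)),d);
cost 2  (((a,b),c),d);
cost 2  (((a,d),b),c);
cost 3  ((a,b,c),d);
cost 3  ((a,b),c,d);
cost 3  ((a,d),b,c);
cost 4  (a,b,c,d);
final: ((a,d),(b,c));
```

Half of the four input clades conflict with another clade. The cheapest
resolution deletes a single unit-weight column (cost 1), yielding the
supertree ((a,d),(b,c)); the beam also reports every strictly worse
alternative up to the star tree, which would delete all four columns.

The same pipeline is available on the command line:

```
bcd-beam simulate --config fixture.yaml --output-sources s.nwk --output-model m.nwk
bcd-beam build --input s.nwk --output supertree.nwk -k 25 --method sample --seed 0
bcd-beam eval --supertree supertree.nwk --sources s.nwk --model m.nwk
```

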