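"""Shared fixtures: random cut-graph instances and brute-force oracles."""

from __future__ import annotations

import itertools
import random

import pytest

from bcdbeam import build_graph
from bcdbeam.cutgraph import CutGraph, components, remove_semiuniversal
from bcdbeam.matrix import Clade


def make_clades(specs, universe):
    """Build clades from (ones_string, weight) pairs over a string universe."""
    return [
        Clade(frozenset(ones), frozenset(universe), float(w), 0, i + 1)
        for i, (ones, w) in enumerate(specs)
    ]


def make_graph(specs, universe):
    return build_graph(make_clades(specs, universe), universe)


def random_cut_instance(rng: random.Random, max_s=7, max_d=8, wmax=5):
    """A random connected, normalized CutGraph with >= 2 taxa, or None.

    Clades get random ones/zeros subsets and integer weights in 1..wmax;
    the largest connected component is returned.
    """
    n = rng.randint(3, max_s)
    taxa = [chr(97 + i) for i in range(n)]
    m = rng.randint(2, max_d)
    clades = []
    for j in range(m):
        size = rng.randint(2, n)
        ones = frozenset(rng.sample(taxa, size))
        rest = [t for t in taxa if t not in ones]
        if not rest:
            continue
        zeros = frozenset(rng.sample(rest, rng.randint(1, len(rest))))
        clades.append(Clade(ones, ones | zeros, float(rng.randint(1, wmax)), 0, j + 1))
    if not clades:
        return None
    g = build_graph(clades, taxa)
    comps = [c for c in components(g) if len(c[0]) >= 2 and c[1]]
    if not comps:
        return None
    S, D = max(comps, key=lambda c: len(c[0]))
    g = remove_semiuniversal(CutGraph(S, D))
    if len(g.S) < 2 or not g.D or len(components(g)) > 1:
        return None
    return g


def brute_force_partitions(graph: CutGraph) -> dict[tuple, float]:
    """Minimum deletion weight per achievable induced taxon partition,
    by exhaustive search over all 2^|D| deletion sets."""
    best: dict[tuple, float] = {}
    for r in range(1, len(graph.D) + 1):
        for U in itertools.combinations(graph.D, r):
            parts = components(graph, frozenset(U))
            if len(parts) < 2:
                continue
            key = tuple(sorted(tuple(sorted(p)) for p, _ in parts))
            w = sum(c.weight for c in U)
            if key not in best or w < best[key]:
                best[key] = w
    return best


def brute_force_min_cut_weight(graph: CutGraph) -> float:
    return min(brute_force_partitions(graph).values())


@pytest.fixture
def caterpillar_newick():
    return "((((a,b),c),d),e);"
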