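"""Beam engine: initialization, expansion, phases, full runs, finalize."""

import pytest

from bcdbeam import (
    Beam,
    FixtureConfig,
    encode,
    finalize,
    init_partial_solutions,
    parse_newick,
    refines,
    restrict,
    run,
    sample_source_trees,
    simulate_model_tree,
    step,
)
from bcdbeam.beam import expand
from bcdbeam.matrix import CladeSystem


def small_conflict_system():
    return encode(parse_newick("((a,b),c);\n((b,c),a);"))


class TestInit:
    def test_single_order_one_solution(self):
        beam = init_partial_solutions(small_conflict_system())
        (sol,) = beam.solutions
        assert sol.order == 1
        assert sol.cost == 0.0
        blocks = sol.blocks
        assert blocks[0][0] == frozenset("abc")
        assert len(blocks[0][1]) == 2

    def test_single_taxon_run(self):
        system = CladeSystem(("a",), [])
        (tree, cost) = run(system, k=1)[0]
        assert cost == 0.0
        assert tree.taxa == {"a"}

    def test_initial_cost_zero_any_weighting(self):
        trees = parse_newick("((a:1,b:2)90:3,c:4);")
        for scheme in ("unit", "bootstrap", "branch_length"):
            beam = init_partial_solutions(encode(trees, weighting=scheme))
            assert beam.solutions[0].cost == 0.0


class TestExpand:
    def test_bipartition_raises_order_by_one(self):
        beam = init_partial_solutions(small_conflict_system())
        (sol,) = beam.solutions
        block = sol.blocks[0]
        cuts = beam.cut_list(block, None)
        new = expand(sol, block, cuts.cuts[0])
        assert new.order == 2
        assert new.cost == 1.0

    def test_multiway_cut_raises_order_accordingly(self):
        # the weight-3 cut of the triangle-free worked instance has 3 parts
        system = encode(parse_newick("((a,b),c);\n((b,c),a);"))
        beam = Beam(system, k=5)
        (sol,) = beam.solutions
        block = sol.blocks[0]
        three_way = next(
            c for c in beam.cut_list(block, None).cuts if len(c.parts) == 3
        )
        new = expand(sol, block, three_way)
        assert new.order == sol.order + 2

    def test_foreign_cut_rejected(self):
        system = small_conflict_system()
        beam_a = Beam(system, k=1)
        beam_b = Beam(encode(parse_newick("((x,y),z);")), k=1)
        cut = beam_b.cut_list(beam_b.solutions[0].blocks[0], None).cuts[0]
        with pytest.raises(ValueError):
            expand(beam_a.solutions[0], beam_b.solutions[0].blocks[0], cut)


class TestStep:
    def test_k2_keeps_both_unit_cost_solutions(self):
        system = small_conflict_system()
        beam = Beam(system, k=2)
        step(beam)
        costs = sorted(s.cost for s in beam.solutions)
        assert costs == [1.0, 1.0]
        keys = {s.partition_key for s in beam.solutions}
        assert keys == {
            (("a",), ("b", "c")),
            (("a", "b"), ("c",)),
        }

    def test_pass_through_when_all_orders_exceed_phase(self):
        system = small_conflict_system()
        beam = Beam(system, k=2)
        step(beam)
        snapshot = list(beam.solutions)
        beam.phase = 1  # rewind: no solution has order == 1 anymore
        step(beam)
        assert beam.solutions == snapshot
        assert beam.phase == 2


class TestRun:
    def test_conflicting_pair_costs_one_clade(self):
        results = run(small_conflict_system(), k=1)
        tree, cost = results[0]
        assert cost == 1.0
        assert tree.topology_id() in ("((a,b),c);", "(a,(b,c));")

    def test_compatible_inputs_cost_zero_parent_tree(self):
        model = simulate_model_tree(16, seed=8)
        sources = sample_source_trees(
            model, FixtureConfig(n_taxa=16, n_clade_trees=4, conflict_nni=0, seed=8)
        )
        system = encode(sources)
        tree, cost = run(system, k=1)[0]
        assert cost == 0.0
        for src in sources:
            assert refines(restrict(tree, src.taxa), src)

    def test_k25_returns_sorted_costs(self):
        model = simulate_model_tree(20, seed=4)
        sources = sample_source_trees(
            model, FixtureConfig(n_taxa=20, n_clade_trees=5, conflict_nni=2, seed=4)
        )
        results = run(encode(sources), k=25, method="enum")
        assert 1 <= len(results) <= 25
        costs = [c for _, c in results]
        assert costs == sorted(costs)
        for tree, _ in results:
            assert tree.taxa == set().union(*(s.taxa for s in sources))

    def test_cache_disabled_is_identical(self):
        model = simulate_model_tree(16, seed=9)
        sources = sample_source_trees(
            model, FixtureConfig(n_taxa=16, n_clade_trees=4, conflict_nni=2, seed=9)
        )
        system = encode(sources)
        for method in ("enum", "sample"):
            with_cache = run(system, k=5, method=method, seed=3, use_cache=True)
            without = run(system, k=5, method=method, seed=3, use_cache=False)
            assert [(t.topology_id(), c) for t, c in with_cache] == [
                (t.topology_id(), c) for t, c in without
            ]

    def test_no_duplicate_solutions_retained(self):
        system = small_conflict_system()
        beam = Beam(system, k=10)
        while not all(s.order == 3 for s in beam.solutions):
            step(beam)
        keys = [s.merge_key for s in beam.solutions]
        assert len(keys) == len(set(keys))

    def test_preprocess_hook_defaults_to_identity(self):
        system = small_conflict_system()
        plain = run(system, k=1)
        hooked = run(system, k=1, preprocess=lambda s: s)
        assert [(t.topology_id(), c) for t, c in plain] == [
            (t.topology_id(), c) for t, c in hooked
        ]


class TestFinalize:
    def test_unique_best(self):
        trees = parse_newick("((a,b),c);\n(a,b,c);\n((b,c),a);")
        results = list(zip(trees, [3.0, 5.0, 7.0]))
        assert finalize(results) is trees[0]

    def test_tied_best_gives_majority_consensus(self):
        trees = parse_newick("((a,b),c);\n((b,c),a);")
        out = finalize(list(zip(trees, [3.0, 3.0])))
        assert out.topology_id() == "(a,b,c);"  # conflicting clade collapsed

    def test_single_result_identity(self):
        (t,) = parse_newick("((a,b),c);")
        assert finalize([(t, 2.0)]) is t
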