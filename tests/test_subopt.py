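"""Suboptimal cut enumeration, projection, and contraction sampling."""

import random

import numpy as np
import pytest

from bcdbeam import enumerate_cuts, min_vertex_cut, project_cut, sample_cuts
from bcdbeam.subopt import default_trials, sample_partitions

from conftest import brute_force_partitions, make_graph, random_cut_instance


class TestEnumerateCuts:
    def test_worked_example_order(self):
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        cuts = enumerate_cuts(g, 3)
        assert [c.weight for c in cuts.cuts] == [1.0, 2.0, 3.0]
        assert [sorted(x.column_id for x in c.deleted) for c in cuts.cuts] == [
            [1], [2], [1, 2],
        ]
        # the weight-3 cut splits S into three parts
        assert len(cuts.cuts[2].parts) == 3

    def test_k1_equals_min_vertex_cut(self):
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        (only,) = enumerate_cuts(g, 1).cuts
        mvc = min_vertex_cut(g)
        assert only.partition_key == mvc.partition_key
        assert only.weight == mvc.weight

    def test_upper_bound_stops_enumeration(self):
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        cuts = enumerate_cuts(g, 5, upper_bound=1.5)
        assert [c.weight for c in cuts.cuts] == [1.0]

    def test_three_part_partition_found(self):
        # triangle of pairwise-overlapping clades: a|b|c costs all three
        g = make_graph([("ab", 1), ("ac", 1), ("bc", 1)], "abc")
        cuts = enumerate_cuts(g, 10)
        assert [c.weight for c in cuts.cuts] == [2.0, 2.0, 2.0, 3.0]
        assert cuts.complete

    def test_k_zero_rejected(self):
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        with pytest.raises(ValueError):
            enumerate_cuts(g, 0)

    def test_disconnected_rejected(self):
        g = make_graph([("ab", 1)], "abc")
        with pytest.raises(ValueError):
            enumerate_cuts(g, 2)

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(99)
        done = 0
        while done < 40:
            g = random_cut_instance(rng, max_s=6, max_d=7)
            if g is None:
                continue
            want = sorted(brute_force_partitions(g).values())[:10]
            got = [c.weight for c in enumerate_cuts(g, 10).cuts]
            assert got == pytest.approx(want)
            assert got == sorted(got)  # non-decreasing
            # distinct induced partitions
            keys = [c.partition_key for c in enumerate_cuts(g, 10).cuts]
            assert len(keys) == len(set(keys))
            done += 1


class TestProjectCut:
    @pytest.mark.parametrize(
        "side, expected_ids, expected_weight",
        [("a", [1], 1.0), ("b", [1, 2], 3.0), ("ab", [2], 2.0)],
    )
    def test_examples(self, side, expected_ids, expected_weight):
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        cand = project_cut((set(side), set("abc") - set(side)), g)
        assert sorted(c.column_id for c in cand.deleted) == expected_ids
        assert cand.weight == expected_weight

    def test_empty_side_rejected(self):
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        with pytest.raises(ValueError):
            project_cut((set(), set("abc")), g)

    def test_weight_never_below_partition_minimum(self):
        rng = random.Random(4)
        done = 0
        while done < 25:
            g = random_cut_instance(rng, max_s=6, max_d=6)
            if g is None:
                continue
            best = brute_force_partitions(g)
            taxa = sorted(g.S)
            for r in range(1, len(taxa)):
                side = frozenset(taxa[:r])
                cand = project_cut((side, g.S - side), g)
                assert cand.weight >= best[cand.partition_key] - 1e-9
            done += 1


class TestSampleCuts:
    def test_seeded_determinism(self):
        g = make_graph([("ab", 1), ("bc", 2), ("ac", 3)], "abc")
        a = sample_cuts(g, 3, seed=7)
        b = sample_cuts(g, 3, seed=7)
        assert [(c.weight, c.partition_key) for c in a.cuts] == [
            (c.weight, c.partition_key) for c in b.cuts
        ]

    def test_minimum_cut_always_included(self):
        # even with trials=1 the flow minimum cut is appended
        g = make_graph([("ab", 1), ("bc", 2)], "abc")
        cuts = sample_cuts(g, 1, seed=0, trials=1)
        mvc = min_vertex_cut(g)
        assert cuts.cuts[0].weight == mvc.weight
        assert cuts.cuts[0].partition_key == mvc.partition_key

    def test_clique_projection_samples_every_pair(self):
        # a single clade over {a,b,c} yields clique edges ab, ac, bc; each
        # trial contracts one of them, so over many trials all three
        # resulting bipartitions occur
        from bcdbeam.cutgraph import CutGraph
        from bcdbeam.matrix import Clade

        g = CutGraph(
            frozenset("abc"),
            [Clade(frozenset("abc"), frozenset("abcx"), 1.0, 0, 1)],
            normalized=True,
        )
        rng = np.random.Generator(np.random.PCG64(1))
        seen = set()
        for a, b in sample_partitions(g, 200, rng):
            seen.add(tuple(sorted((tuple(sorted(a)), tuple(sorted(b))))))
        assert len(seen) == 3

    def test_sampled_weights_match_projection(self):
        rng = random.Random(11)
        done = 0
        while done < 15:
            g = random_cut_instance(rng, max_s=6, max_d=6)
            if g is None:
                continue
            cuts = sample_cuts(g, 10, seed=done)
            best = brute_force_partitions(g)
            for cand in cuts.cuts:
                # weight equals the spanning set of the candidate's own
                # partition, and is never below the partition's true minimum
                side_of = {
                    t: i for i, (taxa, _) in enumerate(cand.parts) for t in taxa
                }
                spanning = sum(
                    c.weight
                    for c in g.D
                    if len({side_of[t] for t in g.members[c]}) >= 2
                )
                assert cand.weight == pytest.approx(spanning)
                assert cand.weight >= best[cand.partition_key] - 1e-9
            done += 1

    def test_default_trials_shape(self):
        assert default_trials(5) == int(np.ceil(25 * np.log10(6) ** 2))
        assert default_trials(32) > default_trials(8) > default_trials(4)


def test_low_weight_cuts_sampled_more_often():
    """On an instance with one cheap and several expensive bipartitions, the
    cheap partition dominates the sample."""
    g = make_graph([("bc", 1), ("ab", 10), ("cd", 10), ("de", 10)], "abcde")
    rng = np.random.Generator(np.random.PCG64(2024))
    counts = {}
    for a, b in sample_partitions(g, 2000, rng):
        key = tuple(sorted((tuple(sorted(a)), tuple(sorted(b)))))
        counts[key] = counts.get(key, 0) + 1
    cheap = tuple(sorted((("a", "b"), ("c", "d", "e"))))
    assert counts[cheap] == max(counts.values())
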