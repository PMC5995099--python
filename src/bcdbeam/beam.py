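"""Beam search over partial supertree solutions (top-down column deletion).

A partial solution of order p partitions the taxa (and surviving clades)
into p blocks, carries the partial tree whose leaves are the blocks, and the
deletion cost accumulated so far.  In each phase every solution of the
current order is expanded through the k best (or k sampled) vertex-cuts of
each of its blocks, and the k lowest-cost distinct solutions are retained.
With k=1 this is exactly the greedy Bad Clade Deletion algorithm.  Cut lists
are cached per block and reused across solutions and phases; a running upper
bound on the k-th best cost of the phase prunes cut generation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .cutgraph import CutCandidate, build_graph, components, weights_close
from .matrix import Clade, CladeSystem
from .subopt import CutList, enumerate_cuts, sample_cuts
from .tree import RootedTree, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "PartialSolution",
    "Beam",
    "init_partial_solutions",
    "expand",
    "step",
    "run",
    "finalize",
]

Block = tuple[frozenset[str], tuple[Clade, ...]]
# partial trees are nested structures: a leaf is a frozenset of taxa, an
# internal node a tuple of children
PartialTree = object


def _tree_key(tree: PartialTree) -> tuple:
    """Canonical hashable encoding of a partial tree (child order ignored)."""
    if isinstance(tree, frozenset):
        return ("L", tuple(sorted(tree)))
    return ("N",) + tuple(sorted(_tree_key(c) for c in tree))


@dataclass(frozen=True)
class PartialSolution:
    blocks: tuple[Block, ...]
    tree: PartialTree
    cost: float

    @property
    def order(self) -> int:
        return len(self.blocks)

    @property
    def partition_key(self) -> tuple[tuple[str, ...], ...]:
        return tuple(sorted(tuple(sorted(S)) for S, _ in self.blocks))

    @property
    def merge_key(self) -> tuple:
        """Solutions with equal keys are duplicates (same blocks, same
        partial tree, reached by different cut orders) and generate
        identical futures."""
        return (
            _tree_key(self.tree),
            frozenset(c.column_id for _, D in self.blocks for c in D),
        )

    def resolved(self, n_taxa: int) -> bool:
        return self.order == n_taxa


class Beam:
    """Beam state: current phase, retained solutions, and the cut cache."""

    def __init__(
        self,
        system: CladeSystem,
        k: int,
        method: str = "enum",
        seed: int = 0,
        use_cache: bool = True,
        trials: Optional[int] = None,
        preprocess: Optional[Callable[[CladeSystem], CladeSystem]] = None,
    ):
        if k < 1:
            raise ValueError("k must be >= 1")
        if method not in ("enum", "sample"):
            raise ValueError("method must be 'enum' or 'sample'")
        # optional preprocessing hook (e.g. greedy strict consensus merging);
        # the default is the identity
        if preprocess is not None:
            system = preprocess(system)
        self.system = system
        self.k = k
        self.method = method
        self.seed = seed
        self.use_cache = use_cache
        self.trials = trials
        self.phase = 1
        self._cache: dict[tuple, CutList] = {}
        root_block: Block = (
            frozenset(system.taxa),
            tuple(sorted(system.clades, key=lambda c: c.column_id)),
        )
        self.solutions: list[PartialSolution] = [
            PartialSolution((root_block,), frozenset(system.taxa), 0.0)
        ]

    # -- cut lists ----------------------------------------------------

    def cut_list(self, block: Block, bound: Optional[float]) -> CutList:
        S, D = block
        key = (S, frozenset(c.column_id for c in D))
        entry = self._cache.get(key) if self.use_cache else None
        if entry is not None and self._cache_usable(entry, bound):
            return entry
        graph = build_graph(D, S)
        comps = components(graph)
        if len(comps) > 1:
            # the block falls apart without deletions: a single free cut
            free = CutCandidate(frozenset(), 0.0, comps)
            entry = CutList((free,), "free", complete=True)
        elif self.method == "enum":
            entry = enumerate_cuts(graph, self.k, upper_bound=bound)
        else:
            entry = sample_cuts(
                graph, self.k, seed=_block_seed(self.seed, key), trials=self.trials
            )
        if self.use_cache:
            self._cache[key] = entry
        return entry

    @staticmethod
    def _cache_usable(entry: CutList, bound: Optional[float]) -> bool:
        if entry.mode in ("free", "sampled") or entry.complete:
            return True
        if entry.bound is None:  # ran unbounded: holds the k best cuts
            return True
        if bound is None:
            return False
        return bound <= entry.bound or weights_close(bound, entry.bound)


def _block_seed(master_seed: int, key: tuple) -> int:
    payload = repr((master_seed, sorted(key[0]), sorted(key[1]))).encode()
    return int.from_bytes(hashlib.blake2b(payload, digest_size=4).digest(), "big") % (
        2**31
    )


def init_partial_solutions(
    system: CladeSystem, k: int = 1, method: str = "enum", seed: int = 0, **kwargs
) -> Beam:
    """A beam holding the single order-1 solution of cost zero."""
    return Beam(system, k, method, seed, **kwargs)


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------


def _replace_leaf(tree: PartialTree, leaf: frozenset, parts: tuple) -> PartialTree:
    if isinstance(tree, frozenset):
        return parts if tree == leaf else tree
    return tuple(_replace_leaf(child, leaf, parts) for child in tree)


def expand(
    P: PartialSolution, block: Block, cut: CutCandidate
) -> PartialSolution:
    """Apply a cut to one block: q parts raise the order by q - 1."""
    if block not in P.blocks:
        raise ValueError("cut applied to a block not present in the solution")
    S, _ = block
    new_blocks = tuple(
        sorted(
            [b for b in P.blocks if b is not block and b != block]
            + [(taxa, clades) for taxa, clades in cut.parts],
            key=lambda b: min(b[0]),
        )
    )
    subtree = tuple(frozenset(taxa) for taxa, _ in cut.parts)
    new_tree = (
        subtree if P.tree == S else _replace_leaf(P.tree, S, subtree)
    )
    return PartialSolution(new_blocks, new_tree, P.cost + cut.weight)


# ---------------------------------------------------------------------------
# One phase of the beam
# ---------------------------------------------------------------------------


def step(beam: Beam) -> Beam:
    """Advance the beam by one phase.

    Solutions of order exactly the current phase are expanded through the
    cut lists of their multi-taxon blocks; solutions of higher order pass
    through unchanged and count against the beam width.
    """
    p = beam.phase
    k = beam.k
    active = [s for s in beam.solutions if s.order == p]
    passthrough = [s for s in beam.solutions if s.order > p]
    if not active:
        beam.phase += 1
        return beam

    # candidate pool: (cost, solution, block, cut); pass-throughs join as-is
    pool: list[tuple[float, PartialSolution, Optional[Block], Optional[CutCandidate]]]
    pool = [(s.cost, s, None, None) for s in passthrough]

    def kth_bound() -> Optional[float]:
        if len(pool) < k:
            return None
        costs = sorted(c for c, *_ in pool)
        return costs[k - 1]

    for sol in sorted(active, key=lambda s: (s.cost, s.partition_key)):
        for block in sol.blocks:
            if len(block[0]) < 2:
                continue
            bound = kth_bound()
            cut_bound = None if bound is None else bound - sol.cost
            if cut_bound is not None and cut_bound < 0 and not weights_close(
                sol.cost, bound
            ):
                continue  # even a free cut cannot enter the top k
            cuts = beam.cut_list(block, cut_bound)
            for cut in cuts.cuts:
                cost = sol.cost + cut.weight
                bound = kth_bound()
                if (
                    bound is not None
                    and cost > bound
                    and not weights_close(cost, bound)
                ):
                    break  # cut lists are sorted by weight
                pool.append((cost, sol, block, cut))
                if len(pool) > 6 * k:
                    pool = _prune_pool(pool, k)
    pool = _prune_pool(pool, k)

    # materialize in (cost, canonical partition) order; merge duplicates
    def sort_key(item):
        cost, sol, block, cut = item
        if cut is None:
            return (cost, sol.partition_key)
        parts = [taxa for taxa, _ in cut.parts]
        merged = [S for S, _ in sol.blocks if S != block[0]] + parts
        return (cost, tuple(sorted(tuple(sorted(S)) for S in merged)))

    pool.sort(key=sort_key)
    retained: list[PartialSolution] = []
    seen: set = set()
    for cost, sol, block, cut in pool:
        cand = sol if cut is None else expand(sol, block, cut)
        if cand.merge_key in seen:
            continue
        seen.add(cand.merge_key)
        retained.append(cand)
        if len(retained) == k:
            break
    beam.solutions = retained
    beam.phase += 1
    return beam


def _prune_pool(pool: list, k: int) -> list:
    pool.sort(key=lambda item: item[0])
    if len(pool) <= k:
        return pool
    cutoff = pool[k - 1][0]
    end = k
    while end < len(pool) and (
        pool[end][0] <= cutoff or weights_close(pool[end][0], cutoff)
    ):
        end += 1
    return pool[:end]


# ---------------------------------------------------------------------------
# Full run and finalization
# ---------------------------------------------------------------------------


def run(
    system: CladeSystem,
    k: int = 1,
    method: str = "enum",
    seed: int = 0,
    use_cache: bool = True,
    trials: Optional[int] = None,
    preprocess: Optional[Callable[[CladeSystem], CladeSystem]] = None,
) -> list[tuple[RootedTree, float]]:
    """Run the beam search to completion.

    Returns up to k supertrees with their deletion costs, ordered by
    non-decreasing cost; every returned tree spans the full taxon universe.
    """
    n = len(system.taxa)
    if n == 1:
        return [(RootedTree(TreeNode(label=system.taxa[0])), 0.0)]
    beam = Beam(system, k, method, seed, use_cache, trials, preprocess)
    while not all(s.resolved(n) for s in beam.solutions):
        step(beam)
    results = [
        (_to_tree(s.tree), s.cost)
        for s in sorted(beam.solutions, key=lambda s: (s.cost, s.partition_key))
    ]
    return results


def _to_tree(partial: PartialTree) -> RootedTree:
    def conv(node) -> TreeNode:
        if isinstance(node, frozenset):
            assert len(node) == 1
            return TreeNode(label=next(iter(node)))
        return TreeNode(children=[conv(c) for c in node])

    return RootedTree(conv(partial), validate=False).canonicalize()


def finalize(
    results: Sequence[tuple[RootedTree, float]]
) -> RootedTree:
    """Single output tree: the best-scoring tree, or the majority consensus
    of all trees tied (within tolerance) for the best score."""
    from .scoring import majority_consensus

    if not results:
        raise ValueError("finalize() requires at least one result")
    best_cost = min(cost for _, cost in results)
    tied = [
        t
        for t, cost in results
        if cost == best_cost or weights_close(cost, best_cost)
    ]
    if len(tied) == 1:
        return tied[0]
    return majority_consensus(tied)
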