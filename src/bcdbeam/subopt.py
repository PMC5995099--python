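"""Suboptimal taxon-separating vertex-cuts: exact enumeration and sampling.

Two subroutines feed the beam search with the k best (or k sampled) ways to
disconnect the taxa of a connected G(S, D).

``enumerate_cuts`` emits cuts in non-decreasing weight order.  It runs a
best-first (Vazirani-Yannakakis style) search over taxon bipartitions:
regions of the search space fix individual taxa to the source or sink side
of the cut and are solved by constrained max-flow; one shared priority queue
orders regions by their minimum cut weight, so each bipartition is reached
exactly once.  Partitions with three or more parts are produced by a lazy
"meet closure": whenever a partition is emitted, its common refinements with
previously emitted partitions are pushed with the weight of their exact
spanning clade set.  Every achievable taxon partition is the meet of its own
part-vs-rest bipartitions, each of weight no larger than the partition's,
so the combined stream emits every achievable partition at its minimum
deletion weight, in non-decreasing order, deduplicated by induced partition.

``sample_cuts`` adapts the Karger-Stein recursive contraction scheme to the
clique projection U(S, E) of G(S, D): each clade contributes a clique over
its incident taxa, an edge is drawn by first picking a clade proportional to
its weight and then an edge of its clique uniformly, and contraction
proceeds until two super-nodes remain.  Low-weight cuts are sampled with
higher probability, but no minimum-cut guarantee exists, so a flow-computed
minimum vertex-cut is always added to the output.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .cutgraph import (
    CutCandidate,
    CutGraph,
    components,
    min_vertex_cut,
    normalized_candidate,
    remove_semiuniversal,
    weights_close,
)
__all__ = ["CutList", "enumerate_cuts", "sample_cuts", "project_cut", "default_trials"]


@dataclass(frozen=True)
class CutList:
    cuts: tuple[CutCandidate, ...]
    mode: str  # "enumerated" | "sampled" | "free"
    complete: bool = False  # enumerated mode: no further cuts exist
    bound: Optional[float] = None  # upper bound the enumeration was run with


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------


def enumerate_cuts(
    graph: CutGraph, k: int, upper_bound: Optional[float] = None
) -> CutList:
    """The first k distinct taxon partitions by non-decreasing deletion weight.

    The first element is a minimum vertex-cut.  Enumeration stops early once
    the next weight would exceed ``upper_bound``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    graph = remove_semiuniversal(graph)
    if len(graph.S) < 2:
        raise ValueError("enumerate_cuts requires at least two taxa")
    if len(components(graph)) > 1:
        raise ValueError("enumerate_cuts requires a connected graph")

    def over_bound(w: float) -> bool:
        return (
            upper_bound is not None
            and w > upper_bound
            and not weights_close(w, upper_bound)
        )

    mvc = min_vertex_cut(graph)
    out: list[CutCandidate] = []
    seen: set[tuple] = set()
    if not over_bound(mvc.weight):
        out.append(mvc)
        seen.add(mvc.partition_key)
    else:
        return CutList((), "enumerated", complete=False, bound=upper_bound)

    solver = graph.solver()
    n = solver.n
    counter = itertools.count()
    # heap items: (weight, partition_key, tag, payload)
    #   tag "region": payload = (forced_src, forced_snk, side) -- a bipartition
    #   tag "meet":   payload = CutCandidate
    heap: list = []

    def push_region(forced_src: frozenset[int], forced_snk: frozenset[int]) -> None:
        side = solver.solve(forced_src, forced_snk)
        cand = normalized_candidate(graph, graph.spanning(side))
        heapq.heappush(
            heap,
            (cand.weight, cand.partition_key, next(counter), "region",
             (forced_src, forced_snk, side, cand)),
        )

    # root regions: partition bipartition space by the smallest sink-side taxon
    for i in range(1, n):
        push_region(frozenset(range(1, i)), frozenset((i,)))

    exhausted = False
    while True:
        if not heap:
            exhausted = True  # no further cuts exist
            break
        if len(out) >= k:
            break
        w, _, _, tag, payload = heapq.heappop(heap)
        if over_bound(w):
            break
        if tag == "region":
            forced_src, forced_snk, side, cand = payload
            # children: refine the region along the unassigned taxa
            side_idx = {solver.graph._tidx[t] for t in side}
            fsrc, fsnk = set(forced_src), set(forced_snk)
            for v in range(1, n):
                if v in forced_src or v in forced_snk:
                    continue
                if v in side_idx:
                    push_region(frozenset(fsrc), frozenset(fsnk | {v}))
                    fsrc.add(v)
                else:
                    push_region(frozenset(fsrc | {v}), frozenset(fsnk))
                    fsnk.add(v)
        else:
            cand = payload
        if cand.partition_key in seen:
            continue
        seen.add(cand.partition_key)
        # meet closure with everything emitted so far
        for prev in out:
            meet = _meet_candidate(graph, cand, prev)
            if meet is not None and meet.partition_key not in seen:
                if not over_bound(meet.weight):
                    heapq.heappush(
                        heap,
                        (meet.weight, meet.partition_key, next(counter), "meet", meet),
                    )
        out.append(cand)
    return CutList(tuple(out), "enumerated", complete=exhausted, bound=upper_bound)


def _meet_candidate(
    graph: CutGraph, a: CutCandidate, b: CutCandidate
) -> Optional[CutCandidate]:
    """Common refinement of two induced partitions, as an exact cut candidate."""
    side_b: dict[str, int] = {}
    for i, (taxa, _) in enumerate(b.parts):
        for t in taxa:
            side_b[t] = i
    refined: list[frozenset[str]] = []
    for taxa, _ in a.parts:
        groups: dict[int, set[str]] = {}
        for t in taxa:
            groups.setdefault(side_b[t], set()).add(t)
        refined.extend(frozenset(g) for g in groups.values())
    if len(refined) == len(a.parts) or len(refined) == len(b.parts):
        return None  # meet equals one of the inputs; nothing new
    side_of: dict[str, int] = {}
    for i, part in enumerate(refined):
        for t in part:
            side_of[t] = i
    spanning = [
        c for c in graph.D if len({side_of[t] for t in graph.members[c]}) >= 2
    ]
    return normalized_candidate(graph, spanning)


# ---------------------------------------------------------------------------
# Projection of a taxon bipartition back onto G(S, D)
# ---------------------------------------------------------------------------


def project_cut(
    bipartition: tuple[Iterable[str], Iterable[str]], graph: CutGraph
) -> CutCandidate:
    """Clades that must be deleted to realize a bipartition of S.

    The deleted set is every clade with incident taxa on both sides; the
    induced parts are recomputed from the surviving graph (and may be finer
    than the bipartition).
    """
    a, b = (frozenset(side) for side in bipartition)
    if not a or not b:
        raise ValueError("both sides of the bipartition must be non-empty")
    if a & b or (a | b) != graph.S:
        raise ValueError("bipartition must partition exactly the graph's taxa")
    return normalized_candidate(graph, graph.spanning(a))


# ---------------------------------------------------------------------------
# Randomized contraction sampling
# ---------------------------------------------------------------------------


def default_trials(n_taxa: int) -> int:
    """Default number of sampled cuts: ceil(|S|^2 * log10^2(|S|+1)).

    The |S|^2 log^2 |S| shape matches what the recursive contraction scheme
    can produce without changing its asymptotic running time; the base-10
    logarithm sets the constant factor.
    """
    return int(math.ceil(n_taxa**2 * math.log10(n_taxa + 1) ** 2))


class _ContractionState:
    """Super-node partition of S with per-clade incidence counts.

    ``counts[j, i]`` is the number of taxa of clade j inside super-node i
    (super-nodes live in fixed columns; merged columns are zeroed).  A clade
    is alive while its taxa span at least two super-nodes; dead clades get
    sampling weight zero.
    """

    __slots__ = ("graph", "members", "counts", "nnz", "weights", "nsuper")

    def __init__(self, graph: CutGraph):
        self.graph = graph
        taxa = graph.taxa_order
        n, m = len(taxa), len(graph.D)
        self.members: dict[int, list[str]] = {i: [t] for i, t in enumerate(taxa)}
        tidx = graph._tidx
        self.counts = np.zeros((m, n), dtype=np.int32)
        for j, c in enumerate(graph.D):
            for t in graph.members[c]:
                self.counts[j, tidx[t]] = 1
        self.nnz = (self.counts > 0).sum(axis=1)
        base_w = np.array([c.weight for c in graph.D])
        self.weights = np.where(self.nnz >= 2, base_w, 0.0)
        self.nsuper = n

    def copy(self) -> "_ContractionState":
        st = object.__new__(_ContractionState)
        st.graph = self.graph
        st.members = {k: list(v) for k, v in self.members.items()}
        st.counts = self.counts.copy()
        st.nnz = self.nnz.copy()
        st.weights = self.weights.copy()
        st.nsuper = self.nsuper
        return st

    def contract_step(self, rng: np.random.Generator) -> None:
        # 1) pick a clade (edge color) proportional to its weight
        cum = np.cumsum(self.weights)
        total = cum[-1]
        if total <= 0:
            # alive clades all have zero weight: choose uniformly among them
            alive = np.flatnonzero(self.nnz >= 2)
            j = int(alive[rng.integers(len(alive))])
        else:
            j = int(np.searchsorted(cum, rng.random() * total, side="right"))
            j = min(j, len(self.weights) - 1)
        # 2) draw a non-loop clique edge of E(c) uniformly: a super-node pair
        #    (a, b) with probability proportional to count_a * count_b
        row = self.counts[j]
        sids = np.flatnonzero(row).tolist()
        if len(sids) == 2:
            self.merge(sids[0], sids[1])
            return
        g = [int(row[i]) for i in sids]
        pairs = [
            (g[ai] * g[bi], sids[ai], sids[bi])
            for ai in range(len(sids))
            for bi in range(ai + 1, len(sids))
        ]
        total_pairs = sum(p for p, _, _ in pairs)
        x = rng.random() * total_pairs
        acc = 0.0
        for p, a, bnode in pairs:
            acc += p
            if acc > x:
                self.merge(a, bnode)
                return
        self.merge(pairs[-1][1], pairs[-1][2])

    def merge(self, a: int, b: int) -> None:
        if len(self.members[a]) < len(self.members[b]):
            a, b = b, a
        self.members[a].extend(self.members.pop(b))
        colb = self.counts[:, b]
        hit = colb > 0
        both = hit & (self.counts[:, a] > 0)
        self.counts[:, a] += colb
        self.counts[:, b] = 0
        self.nnz[both] -= 1
        self.nnz[hit & ~both] += 0  # column moved, span unchanged
        dead = both & (self.nnz < 2)
        self.weights[dead] = 0.0
        self.nsuper -= 1

    def bipartition(self) -> tuple[frozenset[str], frozenset[str]]:
        (ma, mb) = self.members.values()
        return frozenset(ma), frozenset(mb)


def sample_partitions(
    graph: CutGraph, n_cuts: int, rng: np.random.Generator
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Raw bipartitions from the recursive contraction scheme (with repeats)."""
    out: list[tuple[frozenset[str], frozenset[str]]] = []
    base = _ContractionState(graph)

    def recurse(state: _ContractionState) -> None:
        if len(out) >= n_cuts:
            return
        if state.nsuper == 2:
            out.append(state.bipartition())
            return
        target = max(2, math.ceil(1 + state.nsuper / math.sqrt(2)))
        if target >= state.nsuper:
            target = state.nsuper - 1
        for branch in range(2):
            st = state.copy() if branch == 0 else state
            while st.nsuper > target:
                st.contract_step(rng)
            recurse(st)
            if len(out) >= n_cuts:
                return

    while len(out) < n_cuts:
        recurse(base.copy())
    return out


def sample_cuts(
    graph: CutGraph,
    k: int,
    seed: int,
    trials: Optional[int] = None,
) -> CutList:
    """k lowest-weight distinct sampled cuts, plus the flow minimum cut.

    Fully reproducible from ``seed``.  ``trials`` defaults to
    :func:`default_trials` of |S|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    graph = remove_semiuniversal(graph)
    if len(graph.S) < 2:
        raise ValueError("sample_cuts requires at least two taxa")
    if len(components(graph)) > 1:
        raise ValueError("sample_cuts requires a connected graph")
    if trials is None:
        trials = default_trials(len(graph.S))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))

    best: dict[tuple, CutCandidate] = {}
    mvc = min_vertex_cut(graph)
    best[mvc.partition_key] = mvc
    # project each distinct bipartition once (trials repeat heavily)
    distinct = {
        frozenset((a, b)): (a, b) for a, b in sample_partitions(graph, trials, rng)
    }
    for bip in distinct.values():
        cand = project_cut(bip, graph)
        prev = best.get(cand.partition_key)
        if prev is None or cand.weight < prev.weight:
            best[cand.partition_key] = cand
    ordered = sorted(best.values(), key=lambda c: (c.weight, c.partition_key))
    return CutList(tuple(ordered[:k]), "sampled")
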