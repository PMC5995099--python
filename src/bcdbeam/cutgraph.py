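"""The bipartite taxon/clade graph G(S, D) and minimum vertex-cuts.

G(S, D) joins taxon t and clade c whenever the matrix entry M[t, c] is 1.
Clades that are semiuniversal over S (no 0-entry inside S) are removed at no
cost, since their "?" entries can be resolved to 1.  Disconnecting the taxon
side of the graph by deleting clade vertices corresponds to deleting matrix
columns; the minimum-weight vertex-cut is found by max-flow in the standard
vertex-splitting network H(S, D'): every clade c becomes an arc (c-, c+) of
capacity w(c); all taxon-incident arcs have effectively infinite capacity, so
a finite cut consists of clade arcs only.

A compact Dinic solver operates on the network directly; its results are
cross-checked against an independent flow library in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .matrix import Clade, CladeSystem

__all__ = [
    "CutGraph",
    "CutCandidate",
    "build_graph",
    "remove_semiuniversal",
    "components",
    "min_vertex_cut",
]

REL_TOL = 1e-9
_EPS = 1e-12


def weights_close(a: float, b: float, rel_tol: float = REL_TOL) -> bool:
    return abs(a - b) <= rel_tol * max(1.0, abs(a), abs(b))


# ---------------------------------------------------------------------------
# Graph model
# ---------------------------------------------------------------------------


class CutGraph:
    """G(S, D) restricted to S, with per-clade incident taxon sets."""

    __slots__ = ("S", "D", "members", "taxa_order", "_tidx", "_solver", "normalized")

    def __init__(self, S: frozenset[str], D: Sequence[Clade], normalized: bool = False):
        self.S = S
        # drop clades with no incident taxon in S (isolated vertices)
        kept: list[Clade] = []
        members: dict[Clade, frozenset[str]] = {}
        for c in D:
            inc = c.ones & S
            if inc:
                kept.append(c)
                members[c] = inc
        self.D: tuple[Clade, ...] = tuple(sorted(kept, key=lambda c: c.column_id))
        self.members = members
        self.taxa_order: tuple[str, ...] = tuple(sorted(S))
        self._tidx = {t: i for i, t in enumerate(self.taxa_order)}
        self._solver: Optional[_Dinic] = None
        self.normalized = normalized

    @property
    def total_weight(self) -> float:
        return sum(c.weight for c in self.D)

    def spanning(self, side: frozenset[str]) -> tuple[Clade, ...]:
        """Clades with incident taxa both inside and outside ``side``."""
        return tuple(
            c
            for c in self.D
            if (self.members[c] & side) and (self.members[c] - side)
        )

    def solver(self) -> "_Dinic":
        if self._solver is None:
            self._solver = _Dinic(self)
        return self._solver

    def __repr__(self) -> str:  # pragma: no cover
        return f"CutGraph(|S|={len(self.S)}, |D|={len(self.D)})"


def build_graph(
    system_or_clades: CladeSystem | Sequence[Clade],
    S: Iterable[str],
    D: Optional[Sequence[Clade]] = None,
) -> CutGraph:
    """Build G(S, D) and apply semiuniversal removal."""
    if isinstance(system_or_clades, CladeSystem):
        clades = system_or_clades.clades if D is None else D
    else:
        clades = system_or_clades if D is None else D
    return remove_semiuniversal(CutGraph(frozenset(S), tuple(clades)))


def remove_semiuniversal(graph: CutGraph) -> CutGraph:
    """Remove all clades with entries in {1, ?} over all of S; idempotent."""
    if graph.normalized:
        return graph
    S = graph.S
    kept = [c for c in graph.D if c.zeros & S]
    if len(kept) == len(graph.D):
        graph.normalized = True
        return graph
    return CutGraph(S, kept, normalized=True)


def components(
    graph: CutGraph, deleted: frozenset[Clade] = frozenset()
) -> tuple[tuple[frozenset[str], tuple[Clade, ...]], ...]:
    """Connected components of G(S, D \\ deleted), ordered by smallest taxon.

    Taxa with no incident surviving clade form singleton components; each
    surviving clade is listed with the component containing its taxa.
    """
    parent: dict[str, str] = {t: t for t in graph.S}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    survivors = [c for c in graph.D if c not in deleted]
    for c in survivors:
        it = iter(graph.members[c])
        r = find(next(it))
        for t in it:
            parent[find(t)] = r
    taxa_parts: dict[str, set[str]] = {}
    for t in graph.S:
        taxa_parts.setdefault(find(t), set()).add(t)
    clade_parts: dict[str, list[Clade]] = {r: [] for r in taxa_parts}
    for c in survivors:
        clade_parts[find(next(iter(graph.members[c])))].append(c)
    out = []
    for r, taxa in taxa_parts.items():
        out.append((frozenset(taxa), tuple(clade_parts[r])))
    out.sort(key=lambda p: min(p[0]))
    return tuple(out)


# ---------------------------------------------------------------------------
# Cut candidates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutCandidate:
    """A set of deleted clades with its weight and the induced partition of S."""

    deleted: frozenset[Clade]
    weight: float
    parts: tuple[tuple[frozenset[str], tuple[Clade, ...]], ...]

    @property
    def partition_key(self) -> tuple[tuple[str, ...], ...]:
        """Canonical encoding of the induced taxon partition."""
        return tuple(sorted(tuple(sorted(p)) for p, _ in self.parts))

    @property
    def order_increase(self) -> int:
        return len(self.parts) - 1


def make_candidate(graph: CutGraph, deleted: Iterable[Clade]) -> CutCandidate:
    dset = frozenset(deleted)
    return CutCandidate(
        deleted=dset,
        weight=sum(c.weight for c in sorted(dset, key=lambda c: c.column_id)),
        parts=components(graph, dset),
    )


def normalized_candidate(graph: CutGraph, deleted: Iterable[Clade]) -> CutCandidate:
    """Reduce a deletion set to the exact spanning set of its induced partition.

    Deleting U may split S into parts that some members of U do not actually
    separate; the spanning set of the induced partition is the unique minimal
    deletion set inducing it (for positive weights), and re-deleting it
    induces the same partition.
    """
    parts = components(graph, frozenset(deleted))
    side_of: dict[str, int] = {}
    for i, (taxa, _) in enumerate(parts):
        for t in taxa:
            side_of[t] = i
    exact = [
        c for c in graph.D if len({side_of[t] for t in graph.members[c]}) >= 2
    ]
    return CutCandidate(
        deleted=frozenset(exact),
        weight=sum(c.weight for c in exact),
        parts=parts,
    )


# ---------------------------------------------------------------------------
# Dinic max-flow on H(S, D')
# ---------------------------------------------------------------------------


class _Dinic:
    """Max-flow solver on H(S, D') with switchable side-constraint arcs.

    Node layout: taxa 0..n-1 (in ``taxa_order``), clade i split into
    c- = n+2i and c+ = n+2i+1, plus a virtual sink T = n+2m.  The source is
    always taxon 0 (the smallest taxon of S).  Constraint arcs (s -> v) and
    (v -> T) exist for every taxon v with default capacity 0 and are raised
    to "infinity" (total clade weight + 1) to force v onto the source or
    sink side of the cut.
    """

    def __init__(self, graph: CutGraph):
        self.graph = graph
        n = len(graph.taxa_order)
        m = len(graph.D)
        self.n, self.m = n, m
        self.sink = n + 2 * m
        self.inf = graph.total_weight + 1.0
        self.adj: list[list[int]] = [[] for _ in range(self.sink + 1)]
        self.to: list[int] = []
        self.base_cap: list[float] = []

        def add(u: int, v: int, cap: float) -> int:
            i = len(self.to)
            self.to.append(v)
            self.base_cap.append(cap)
            self.adj[u].append(i)
            self.to.append(u)
            self.base_cap.append(0.0)
            self.adj[v].append(i + 1)
            return i

        tidx = graph._tidx
        self.clade_arc: list[int] = []
        for i, c in enumerate(graph.D):
            cm, cp = n + 2 * i, n + 2 * i + 1
            self.clade_arc.append(add(cm, cp, c.weight))
            for t in graph.members[c]:
                add(tidx[t], cm, self.inf)
                add(cp, tidx[t], self.inf)
        # switchable constraint arcs
        self.force_src_arc = [-1] * n
        self.force_snk_arc = [-1] * n
        for v in range(n):
            if v != 0:
                self.force_src_arc[v] = add(0, v, 0.0)
            self.force_snk_arc[v] = add(v, self.sink, 0.0)

    def solve(
        self, forced_src: Iterable[int], forced_snk: Iterable[int]
    ) -> frozenset[str]:
        """Min cut separating taxon 0 (+forced_src) from forced_snk.

        Returns the source-side taxon set of a minimum cut (residual
        reachability).  ``forced_snk`` must be non-empty.
        """
        cap = self.base_cap.copy()
        for v in forced_src:
            cap[self.force_src_arc[v]] = self.inf
        snk = list(forced_snk)
        if not snk:
            raise ValueError("no sink-side taxon given")
        for v in snk:
            cap[self.force_snk_arc[v]] = self.inf
        self._maxflow(cap)
        reach = self._reachable(cap)
        return frozenset(
            self.graph.taxa_order[v] for v in range(self.n) if reach[v]
        )

    # -- internals ----------------------------------------------------

    def _maxflow(self, cap: list[float]) -> float:
        to, adj, s, t = self.to, self.adj, 0, self.sink
        total = 0.0
        nnodes = t + 1
        while True:
            level = [-1] * nnodes
            level[s] = 0
            queue = [s]
            for u in queue:
                for ai in adj[u]:
                    v = to[ai]
                    if cap[ai] > _EPS and level[v] < 0:
                        level[v] = level[u] + 1
                        queue.append(v)
            if level[t] < 0:
                return total
            it = [0] * nnodes
            # iterative blocking flow
            path: list[int] = []
            u = s
            while True:
                if u == t:
                    f = min(cap[ai] for ai in path)
                    for ai in path:
                        cap[ai] -= f
                        cap[ai ^ 1] += f
                    total += f
                    path = []
                    u = s
                    continue
                advanced = False
                while it[u] < len(adj[u]):
                    ai = adj[u][it[u]]
                    v = to[ai]
                    if cap[ai] > _EPS and level[v] == level[u] + 1:
                        path.append(ai)
                        u = v
                        advanced = True
                        break
                    it[u] += 1
                if not advanced:
                    if u == s:
                        break  # blocking flow complete for this level graph
                    level[u] = -1  # dead end; prune
                    ai = path.pop()
                    u = to[ai ^ 1]
                    it[u] += 1

    def _reachable(self, cap: list[float]) -> list[bool]:
        reach = [False] * (self.sink + 1)
        reach[0] = True
        queue = [0]
        for u in queue:
            for ai in self.adj[u]:
                v = self.to[ai]
                if cap[ai] > _EPS and not reach[v]:
                    reach[v] = True
                    queue.append(v)
        return reach


# ---------------------------------------------------------------------------
# Minimum vertex-cut
# ---------------------------------------------------------------------------


def min_vertex_cut(graph: CutGraph) -> CutCandidate:
    """Minimum-weight vertex-cut of a connected G(S, D).

    Fixes s = smallest taxon and minimizes over min s-t cuts for the
    remaining taxa; ties are broken by the lexicographically smallest
    canonical encoding of the induced taxon partition.
    """
    graph = remove_semiuniversal(graph)
    if len(graph.S) < 2:
        raise ValueError("min_vertex_cut requires at least two taxa")
    comps = components(graph)
    if len(comps) > 1:
        raise ValueError("min_vertex_cut requires a connected graph; split into components first")
    solver = graph.solver()
    best: Optional[CutCandidate] = None
    for t in range(1, solver.n):
        side = solver.solve((), (t,))
        cand = normalized_candidate(graph, graph.spanning(side))
        if (
            best is None
            or (cand.weight < best.weight and not weights_close(cand.weight, best.weight))
            or (weights_close(cand.weight, best.weight) and cand.partition_key < best.partition_key)
        ):
            best = cand
    assert best is not None
    return best
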