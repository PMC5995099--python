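"""Independent greedy Bad Clade Deletion reference implementation.

Coded against networkx max-flow, sharing no graph or flow machinery with the
package's own engine, so that the beam search with k=1 can be checked against
it.  The same tie-breaking conventions are used (source = smallest taxon;
equal-weight cuts resolved by the lexicographically smallest canonical
encoding of the induced taxon partition) so that not only costs but also
topologies must agree.
"""

from __future__ import annotations

import networkx as nx


def _components(S, D, members):
    """Connected components of the taxon/clade incidence, via networkx."""
    g = nx.Graph()
    g.add_nodes_from(S)
    for c in D:
        ts = list(members[c])
        for t in ts[1:]:
            g.add_edge(ts[0], t)
    comps = []
    for taxa in nx.connected_components(g):
        taxa = frozenset(taxa)
        comps.append((taxa, [c for c in D if members[c] <= taxa]))
    comps.sort(key=lambda p: min(p[0]))
    return comps


def _partition_key(S, D, members, deleted):
    survivors = [c for c in D if c not in deleted]
    comps = _components(S, survivors, members)
    return tuple(sorted(tuple(sorted(p)) for p, _ in comps))


def _min_cut(S, D, members):
    """Minimum vertex-cut by networkx max-flow over all sink choices.

    The representative cut for each terminal is the canonical one used
    throughout: the minimal source side, i.e. the set of vertices reachable
    from s in the residual network (identical for every maximum flow).
    """
    H = nx.DiGraph()
    inf = sum(c.weight for c in D) + 1.0
    for c in D:
        H.add_edge(("-", c.column_id), ("+", c.column_id), capacity=c.weight)
        for t in members[c]:
            H.add_edge(t, ("-", c.column_id), capacity=inf)
            H.add_edge(("+", c.column_id), t, capacity=inf)
    s = min(S)
    best = None
    for t in sorted(S - {s}):
        R = nx.algorithms.flow.edmonds_karp(H, s, t)
        # residual reachability from s
        side = set()
        stack = [s]
        while stack:
            u = stack.pop()
            if u in side:
                continue
            side.add(u)
            for v, attr in R[u].items():
                if attr["capacity"] - attr["flow"] > 1e-12 and v not in side:
                    stack.append(v)
        side = frozenset(x for x in side if isinstance(x, str))
        deleted = frozenset(
            c for c in D if (members[c] & side) and (members[c] - side)
        )
        weight = sum(c.weight for c in deleted)
        key = _partition_key(S, D, members, deleted)
        item = (weight, key, deleted)
        if best is None or item[:2] < best[:2]:
            best = item
    return best


def greedy_bcd(system):
    """Greedy BCD: returns (nested tuple topology, total deletion cost).

    Leaves of the nested structure are taxon labels; internal nodes are
    tuples of children.
    """

    def solve(S, D):
        if len(S) == 1:
            return next(iter(S)), 0.0
        members = {c: c.ones & S for c in D}
        live = [c for c in D if members[c] and (c.zeros & S)]  # semiuniversal out
        comps = _components(S, live, members)
        if len(comps) > 1:
            children, cost = [], 0.0
            for taxa, clades in comps:
                sub, c = solve(taxa, clades)
                children.append(sub)
                cost += c
            return tuple(children), cost
        weight, _, deleted = _min_cut(S, live, members)
        survivors = [c for c in live if c not in deleted]
        children, cost = [], weight
        for taxa, clades in _components(S, survivors, members):
            sub, c = solve(taxa, clades)
            children.append(sub)
            cost += c
        return tuple(children), cost

    return solve(frozenset(system.taxa), list(system.clades))
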