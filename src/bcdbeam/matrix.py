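"""Matrix representation of a tree collection: weighted clades over {0, 1, ?}.

Every non-trivial clade of every input tree becomes one column.  A column
scores "1" for taxa inside the clade, "0" for the other taxa of the clade's
source tree, and "?" for taxa the source tree does not contain.  A collection
of trees has a parent tree exactly when this incomplete matrix admits a
directed perfect phylogeny, which holds iff a compatible completion of the
columns exists; the deletion objective optimized downstream removes a
minimum-weight set of columns to reach that state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .tree import RootedTree
from .weights import assign_weights

logger = logging.getLogger(__name__)

__all__ = ["Clade", "CladeSystem", "encode", "compatible", "conflict_fraction"]


@dataclass(frozen=True)
class Clade:
    """One matrix column.

    ``ones`` are the taxa scored 1; taxa in ``source_taxa - ones`` are scored
    0; all other taxa are "?".  ``column_id`` is unique within a system.
    """

    ones: frozenset[str]
    source_taxa: frozenset[str]
    weight: float
    source_id: int
    column_id: int

    def __post_init__(self):
        if not (2 <= len(self.ones) < len(self.source_taxa)):
            raise ValueError("clade must satisfy 2 <= |ones| < |source taxa|")
        if not self.ones <= self.source_taxa:
            raise ValueError("clade ones-set must lie inside its source taxa")
        if self.weight < 0:
            raise ValueError("clade weight must be non-negative")

    @property
    def zeros(self) -> frozenset[str]:
        return self.source_taxa - self.ones

    def entry(self, taxon: str) -> str:
        if taxon in self.ones:
            return "1"
        if taxon in self.source_taxa:
            return "0"
        return "?"

    def __hash__(self) -> int:
        return hash(self.column_id)

    def __eq__(self, other) -> bool:
        return isinstance(other, Clade) and self.column_id == other.column_id


@dataclass
class CladeSystem:
    """The full matrix M over {0,1,?}: taxon universe plus weighted columns."""

    taxa: tuple[str, ...]
    clades: list[Clade]
    by_taxon: dict[str, list[Clade]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.by_taxon:
            self.by_taxon = {t: [] for t in self.taxa}
            for c in self.clades:
                for t in c.ones:
                    self.by_taxon[t].append(c)

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def m(self) -> int:
        return len(self.clades)

    def dump(self) -> str:
        """Tab-separated debug view of the matrix (rows = taxa)."""
        lines = ["\t" + "\t".join(f"c{c.column_id}" for c in self.clades)]
        for t in self.taxa:
            lines.append(t + "\t" + "\t".join(c.entry(t) for c in self.clades))
        return "\n".join(lines)


def encode(
    trees: Sequence[RootedTree],
    weighting: str = "unit",
    missing_policy: float = 1.0,
) -> CladeSystem:
    """Encode input trees as a :class:`CladeSystem`.

    ``weighting`` is one of ``unit``, ``bootstrap``, ``branch_length`` (see
    :func:`bcdbeam.weights.assign_weights`).  Trees with fewer than two taxa
    contribute no clades and are skipped with a warning.
    """
    if not trees:
        raise ValueError("encode() requires at least one input tree")
    usable = []
    for i, t in enumerate(trees):
        if len(t) < 2:
            logger.warning("input tree %d has fewer than two taxa; skipped", i)
        else:
            usable.append((i, t))
    if not usable:
        raise ValueError("no input tree with at least two taxa")

    taxa = sorted(set().union(*(t.taxa for _, t in usable)))
    weight_maps = assign_weights(
        [t for _, t in usable], scheme=weighting, missing_policy=missing_policy
    )
    clades: list[Clade] = []
    col = 0
    for (i, t), wmap in zip(usable, weight_maps):
        source = t.taxa
        for ones in sorted(t.clades(), key=lambda s: (len(s), sorted(s))):
            if len(ones) < 2 or len(ones) >= len(source):
                continue  # trivial columns carry no information
            col += 1
            clades.append(Clade(ones, source, wmap[ones], i, col))
    return CladeSystem(tuple(taxa), clades)


def compatible(a: Clade, b: Clade) -> bool:
    """Pairwise column compatibility over {0, 1, ?}.

    Two partial columns conflict exactly when the patterns (1,1), (1,0) and
    (0,1) all occur on taxa where both entries are known; "?" entries are
    unconstrained.  For complete columns this reduces to the classical rule:
    the ones-sets are nested or disjoint.
    """
    A, B = a.ones, b.ones
    return not (A & B) or not (A & b.zeros) or not (a.zeros & B)


def conflict_fraction(system: CladeSystem) -> float:
    """Fraction of clades that conflict with at least one other clade."""
    if not system.clades:
        return 0.0
    conflicted = [False] * len(system.clades)
    cl = system.clades
    for i in range(len(cl)):
        for j in range(i + 1, len(cl)):
            if not compatible(cl[i], cl[j]):
                conflicted[i] = conflicted[j] = True
    return sum(conflicted) / len(cl)
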