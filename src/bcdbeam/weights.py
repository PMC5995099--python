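"""Clade weighting schemes: unit, bootstrap support, branch length.

The deletion objective sums the weights of removed columns, so weights encode
how much a clade's removal should cost.  Unit weights treat all clades alike;
bootstrap weights use the support value attached to the clade's node; branch
length weights use the length of the clade's incoming edge (a long edge means
a well separated, presumably reliable clade).  The exact transformation from
support/length to weight is pluggable via ``transform``; the default is the
identity, i.e. the plain support value or edge length.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

from .tree import RootedTree, TreeNode

logger = logging.getLogger(__name__)

__all__ = ["assign_weights", "SCHEMES"]

SCHEMES = ("unit", "bootstrap", "branch_length")


def assign_weights(
    trees: Sequence[RootedTree],
    scheme: str = "unit",
    missing_policy: float = 1.0,
    transform: Optional[Callable[[float], float]] = None,
) -> list[dict[frozenset[str], float]]:
    """Per-tree mapping from clade (ones-set) to weight w(c).

    ``missing_policy`` is the weight used where a support value or branch
    length is absent under the bootstrap / branch_length schemes (default 1.0,
    i.e. fall back to a unit weight, with a logged warning).

    Raises ``ValueError`` if ``scheme='bootstrap'`` and no tree carries any
    support value (advice: use unit weights), and correspondingly for
    ``branch_length`` with no branch lengths.
    """
    scheme = scheme.replace("-", "_")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; choose from {SCHEMES}")
    tf = transform if transform is not None else (lambda x: x)

    if scheme == "bootstrap":
        if not any(
            n.support is not None for t in trees for n in t.iter_nodes() if not n.is_leaf
        ):
            raise ValueError(
                "bootstrap weighting requested but no support values are present; "
                "use unit weights instead"
            )
    if scheme == "branch_length":
        if not any(n.length is not None for t in trees for n in t.iter_nodes()):
            raise ValueError(
                "branch_length weighting requested but no branch lengths are present; "
                "use unit weights instead"
            )

    out: list[dict[frozenset[str], float]] = []
    for t in trees:
        wmap: dict[frozenset[str], float] = {}

        def walk(node: TreeNode, is_root: bool) -> frozenset[str]:
            if node.is_leaf:
                return frozenset((node.label,))
            below = frozenset().union(*(walk(c, False) for c in node.children))
            if not is_root:
                if scheme == "unit":
                    w = 1.0
                elif scheme == "bootstrap":
                    if node.support is None:
                        logger.warning(
                            "clade without support value; using missing_policy=%g",
                            missing_policy,
                        )
                        w = missing_policy
                    else:
                        w = tf(float(node.support))
                else:  # branch_length
                    if node.length is None:
                        logger.warning(
                            "clade without branch length; using missing_policy=%g",
                            missing_policy,
                        )
                        w = missing_policy
                    else:
                        w = tf(float(node.length))
                if w < 0:
                    raise ValueError(f"negative clade weight {w}")
                wmap[below] = w
            return below

        walk(t.root, True)
        out.append(wmap)
    return out
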