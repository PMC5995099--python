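"""Supertree quality metrics and majority-rule consensus.

All metrics operate on non-trivial unrooted splits (both sides with at least
two taxa), even though the trees themselves are rooted — the common practice
for supertree evaluation.  Against a known model tree the split F1 score is
reported; against the source trees themselves the summed false negative
(SFN) and summed false positive (SFP) split rates of the supertree's
restrictions are reported.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .tree import RootedTree, TreeNode, restrict

__all__ = ["SplitConfusion", "split_confusion", "f1_score", "sfn_sfp", "majority_consensus"]


@dataclass(frozen=True)
class SplitConfusion:
    tp: int
    fp: int
    fn: int


def split_confusion(estimate: RootedTree, model: RootedTree) -> SplitConfusion:
    if estimate.taxa != model.taxa:
        raise ValueError("split comparison requires identical leaf sets")
    se, sm = estimate.splits(), model.splits()
    return SplitConfusion(tp=len(se & sm), fp=len(se - sm), fn=len(sm - se))


def f1_score(supertree: RootedTree, model: RootedTree) -> float:
    """F1 = 2TP / (2TP + FP + FN) over non-trivial unrooted splits.

    Two trees with no non-trivial splits at all are identical star trees and
    score 1.0.
    """
    c = split_confusion(supertree, model)
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def sfn_sfp(
    supertree: RootedTree, sources: Sequence[RootedTree]
) -> tuple[float, float]:
    """Summed false negative / false positive split rates vs the sources.

    SFN rate = sum over sources T of |S(T) - S(T'|L(T))| divided by the total
    number of source splits; SFP rate = sum of |S(T'|L(T)) - S(T)| divided by
    the total number of splits of the restricted supertree.
    """
    missing = set().union(*(t.taxa for t in sources)) - supertree.taxa
    if missing:
        raise ValueError(f"source taxa absent from the supertree: {sorted(missing)}")
    fn = fp = n_src = n_rest = 0
    for t in sources:
        rt = restrict(supertree, t.taxa)
        ss, sr = t.splits(), rt.splits()
        fn += len(ss - sr)
        fp += len(sr - ss)
        n_src += len(ss)
        n_rest += len(sr)
    sfn = fn / n_src if n_src else 0.0
    sfp = fp / n_rest if n_rest else 0.0
    return sfn, sfp


def majority_consensus(trees: Sequence[RootedTree]) -> RootedTree:
    """Rooted majority-rule consensus: clades in strictly more than half of
    the input trees (such clades are always pairwise compatible)."""
    if not trees:
        raise ValueError("majority_consensus requires at least one tree")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("majority_consensus requires identical leaf sets")
    counts = Counter(c for t in trees for c in t.clades())
    majority = [c for c, n in counts.items() if 2 * n > len(trees)]

    def build(node_taxa: frozenset[str], clades: list[frozenset[str]]) -> TreeNode:
        inner = [c for c in clades if c < node_taxa]
        maximal = [c for c in inner if not any(c < d for d in inner)]
        node = TreeNode()
        covered: set[str] = set()
        for m in sorted(maximal, key=sorted):
            node.children.append(build(m, [c for c in inner if c < m]))
            covered |= m
        for t in sorted(node_taxa - covered):
            node.children.append(TreeNode(label=t))
        return node

    return RootedTree(build(taxa, majority), validate=False).canonicalize()
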