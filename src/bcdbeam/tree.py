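"""Rooted phylogenetic trees: Newick I/O, restriction, refinement, clades and splits.

The tree model is deliberately small: nodes carry children, an optional leaf
label (the taxon), an optional branch length on the incoming edge, and an
optional support value on internal nodes.  Invariants maintained throughout:
no node has out-degree one (such nodes are contracted, summing branch
lengths), every leaf is labeled, and no taxon label occurs twice in a tree.

Newick parsing is delegated to dendropy; writing is done here so that output
is canonical: children are ordered by their lexicographically smallest
descendant taxon, which makes all downstream tie-breaking reproducible.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "RootedTree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "restrict",
    "refines",
    "clades_of",
    "splits_of",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input (message names the position)."""


class TreeNode:
    __slots__ = ("children", "label", "length", "support")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
        children: Optional[list["TreeNode"]] = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, children={len(self.children)})"


class RootedTree:
    """A rooted phylogenetic tree with labeled leaves.

    Construct from a root :class:`TreeNode`, from a Newick string via
    :func:`parse_newick`, or from a nested structure of labels via
    :meth:`from_structure`.
    """

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_structure(cls, obj) -> "RootedTree":
        """Build a tree from nested tuples/lists of taxon labels.

        ``("a", ("b", "c"))`` gives the tree ``(a,(b,c));``.
        """

        def build(o) -> TreeNode:
            if isinstance(o, (tuple, list)):
                return TreeNode(children=[build(c) for c in o])
            return TreeNode(label=str(o))

        return cls(build(obj))

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.iter_nodes():
            if node.is_leaf:
                if node.label is None:
                    raise ValueError("unlabeled leaf node")
                if node.label in seen:
                    raise ValueError(f"duplicate taxon label {node.label!r}")
                seen.add(node.label)
            elif len(node.children) == 1 and node is not self.root:
                raise ValueError("internal node of out-degree one")
        # a root with a single child is contracted rather than rejected
        while len(self.root.children) == 1:
            child = self.root.children[0]
            child.length = None
            self.root = child

    # -- traversal ----------------------------------------------------

    def iter_nodes(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def iter_leaves(self) -> Iterator[TreeNode]:
        for node in self.iter_nodes():
            if node.is_leaf:
                yield node

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(leaf.label for leaf in self.iter_leaves())

    def __len__(self) -> int:
        return sum(1 for _ in self.iter_leaves())

    # -- copying ------------------------------------------------------

    def copy(self) -> "RootedTree":
        def cp(node: TreeNode) -> TreeNode:
            return TreeNode(
                node.label, node.length, node.support, [cp(c) for c in node.children]
            )

        return RootedTree(cp(self.root), validate=False)

    # -- clades and splits --------------------------------------------

    def clades(self) -> set[frozenset[str]]:
        """Taxon sets below each non-root internal node."""
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset((node.label,))
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root:
                out.add(below)
            return below

        walk(self.root)
        return out

    def splits(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial unrooted bipartitions induced by the tree's edges."""
        universe = self.taxa
        out: set[frozenset[frozenset[str]]] = set()
        for clade in self.clades():
            other = universe - clade
            if len(clade) >= 2 and len(other) >= 2:
                out.add(frozenset((clade, other)))
        return out

    # -- canonical form -----------------------------------------------

    def canonicalize(self) -> "RootedTree":
        """Sort children in place by smallest descendant taxon; returns self."""

        def walk(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            keys = [(walk(c), c) for c in node.children]
            keys.sort(key=lambda kc: kc[0])
            node.children = [c for _, c in keys]
            return keys[0][0]

        walk(self.root)
        return self

    def newick(self, lengths: bool = True, supports: bool = True) -> str:
        self.canonicalize()
        buf = io.StringIO()

        def fmt(x: float) -> str:
            return f"{x:g}"

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                buf.write(_quote(node.label))
            else:
                buf.write("(")
                for i, c in enumerate(node.children):
                    if i:
                        buf.write(",")
                    walk(c)
                buf.write(")")
                if supports and node.support is not None:
                    buf.write(fmt(node.support))
            if lengths and node.length is not None:
                buf.write(":" + fmt(node.length))

        walk(self.root)
        buf.write(";")
        return buf.getvalue()

    def topology_id(self) -> str:
        """Canonical topology-only Newick string (no lengths, no supports)."""
        return self.copy().newick(lengths=False, supports=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({len(self)} taxa)"


_NEEDS_QUOTE = set("()[]{}/\\,;:=*'\"`+<> ")


def _quote(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> list[RootedTree]:
    """Parse one or more semicolon-terminated Newick trees.

    Internal-node labels that parse as numbers are interpreted as support
    values; ``:x`` tokens as branch lengths; comments in ``[...]`` are
    skipped; quoted labels are supported.  Nodes of out-degree one are
    contracted on load (branch lengths summed).
    """
    if not text or ";" not in text:
        raise NewickParseError("no semicolon-terminated Newick tree found in input")
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise NewickParseError(f"malformed Newick input: {exc}") from None
    if not tree_list:
        raise NewickParseError("no trees found in input")
    return [_from_dendropy(t) for t in tree_list]


def _from_dendropy(dtree: "dendropy.Tree") -> RootedTree:
    def conv(dnode) -> TreeNode:
        children = [conv(c) for c in dnode.child_nodes()]
        # contract out-degree-one chains, summing branch lengths
        while len(children) == 1:
            only = children[0]
            lengths = [x for x in (dnode.edge.length, only.length) if x is not None]
            only.length = sum(lengths) if lengths else None
            return only
        if children:
            node = TreeNode(children=children)
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is not None:
                try:
                    node.support = float(label)
                except (TypeError, ValueError):
                    pass  # non-numeric internal labels are not supports
        else:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise ValueError("unlabeled leaf in Newick input")
            node = TreeNode(label=str(label))
        node.length = dnode.edge.length if node.length is None else node.length
        return node

    root = conv(dtree.seed_node)
    root.length = None
    # duplicate-taxon validation happens in the RootedTree constructor
    return RootedTree(root)


def write_newick(trees: Iterable[RootedTree] | RootedTree) -> str:
    """Serialize trees to canonical Newick, one per line."""
    if isinstance(trees, RootedTree):
        trees = [trees]
    return "\n".join(t.newick() for t in trees) + "\n"


# ---------------------------------------------------------------------------
# Restriction, refinement
# ---------------------------------------------------------------------------


def restrict(tree: RootedTree, taxa: Iterable[str]) -> RootedTree:
    """The minimal induced subtree of ``tree`` connecting ``taxa``.

    Out-degree-one nodes created by the pruning are contracted; the branch
    lengths of contracted edges are summed.  The result's root is the MRCA
    of ``taxa``.
    """
    want = frozenset(taxa)
    missing = want - tree.taxa
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if not want:
        raise ValueError("restriction to an empty taxon set")

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if node.label in want:
                return TreeNode(node.label, node.length, node.support)
            return None
        kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            only = kept[0]
            lengths = [x for x in (node.length, only.length) if x is not None]
            only.length = sum(lengths) if lengths else None
            return only
        return TreeNode(None, node.length, node.support, kept)

    root = prune(tree.root)
    assert root is not None
    if root.is_leaf:
        root = TreeNode(root.label)  # single-taxon restriction: drop edge length
    else:
        root.length = None
    return RootedTree(root, validate=False)


def refines(tree: RootedTree, other: RootedTree) -> bool:
    """True iff ``other`` can be reached from ``tree`` by contracting internal edges.

    Equivalently: every non-trivial clade of ``other`` is a clade of ``tree``.
    Both trees must be on the same leaf set.
    """
    if tree.taxa != other.taxa:
        raise ValueError("refines() requires identical leaf sets")
    return other.clades() <= tree.clades()


def clades_of(tree: RootedTree) -> set[frozenset[str]]:
    return tree.clades()


def splits_of(tree: RootedTree) -> set[frozenset[frozenset[str]]]:
    return tree.splits()
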