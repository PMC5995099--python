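"""Seeded synthetic model trees and source-tree collections.

The generator emulates the structure of the clade-based supertree benchmark
data: a random binary model tree; several clade-based source trees, each a
densely sampled restriction of one clade of the model; and one scaffold
source tree sampling a fixed fraction of all taxa (the scaffold factor).
Optional per-tree taxa deletion and random NNI edits introduce missing data
and topological conflict; with zero NNI edits the collection is compatible
by construction (restrictions of a single model tree).

Everything is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .tree import RootedTree, TreeNode, restrict

__all__ = ["FixtureConfig", "simulate_model_tree", "sample_source_trees"]

SCAFFOLD_FACTORS = (0.25, 0.5, 0.75, 1.0)
DELETION_RATES = (0.0, 0.25, 0.5, 0.75)


@dataclass
class FixtureConfig:
    n_taxa: int = 32
    n_clade_trees: int = 6
    scaffold_factor: float = 1.0
    deletion_rate: float = 0.0
    conflict_nni: int = 0
    seed: int = 0
    support_model: str = "none"  # "none" | "uniform"
    dense_p: float = 0.75  # within-clade sampling density of clade-based trees
    min_clade_size: int = 4  # smallest model clade a source tree may be drawn from

    def __post_init__(self):
        if self.scaffold_factor not in SCAFFOLD_FACTORS:
            raise ValueError(f"scaffold_factor must be one of {SCAFFOLD_FACTORS}")
        if self.deletion_rate not in DELETION_RATES:
            raise ValueError(f"deletion_rate must be one of {DELETION_RATES}")
        if self.conflict_nni < 0:
            raise ValueError("conflict_nni must be non-negative")
        if self.support_model not in ("none", "uniform"):
            raise ValueError("support_model must be 'none' or 'uniform'")
        if not 0 < self.dense_p <= 1:
            raise ValueError("dense_p must be in (0, 1]")


def simulate_model_tree(n: int, seed: int) -> RootedTree:
    """Random rooted binary model tree on n taxa.

    Topology follows a Yule process (repeatedly split a uniformly chosen
    leaf); branch lengths are exponential with mean 0.1.
    """
    if n < 3:
        raise ValueError("a model tree needs at least three taxa")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 0])))
    root = TreeNode(children=[TreeNode(), TreeNode()])
    leaves = list(root.children)
    while len(leaves) < n:
        i = int(rng.integers(len(leaves)))
        leaf = leaves[i]
        leaf.children = [TreeNode(), TreeNode()]
        leaves[i] = leaf.children[0]
        leaves.append(leaf.children[1])
    width = len(str(n))
    labels = [f"t{i + 1:0{width}d}" for i in range(n)]
    rng.shuffle(labels)
    for leaf, label in zip(leaves, labels):
        leaf.label = label
    tree = RootedTree(root)
    for node in tree.iter_nodes():
        if node is not tree.root:
            node.length = float(rng.exponential(0.1))
    return tree.canonicalize()


def _random_nni(tree: RootedTree, rng: np.random.Generator) -> None:
    """One random rooted NNI move in place: swap a child of an internal
    non-root node with that node's sibling subtree."""
    pairs = []  # (parent, internal child)
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in node.children:
            if child.children:
                pairs.append((node, child))
            stack.append(child)
    if not pairs:
        return  # no internal edge: nothing to rearrange
    parent, node = pairs[int(rng.integers(len(pairs)))]
    siblings = [c for c in parent.children if c is not node]
    sib = siblings[int(rng.integers(len(siblings)))]
    child = node.children[int(rng.integers(len(node.children)))]
    parent.children[parent.children.index(sib)] = child
    node.children[node.children.index(child)] = sib


def sample_source_trees(
    model: RootedTree, config: FixtureConfig, max_retries: int = 100
) -> list[RootedTree]:
    """Clade-based source trees plus one scaffold tree, per the config.

    Resamples (up to ``max_retries`` times) until the union of the source
    trees' leaf sets covers every model taxon.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([config.seed, 1]))
    )
    all_taxa = sorted(model.taxa)
    n = len(all_taxa)
    clades = sorted(
        (c for c in model.clades() if len(c) >= config.min_clade_size),
        key=sorted,
    )
    if not clades:
        raise ValueError("model tree has no clade large enough for source trees")

    for _ in range(max_retries):
        trees: list[RootedTree] = []
        for _ in range(config.n_clade_trees):
            clade = sorted(clades[int(rng.integers(len(clades)))])
            keep = [t for t in clade if rng.random() < config.dense_p]
            if len(keep) < 3:
                keep = list(rng.choice(clade, size=3, replace=False))
            trees.append(restrict(model, keep))
        n_scaffold = int(np.ceil(config.scaffold_factor * n))
        scaffold_taxa = sorted(
            rng.choice(all_taxa, size=max(3, n_scaffold), replace=False)
        )
        trees.append(restrict(model, scaffold_taxa))

        # per-tree taxa deletion
        if config.deletion_rate > 0:
            deleted_trees = []
            for t in trees:
                taxa = sorted(t.taxa)
                n_del = min(int(np.floor(config.deletion_rate * len(taxa))), len(taxa) - 3)
                if n_del > 0:
                    drop = set(rng.choice(taxa, size=n_del, replace=False))
                    t = restrict(t, set(taxa) - drop)
                deleted_trees.append(t)
            trees = deleted_trees

        # topological conflict via random NNI edits
        for t in trees:
            for _ in range(config.conflict_nni):
                _random_nni(t, rng)

        if config.support_model == "uniform":
            for t in trees:
                for node in t.iter_nodes():
                    if node.children and node is not t.root:
                        node.support = float(np.round(rng.uniform(50, 100), 1))

        if set().union(*(t.taxa for t in trees)) == model.taxa:
            return [t.canonicalize() for t in trees]
    raise RuntimeError(
        "could not cover all model taxa with source trees; "
        "loosen deletion/scaffold settings"
    )
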