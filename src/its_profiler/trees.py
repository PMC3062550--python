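"""Phylogenetic tree structure plus Newick serialization.

The tree is a plain rooted node structure; an unrooted tree is represented
by a root of degree three (the usual NJ convention) with ``rooted=False``.
Newick writing is done directly (so that bootstrap supports land as internal
node labels); reading is delegated to dendropy and converted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

_NEEDS_QUOTING = re.compile(r"[\s()\[\]:;,']")


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: float = 0.0
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """A tree with labeled leaves, branch lengths, optional internal supports."""

    root: TreeNode
    rooted: bool = False

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def validate(self) -> None:
        labels = self.leaf_labels()
        if any(lab is None for lab in labels):
            raise ValueError("tree has an unlabeled leaf")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")
        for node in self.root.walk():
            if node.length < 0 or not math.isfinite(node.length):
                raise ValueError(f"invalid branch length {node.length}")

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each given as the smaller-or-canonical side.

        A split is represented by the frozenset of leaf labels on one side;
        the side chosen is the one not containing the lexicographically
        smallest leaf, which is a canonical representative for unrooted
        comparison.
        """
        all_labels = frozenset(self.leaf_labels())
        anchor = min(all_labels)
        splits: set[frozenset[str]] = set()

        def collect(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(collect(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_labels) - 1:
                side = below if anchor not in below else all_labels - below
                splits.add(side)
            return below

        collect(self.root)
        return splits

    def robinson_foulds(self, other: "PhyloTree") -> int:
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            raise ValueError("trees have different leaf sets")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)


def _format_label(label: str) -> str:
    if _NEEDS_QUOTING.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _node_newick(node: TreeNode, *, is_root: bool) -> str:
    if node.is_leaf:
        if node.label is None:
            raise ValueError("leaf without a label cannot be serialized")
        s = _format_label(node.label)
    else:
        inner = ",".join(_node_newick(c, is_root=False) for c in node.children)
        tag = ""
        if node.support is not None:
            tag = _format_number(node.support)
        elif node.label is not None:
            tag = _format_label(node.label)
        s = f"({inner}){tag}"
    if not is_root:
        s += f":{_format_number(node.length)}"
    return s


def _format_number(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def tree_to_newick(tree: PhyloTree) -> str:
    return _node_newick(tree.root, is_root=True) + ";"


def write_newick(tree: PhyloTree, path: str) -> None:
    """Serialize with branch lengths and supports as internal-node labels."""
    tree.validate()
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree) + "\n")


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    node = TreeNode()
    if dnode.taxon is not None:
        node.label = dnode.taxon.label
    elif dnode.label is not None:
        node.label = dnode.label
    node.length = float(dnode.edge.length or 0.0)
    for child in dnode.child_nodes():
        node.children.append(_from_dendropy(child))
    if node.children and node.label is not None:
        # Internal labels written by this package are bootstrap supports.
        try:
            node.support = float(node.label)
            node.label = None
        except ValueError:
            pass
    return node


def newick_to_tree(newick: str, rooted: bool = False) -> PhyloTree:
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    return PhyloTree(root=_from_dendropy(dtree.seed_node), rooted=rooted)


def read_newick(path: str, rooted: bool = False) -> PhyloTree:
    with open(path) as fh:
        return newick_to_tree(fh.read(), rooted=rooted)
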