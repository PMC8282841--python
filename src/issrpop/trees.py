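"""Rooted trees from agglomerative clustering, with Newick serialization.

The clustering routines in :mod:`issrpop.distance` return :class:`Tree`
objects: rooted, binary (except for the degenerate single-leaf case), with a
height per node.  For UPGMA the heights are ultrametric (every leaf sits at
height 0 and cophenetic distances are twice the merge heights); for Ward the
height records the merge cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TreeNode", "Tree", "write_newick"]


@dataclass
class TreeNode:
    name: str | None
    height: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def cophenetic_matrix(self, labels: list[str] | None = None) -> np.ndarray:
        """Pairwise cophenetic distances (2 x merge height for ultrametric trees)."""
        labels = labels or self.leaf_names
        pos = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def visit(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [visit(c) for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for x in groups[a]:
                        for y in groups[b]:
                            d[pos[x], pos[y]] = d[pos[y], pos[x]] = 2.0 * node.height
            return [x for g in groups for x in g]

        visit(self.root)
        return d

    def cut(self, k: int) -> dict[str, int]:
        """Cut into *k* clusters by splitting the highest nodes first.

        Returns a mapping leaf name -> cluster index (0..k-1, in leaf order).
        """
        if k < 1 or k > len(self.leaf_names):
            raise ValueError("k out of range")
        groups: list[TreeNode] = [self.root]
        while len(groups) < k:
            # split the non-leaf group with the greatest height
            cands = [g for g in groups if not g.is_leaf]
            if not cands:
                break
            tallest = max(cands, key=lambda g: g.height)
            groups.remove(tallest)
            groups.extend(tallest.children)
        label: dict[str, int] = {}
        for gi, g in enumerate(sorted(groups, key=lambda g: min(l.name for l in g.leaves()))):
            for leaf in g.leaves():
                label[leaf.name] = gi
        return label


def write_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize to Newick with branch lengths (parent height - child height)."""
    if tree is None or tree.root is None:
        raise ValueError("empty tree")

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        bl = parent_height - node.height
        return f"{body}:{bl:.{precision}f}"

    return render(tree.root, None) + ";"
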