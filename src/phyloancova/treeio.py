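"""Rooted phylogenetic trees: Newick I/O, validation, and branch-length conventions.

The central type is :class:`PhyloTree`, a flat node table (id, parent,
children, branch length, tip label) with the root at index 0 and tips in
left-to-right Newick order.  Composite trees assembled from the literature
usually carry no meaningful branch lengths, so
:func:`assign_pagel_branch_lengths` implements the standard "arbitrary"
convention in which each internal node sits at a height equal to its number
of descendant tips minus one, yielding an ultrametric tree with
contemporaneous tips.

Newick parsing is delegated to dendropy; writing is a small recursive
emitter so that round-trips preserve branch lengths to full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "Node",
    "PhyloTree",
    "NewickParseError",
    "TreeStructureError",
    "parse_newick",
    "write_newick",
    "load_tree",
    "save_tree",
    "assign_pagel_branch_lengths",
    "tree_table",
    "canonical_label",
]


class NewickParseError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate or empty tip labels...)."""


class TreeStructureError(ValueError):
    """A PhyloTree violating its structural invariants."""


def canonical_label(label: str) -> str:
    """Canonical form used to match tip labels against trait-table species names.

    Matching is exact after trimming surrounding whitespace and unifying
    underscores and spaces; no fuzzy matching.
    """
    return label.strip().replace(" ", "_")


@dataclass
class Node:
    id: int
    parent: int | None
    children: list[int] = field(default_factory=list)
    length: float | None = None
    label: str | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Rooted tree as a node table; root at index ``root``, tips in Newick order."""

    nodes: list[Node]
    root: int = 0

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            # push children reversed so the leftmost child is visited first
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def postorder(self) -> list[int]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(self.nodes[nid].children)
        return order

    # -- basic queries -----------------------------------------------------

    @property
    def tips(self) -> list[int]:
        """Tip node ids in left-to-right Newick order."""
        return [nid for nid in self.preorder() if self.nodes[nid].is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [self.nodes[nid].label for nid in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths (root depth 0); missing lengths count as 0."""
        out = {self.root: 0.0}
        for nid in self.preorder():
            if nid == self.root:
                continue
            node = self.nodes[nid]
            out[nid] = out[node.parent] + (node.length or 0.0)
        return out

    @property
    def height(self) -> float:
        depths = self.depths()
        return max(depths[t] for t in self.tips)

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        depths = self.depths()
        tip_depths = [depths[t] for t in self.tips]
        hi = max(tip_depths)
        if hi == 0:
            return True
        return (hi - min(tip_depths)) <= rtol * hi

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            nodes=[Node(n.id, n.parent, list(n.children), n.length, n.label) for n in self.nodes],
            root=self.root,
        )

    def rescaled_to_unit_height(self) -> "PhyloTree":
        """Divide all branch lengths by the tree height so root-to-tip depth is 1."""
        h = self.height
        if h <= 0:
            raise TreeStructureError("tree height is zero; cannot rescale")
        out = self.copy()
        for node in out.nodes:
            if node.length is not None:
                node.length /= h
        return out

    def validate(self) -> None:
        """Raise TreeStructureError on parent/child inconsistencies or bad tips."""
        seen: set[int] = set()
        for nid in self.preorder():
            if nid in seen:
                raise TreeStructureError(f"cycle detected at node {nid}")
            seen.add(nid)
            node = self.nodes[nid]
            if nid == self.root:
                if node.parent is not None:
                    raise TreeStructureError("root node has a parent")
            elif node.parent is None:
                raise TreeStructureError(f"non-root node {nid} has no parent")
            elif nid not in self.nodes[node.parent].children:
                raise TreeStructureError(f"node {nid} missing from its parent's child list")
            if node.length is not None and node.length < 0:
                raise TreeStructureError(f"negative branch length at node {nid}")
        if len(seen) != len(self.nodes):
            raise TreeStructureError("unreachable nodes present")
        labels = self.tip_labels
        if any(not lab for lab in labels):
            raise TreeStructureError("tip without a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
            raise TreeStructureError(f"duplicate tip labels: {', '.join(dupes)}")


# -- Newick I/O -------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Polytomies are permitted and retained; branch lengths are optional.
    Raises :class:`NewickParseError` on malformed input, empty input, or
    duplicate/empty tip labels.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various error classes with positions
        raise NewickParseError(f"malformed Newick: {exc}") from None

    nodes: list[Node] = []
    index: dict[int, int] = {}
    for dnode in dtree.preorder_node_iter():
        parent = index.get(id(dnode.parent_node))
        nid = len(nodes)
        index[id(dnode)] = nid
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            label = None
        length = dnode.edge.length if parent is not None else None
        nodes.append(Node(nid, parent, [], length, label))
        if parent is not None:
            nodes[parent].children.append(nid)

    tree = PhyloTree(nodes=nodes, root=0)
    labels = tree.tip_labels
    empties = [i for i, lab in enumerate(labels) if not lab]
    if empties:
        raise NewickParseError(f"tip(s) without a label at tip position(s) {empties}")
    if len(set(labels)) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise NewickParseError(f"duplicate tip labels: {', '.join(dupes)}")
    for node in nodes:
        if node.length is not None and node.length < 0:
            raise NewickParseError(f"negative branch length on node {node.id}")
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; branch lengths written with full (17 s.f.) precision."""

    def emit(nid: int) -> str:
        node = tree.nodes[nid]
        if node.children:
            s = "(" + ",".join(emit(c) for c in node.children) + ")"
        else:
            s = node.label or ""
        if node.parent is not None and node.length is not None:
            s += f":{node.length:.17g}"
        return s

    return emit(tree.root) + ";"


def load_tree(path: str | Path) -> PhyloTree:
    """Read a single Newick tree from a .phy/.nwk/.tre file."""
    return parse_newick(Path(path).read_text())


def save_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# -- branch-length conventions ----------------------------------------------


def assign_pagel_branch_lengths(tree: PhyloTree) -> PhyloTree:
    """Assign arbitrary ultrametric branch lengths by the node-height rule.

    Each internal node gets height (number of descendant tips - 1); tips have
    height 0; a branch's length is the parent height minus the child height.
    Any existing lengths are discarded.  The result is ultrametric with root
    height n_tips - 1; zero-length branches can arise at polytomies and are
    valid downstream.
    """
    out = tree.copy()
    n_desc: dict[int, int] = {}
    for nid in out.postorder():
        node = out.nodes[nid]
        n_desc[nid] = 1 if node.is_tip else sum(n_desc[c] for c in node.children)
    height = {nid: (0 if out.nodes[nid].is_tip else n_desc[nid] - 1) for nid in n_desc}
    for node in out.nodes:
        if node.parent is None:
            node.length = None
        else:
            node.length = float(height[node.parent] - height[node.id])
            if node.length < 0:
                raise TreeStructureError(
                    f"negative branch length from height rule at node {node.id}"
                )
    return out


def tree_table(tree: PhyloTree) -> pd.DataFrame:
    """Node table (id, parent, length, label) for debugging / TSV dumps."""
    return pd.DataFrame(
        {
            "id": [n.id for n in tree.nodes],
            "parent": [n.parent if n.parent is not None else math.nan for n in tree.nodes],
            "length": [n.length if n.length is not None else math.nan for n in tree.nodes],
            "label": [n.label or "" for n in tree.nodes],
        }
    )
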