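"""Rooted trees, leaf orderings, and clade <-> interval maps.

The segmentation machinery operates on a linear ordering of the leaves in
which every clade occupies a contiguous interval of positions.  This module
parses Newick trees (via dendropy), assigns the canonical integer node
labelling (leaves ``1..n``, inner nodes ``n+1..node_count`` with the root
last), and produces deterministic ("standard") or seeded random leaf
orderings together with the per-node position intervals.

Positions and intervals are 1-based and inclusive throughout, mirroring the
index convention of the underlying change-point formulation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "RootedTree",
    "LeafOrdering",
    "TreeFormatError",
    "read_newick",
    "write_newick",
    "standard_ordering",
    "random_ordering",
    "boundary_nodes",
]


class TreeFormatError(ValueError):
    """Raised for malformed or unsupported tree input."""


@dataclass
class RootedTree:
    """A rooted tree with integer node ids.

    Leaves carry ids ``1..n``; inner nodes ``n+1..node_count`` with the root
    equal to ``node_count`` (``2n-1`` for binary trees).  Polytomies are
    allowed.  Branch lengths are deliberately not stored: the method uses
    only the topology-induced ordering of the leaves.
    """

    n_leaves: int
    node_count: int
    root: int
    parent: dict[int, int]
    children: dict[int, list[int]]
    leaf_labels: dict[int, str]
    inner_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        n = self.n_leaves
        if n < 1:
            raise TreeFormatError("tree must have at least one leaf")
        if self.root in self.parent:
            raise TreeFormatError("root must not have a parent")
        seen = set()
        stack = [self.root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeFormatError("cycle detected in tree")
            seen.add(v)
            for c in self.children.get(v, []):
                if self.parent.get(c) != v:
                    raise TreeFormatError(f"inconsistent parent pointer at node {c}")
                stack.append(c)
        if len(seen) != self.node_count:
            raise TreeFormatError("not all nodes reachable from root")
        for leaf in range(1, n + 1):
            if self.children.get(leaf):
                raise TreeFormatError(f"leaf id {leaf} has children")
            if leaf not in self.leaf_labels:
                raise TreeFormatError(f"leaf id {leaf} has no label")

    @property
    def leaves(self) -> range:
        return range(1, self.n_leaves + 1)

    @property
    def inner_nodes(self) -> range:
        return range(self.n_leaves + 1, self.node_count + 1)

    def is_leaf(self, v: int) -> bool:
        return 1 <= v <= self.n_leaves

    def offspring_leaves(self, v: int) -> list[int]:
        """``Off(v)``: the leaf descendants of node ``v`` (v itself if a leaf)."""
        out: list[int] = []
        stack = [v]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return out

    def node_label(self, v: int) -> str:
        """Human-readable name for a node, stable across serialisations.

        Leaves report their label; inner nodes report their own label if the
        input tree carried one, otherwise ``MRCA(a,b)`` using the
        lexicographically extremal offspring-leaf labels of the clade.
        """
        if self.is_leaf(v):
            return self.leaf_labels[v]
        if v in self.inner_labels:
            return self.inner_labels[v]
        labels = sorted(self.leaf_labels[u] for u in self.offspring_leaves(v))
        return f"MRCA({labels[0]},{labels[-1]})"


@dataclass
class LeafOrdering:
    """A tree-consistent left-to-right arrangement of the leaves.

    ``order[i]`` is the leaf id at position ``i+1``; ``position`` maps leaf id
    to its 1-based position; ``clade_interval`` maps every node to the
    inclusive 1-based position range spanned by its offspring leaves.
    """

    tree: RootedTree
    order: list[int]
    position: dict[int, int]
    clade_interval: dict[int, tuple[int, int]]

    @property
    def n(self) -> int:
        return self.tree.n_leaves

    def labels_in_order(self) -> list[str]:
        return [self.tree.leaf_labels[v] for v in self.order]


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    leaves = [nd for nd in dtree.leaf_node_iter()]
    labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
    if any(lb is None for lb in labels):
        raise TreeFormatError("every leaf must carry a label")
    if len(set(labels)) != len(labels):
        dup = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise TreeFormatError(f"duplicate leaf labels: {dup}")

    n = len(leaves)
    ids: dict[dendropy.Node, int] = {}
    # leaves numbered 1..n in the input's left-to-right order
    next_leaf = 1
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            ids[nd] = next_leaf
            next_leaf += 1
    # inner nodes numbered n+1.. in postorder, so the root comes out last
    next_inner = n + 1
    for nd in dtree.postorder_node_iter():
        if not nd.is_leaf():
            ids[nd] = next_inner
            next_inner += 1

    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    leaf_labels: dict[int, str] = {}
    inner_labels: dict[int, str] = {}
    for nd, v in ids.items():
        children[v] = [ids[c] for c in nd.child_nodes()]
        if nd.parent_node is not None:
            parent[v] = ids[nd.parent_node]
        if nd.is_leaf():
            leaf_labels[v] = nd.taxon.label
        elif nd.label:
            inner_labels[v] = nd.label

    return RootedTree(
        n_leaves=n,
        node_count=next_inner - 1,
        root=ids[dtree.seed_node],
        parent=parent,
        children=children,
        leaf_labels=leaf_labels,
        inner_labels=inner_labels,
    )


def read_newick(text: str, auto_root: bool = False) -> RootedTree:
    """Parse a Newick string into a :class:`RootedTree`.

    Branch lengths are ignored.  Polytomies are preserved.  A top-level
    trifurcation is the conventional serialisation of an unrooted tree and is
    rejected unless ``auto_root=True``, in which case it is kept as a rooted
    tree whose root is the trifurcating node.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeFormatError(f"could not parse Newick input: {exc}") from exc
    n_tips = sum(1 for _ in dtree.leaf_node_iter())
    root_degree = len(dtree.seed_node.child_nodes())
    if root_degree == 3 and n_tips > 3 and not auto_root:
        raise TreeFormatError(
            "input looks unrooted (top-level trifurcation); re-root it first "
            "or pass auto_root=True to treat the trifurcation as the root"
        )
    return _from_dendropy(dtree)


def write_newick(tree: RootedTree, ordering: LeafOrdering | None = None,
                 node_annotations: dict[int, str] | None = None) -> str:
    """Serialise a tree to Newick.

    If ``ordering`` is given, children are written in the order the ordering
    was built with; ``node_annotations`` adds labels to inner nodes (used by
    the CLI to tag active / confidence-set nodes).
    """
    ann = node_annotations or {}

    def render(v: int) -> str:
        if tree.is_leaf(v):
            return _quote_label(tree.leaf_labels[v])
        inner = ",".join(render(c) for c in tree.children[v])
        label = ann.get(v, tree.inner_labels.get(v, ""))
        return f"({inner}){_quote_label(label) if label else ''}"

    return render(tree.root) + ";"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _build_ordering(tree: RootedTree, child_order: dict[int, list[int]]) -> LeafOrdering:
    order: list[int] = []
    clade_interval: dict[int, tuple[int, int]] = {}

    # iterative DFS computing intervals on the way back up
    stack: list[tuple[int, bool]] = [(tree.root, False)]
    while stack:
        v, done = stack.pop()
        if tree.is_leaf(v):
            order.append(v)
            clade_interval[v] = (len(order), len(order))
            continue
        if not done:
            stack.append((v, True))
            for c in reversed(child_order[v]):
                stack.append((c, False))
        else:
            kids = child_order[v]
            lo = clade_interval[kids[0]][0]
            hi = clade_interval[kids[-1]][1]
            clade_interval[v] = (lo, hi)

    position = {leaf: i + 1 for i, leaf in enumerate(order)}
    return LeafOrdering(tree=tree, order=order, position=position,
                        clade_interval=clade_interval)


def standard_ordering(tree: RootedTree) -> LeafOrdering:
    """The canonical leaf ordering, independent of input child order.

    At every inner node children are sorted by (number of offspring leaves,
    lexicographically smallest offspring-leaf label); the leaves are then read
    off depth-first left to right.  Two serialisations of the same tree that
    differ only by child rotations therefore yield identical orderings, which
    makes the whole pipeline's output independent of how the user happened to
    write the tree.
    """
    size: dict[int, int] = {}
    min_label: dict[int, str] = {}
    # postorder without recursion
    stack: list[tuple[int, bool]] = [(tree.root, False)]
    post: list[int] = []
    while stack:
        v, done = stack.pop()
        if done or tree.is_leaf(v):
            post.append(v)
        else:
            stack.append((v, True))
            for c in tree.children[v]:
                stack.append((c, False))
    for v in post:
        if tree.is_leaf(v):
            size[v] = 1
            min_label[v] = tree.leaf_labels[v]
        else:
            size[v] = sum(size[c] for c in tree.children[v])
            min_label[v] = min(min_label[c] for c in tree.children[v])

    child_order = {
        v: sorted(tree.children[v], key=lambda c: (size[c], min_label[c]))
        for v in tree.children
        if tree.children[v]
    }
    return _build_ordering(tree, child_order)


def random_ordering(tree: RootedTree, seed: int) -> LeafOrdering:
    """A tree-consistent ordering with every node's child order shuffled.

    Used for ordering-robustness studies: any such ordering is equally valid
    as long as it is chosen independently of the responses.
    """
    rng = np.random.default_rng(seed)
    child_order = {}
    for v in sorted(tree.children):
        kids = list(tree.children[v])
        if len(kids) > 1:
            rng.shuffle(kids)
        if kids:
            child_order[v] = kids
    return _build_ordering(tree, child_order)


def boundary_nodes(ordering: LeafOrdering, gap: int,
                   include_leaves: bool = True) -> list[int]:
    """Nodes whose clade interval abuts the gap between positions ``gap`` and
    ``gap + 1``.

    These are the candidate tree nodes responsible for a change in response
    distribution located at that gap.  Returned in order of increasing clade
    size.  ``include_leaves=False`` restricts to inner nodes.
    """
    n = ordering.n
    if not 1 <= gap <= n - 1:
        raise ValueError(f"gap must be in 1..{n - 1}, got {gap}")
    out = []
    for v, (lo, hi) in ordering.clade_interval.items():
        if not include_leaves and ordering.tree.is_leaf(v):
            continue
        if hi == gap or lo == gap + 1:
            out.append(v)
    out.sort(key=lambda v: (ordering.clade_interval[v][1]
                            - ordering.clade_interval[v][0],
                            ordering.clade_interval[v][0]))
    return out
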