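"""Per-chromosome segment tree with canonical subsets.

The tree is built over the *elementary intervals* induced by the sorted
distinct endpoints p_1..p_m of the inputs: the point leaves [p_i, p_i] and,
between consecutive endpoints, the gap leaves [p_i+1, p_{i+1}-1] when
non-empty (the open intervals of the real-line formulation, integerised).
Leaves are paired bottom-up left-to-right into a balanced binary tree; an odd
node at any level is promoted unchanged.

Each input interval g is then inserted from the root: at a node v whose span
Int(v) is fully contained in g, g joins the canonical subset I(v) and the
descent stops; otherwise the descent continues into each child overlapping g.
Hence every g in I(v) contains Int(v) but not Int(parent(v)), and g is stored
at most twice per depth level, giving O(n log n) total storage.

Heights count nodes: a single-node tree has height 1, an empty tree 0.

Elements only need ``low``, ``high`` and ``uid`` attributes, so trees can be
built over raw genomic intervals or over intermediate overlap records alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple


@dataclass(slots=True)
class ElementaryPartition:
    endpoints: Tuple[int, ...]
    leaves: List[Tuple[int, int]]


class SegmentTreeNode:
    __slots__ = ("int_low", "int_high", "canonical", "left", "right", "depth")

    def __init__(self, int_low: int, int_high: int,
                 left: Optional["SegmentTreeNode"] = None,
                 right: Optional["SegmentTreeNode"] = None) -> None:
        self.int_low = int_low
        self.int_high = int_high
        self.canonical: list = []
        self.left = left
        self.right = right
        self.depth = 0

    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    def children(self):
        if self.left is not None:
            yield self.left
        if self.right is not None:
            yield self.right

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node[{self.int_low},{self.int_high}]({len(self.canonical)})"


@dataclass(slots=True)
class SegmentTree:
    chrom: str
    root: Optional[SegmentTreeNode]
    height: int = 0          # node-counting: levels; 0 for empty tree
    n_leaves: int = 0
    n_stored: int = 0        # total attachments, sum of |I(v)|

    def nodes(self):
        """Yield all nodes, pre-order."""
        if self.root is None:
            return
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if node.right is not None:
                stack.append(node.right)
            if node.left is not None:
                stack.append(node.left)


@dataclass(slots=True)
class TreeStats:
    height: int
    n_leaves: int
    n_stored: int
    attachments_by_depth: List[int] = field(default_factory=list)


def elementary_partition(intervals: Sequence) -> ElementaryPartition:
    """Sorted distinct endpoints and the leaf ranges they induce."""
    if not intervals:
        raise ValueError("elementary_partition requires at least one interval")
    points = set()
    for iv in intervals:
        points.add(iv.low)
        points.add(iv.high)
    endpoints = tuple(sorted(points))
    leaves: List[Tuple[int, int]] = [(endpoints[0], endpoints[0])]
    for a, b in zip(endpoints, endpoints[1:]):
        if b > a + 1:
            leaves.append((a + 1, b - 1))
        leaves.append((b, b))
    return ElementaryPartition(endpoints=endpoints, leaves=leaves)


def _assign_depths(root: SegmentTreeNode) -> int:
    """Set node depths (root = 0); return max leaf depth."""
    max_depth = 0
    stack = [(root, 0)]
    while stack:
        node, d = stack.pop()
        node.depth = d
        if node.is_leaf():
            if d > max_depth:
                max_depth = d
        else:
            for child in node.children():
                stack.append((child, d + 1))
    return max_depth


def build_segment_tree(intervals: Sequence, chrom: Optional[str] = None) -> SegmentTree:
    """Build the balanced tree bottom-up, then insert every input interval.

    Canonical subsets preserve input order. Empty input yields an empty tree.
    """
    if chrom is None:
        chrom = intervals[0].chrom if intervals else ""
    if not intervals:
        return SegmentTree(chrom=chrom, root=None)

    part = elementary_partition(intervals)
    level: List[SegmentTreeNode] = [SegmentTreeNode(lo, hi) for lo, hi in part.leaves]
    n_leaves = len(level)
    while len(level) > 1:
        nxt: List[SegmentTreeNode] = []
        it = iter(range(0, len(level) - 1, 2))
        for i in it:
            left, right = level[i], level[i + 1]
            nxt.append(SegmentTreeNode(left.int_low, right.int_high, left, right))
        if len(level) % 2:
            nxt.append(level[-1])     # odd node promoted unchanged
        level = nxt
    root = level[0]
    max_depth = _assign_depths(root)

    tree = SegmentTree(chrom=chrom, root=root, height=max_depth + 1, n_leaves=n_leaves)
    for iv in intervals:
        tree.n_stored += _insert(root, iv)
    return tree


def _insert(root: SegmentTreeNode, iv) -> int:
    """Attach iv to the canonical subsets it belongs to; return attachment count."""
    n = 0
    lo, hi = iv.low, iv.high
    stack = [root]
    while stack:
        node = stack.pop()
        if lo <= node.int_low and node.int_high <= hi:
            node.canonical.append(iv)
            n += 1
            continue
        # push right before left so left is processed first (stable order)
        right = node.right
        if right is not None and right.int_low <= hi and lo <= right.int_high:
            stack.append(right)
        left = node.left
        if left is not None and left.int_low <= hi and lo <= left.int_high:
            stack.append(left)
    return n


def query_point(tree: SegmentTree, x: int, _visits: Optional[list] = None) -> list:
    """All stored intervals containing point x; one node visited per level."""
    out: list = []
    node = tree.root
    visits = 0
    while node is not None:
        if not (node.int_low <= x <= node.int_high):
            break
        visits += 1
        out.extend(node.canonical)
        if node.is_leaf():
            break
        left = node.left
        node = left if (left is not None and x <= left.int_high) else node.right
    if _visits is not None:
        _visits.append(visits)
    return out


def query_interval(tree: SegmentTree, q_low: int, q_high: int) -> list:
    """All stored intervals overlapping [q_low, q_high], each reported once.

    Multi-branch descent emitting I(v) at every node overlapping the query;
    correctness needs no per-interval filter because every g in I(v) fully
    contains Int(v). Duplicates across nodes are removed by uid.
    """
    if q_low > q_high:
        raise ValueError("q_low must be <= q_high")
    out: list = []
    seen: set = set()
    root = tree.root
    if root is None:
        return out
    if root.int_low <= q_high and q_low <= root.int_high:
        collect_overlapping(root, q_low, q_high, seen, out)
    return out


def collect_overlapping(root: SegmentTreeNode, q_low: int, q_high: int,
                        seen: set, out: list) -> None:
    """Emit canonical subsets of all nodes under ``root`` overlapping the query.

    Caller guarantees ``root`` itself overlaps [q_low, q_high]. ``seen`` and
    ``out`` are shared across calls so a forest query can union several short
    trees while deduplicating by uid.
    """
    stack = [root]
    while stack:
        node = stack.pop()
        for iv in node.canonical:
            if iv.uid not in seen:
                seen.add(iv.uid)
                out.append(iv)
        right = node.right
        if right is not None and right.int_low <= q_high and q_low <= right.int_high:
            stack.append(right)
        left = node.left
        if left is not None and left.int_low <= q_high and q_low <= left.int_high:
            stack.append(left)


def tree_stats(tree: SegmentTree) -> TreeStats:
    """Height, leaf count and the attachments-per-depth profile."""
    if tree.root is None:
        return TreeStats(height=0, n_leaves=0, n_stored=0, attachments_by_depth=[])
    by_depth = [0] * tree.height
    for node in tree.nodes():
        by_depth[node.depth] += len(node.canonical)
    return TreeStats(height=tree.height, n_leaves=tree.n_leaves,
                     n_stored=tree.n_stored, attachments_by_depth=by_depth)
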