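"""Indexed segment tree forest (ISTF).

A built segment tree is cut at a *cut-off depth*: the forest keeps the nodes
at that depth plus the childless nodes above it, each the root of a short
segment tree. Attachments living strictly above the cut are redistributed to
the forest members in their subtree, so no interval is lost. Forest members
are doubly linked in coordinate order and hash-indexed by

    hashIndex = int_low // preset

nodes colliding on an index are held in a balanced binary search tree whose
internal "artificial" nodes carry only routing keys.

A query resolves its starting member through a four-step index cascade
(lowIndex -> lowerIndex -> highIndex -> higherIndex), then scans the linked
members covering the query span; because member spans are consecutive and
non-overlapping, at most two members outside the [lowIndex..highIndex] bucket
range are ever touched.

The cut never changes answers: ``query_forest`` returns exactly what
``segment_tree.query_interval`` returns on the uncut tree. Redistributed
attachments are stored on the receiving forest member (``moved``), leaving
the source tree intact so both engines can be run on the same tree.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from statistics import fmean, pstdev
from typing import Dict, List, Optional, Tuple

from .segment_tree import (SegmentTree, SegmentTreeNode, collect_overlapping,
                           tree_stats)


class ForestNode:
    """A retained segment-tree node: root of a short tree, doubly linked."""

    __slots__ = ("node", "prev", "next", "moved", "hash_index")

    def __init__(self, node: SegmentTreeNode) -> None:
        self.node = node
        self.prev: Optional["ForestNode"] = None
        self.next: Optional["ForestNode"] = None
        self.moved: list = []        # attachments relocated from above the cut
        self.hash_index: int = 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"ForestNode[{self.node.int_low},{self.node.int_high}]@{self.hash_index}"


class _BSTNode:
    """Collision-BST node; leaves hold forest nodes, internals are artificial."""

    __slots__ = ("key", "left", "right", "forest_node")

    def __init__(self, key: int, left=None, right=None, forest_node=None) -> None:
        self.key = key
        self.left = left
        self.right = right
        self.forest_node = forest_node


class BucketBST:
    """Balanced BST over the forest nodes sharing one hash index.

    Built in one shot from the sorted node list; a single node has height 1
    (node-counting convention, used for all height comparisons).
    """

    __slots__ = ("root", "nodes", "height")

    def __init__(self, nodes: List[ForestNode]) -> None:
        if not nodes:
            raise ValueError("empty bucket")
        self.nodes = nodes
        self.root, self.height = self._build(nodes)

    @staticmethod
    def _build(nodes: List[ForestNode]) -> Tuple[_BSTNode, int]:
        if len(nodes) == 1:
            return _BSTNode(nodes[0].node.int_low, forest_node=nodes[0]), 1
        mid = len(nodes) // 2
        left, hl = BucketBST._build(nodes[:mid])
        right, hr = BucketBST._build(nodes[mid:])
        # routing key: minimum int_low of the right subtree
        return _BSTNode(nodes[mid].node.int_low, left=left, right=right), max(hl, hr) + 1

    def search(self, x: int) -> ForestNode:
        """Rightmost held node with int_low <= x, else the leftmost node."""
        node = self.root
        while node.forest_node is None:
            node = node.right if x >= node.key else node.left
        return node.forest_node

    def artificial_count(self) -> int:
        n = 0
        stack = [self.root]
        while stack:
            b = stack.pop()
            if b.forest_node is None:
                n += 1
                stack.append(b.left)
                stack.append(b.right)
        return n


@dataclass(slots=True)
class IndexedForest:
    chrom: str
    preset: int
    percentage: float
    cutoff_depth: int = 0
    source_height: int = 0
    buckets: Dict[int, BucketBST] = field(default_factory=dict)
    bucket_keys: List[int] = field(default_factory=list)   # sorted, frozen
    head: Optional[ForestNode] = None
    tail: Optional[ForestNode] = None
    n_nodes: int = 0
    moved_attachments: int = 0

    def members(self):
        node = self.head
        while node is not None:
            yield node
            node = node.next


@dataclass(slots=True)
class ForestStats:
    chrom: str
    cutoff_depth: int
    source_height: int
    n_nodes: int
    bucket_count: int
    nodes_per_bucket_mean: float
    nodes_per_bucket_sd: float
    bst_heights: List[int]
    mean_bst_height: float
    max_bst_height: int
    moved_attachments: int


@dataclass(slots=True)
class QueryCounters:
    """Instrumentation for the two-extra-nodes bound."""
    visited: int = 0
    outside_index_range: int = 0


def decide_cutoff_depth(tree: SegmentTree, percentage: float = 0.5) -> int:
    """Cut-off depth d+1, where d is the shallowest depth at which the
    cumulative attachment count exceeds ``percentage`` % of all attachments;
    clamped to the maximum leaf depth so the cut never passes the leaves.
    """
    if tree.root is None:
        raise ValueError("cannot choose a cut-off depth for an empty tree")
    if not 0 < percentage <= 100:
        raise ValueError("percentage must be in (0, 100]")
    stats = tree_stats(tree)
    threshold = percentage / 100.0 * stats.n_stored
    max_depth = tree.height - 1
    cum = 0
    for d, cnt in enumerate(stats.attachments_by_depth):
        cum += cnt
        if cum > threshold:
            return min(d + 1, max_depth)
    return max_depth


def hash_index(low: int, preset: int) -> int:
    """Bucket index of a coordinate: floor division by the preset width."""
    if preset <= 0:
        raise ValueError("preset must be positive")
    return low // preset


def build_forest(tree: SegmentTree, percentage: float = 0.5,
                 preset: int = 1_000_000) -> IndexedForest:
    """Cut ``tree`` and assemble the indexed forest. The tree is not mutated."""
    if preset <= 0:
        raise ValueError("preset must be positive")
    forest = IndexedForest(chrom=tree.chrom, preset=preset, percentage=percentage,
                           source_height=tree.height)
    if tree.root is None:
        return forest
    cutoff = decide_cutoff_depth(tree, percentage)
    forest.cutoff_depth = cutoff

    members = [ForestNode(n) for n in _members_below(tree.root, cutoff)]
    by_node = {id(m.node): m for m in members}

    # relocate attachments stored strictly above the cut: deepest sources
    # first, left-to-right within a depth, appended to every forest member in
    # the source's subtree (covers both the childless and the lowest-offspring
    # cases of the redistribution rule)
    sources = [(n, seq) for seq, n in enumerate(_iter_preorder(tree.root))
               if n.depth < cutoff and not n.is_leaf() and n.canonical]
    sources.sort(key=lambda t: (-t[0].depth, t[1]))
    for src, _ in sources:
        receivers = [by_node[id(n)] for n in _members_below(src, cutoff)]
        for g in src.canonical:
            forest.moved_attachments += 1
            for m in receivers:
                m.moved.append(g)

    # doubly link in increasing coordinate order (members are produced
    # left-to-right, i.e. already sorted by int_low)
    for a, b in zip(members, members[1:]):
        a.next = b
        b.prev = a
    forest.head = members[0]
    forest.tail = members[-1]
    forest.n_nodes = len(members)

    grouped: Dict[int, List[ForestNode]] = {}
    for m in members:
        m.hash_index = hash_index(m.node.int_low, preset)
        grouped.setdefault(m.hash_index, []).append(m)
    forest.buckets = {k: BucketBST(v) for k, v in grouped.items()}
    forest.bucket_keys = sorted(forest.buckets)
    return forest


def _members_below(root: SegmentTreeNode, cutoff: int) -> List[SegmentTreeNode]:
    """Forest members within a subtree, left-to-right: nodes at the cut-off
    depth plus childless nodes above it."""
    out: List[SegmentTreeNode] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.depth >= cutoff or node.is_leaf():
            out.append(node)
            continue
        if node.right is not None:
            stack.append(node.right)
        if node.left is not None:
            stack.append(node.left)
    return out


def _iter_preorder(root: SegmentTreeNode):
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        if node.right is not None:
            stack.append(node.right)
        if node.left is not None:
            stack.append(node.left)


def resolve_start(forest: IndexedForest, q_low: int, q_high: int) -> Tuple[Optional[ForestNode], str]:
    """Starting member for a query plus the cascade branch taken.

    Cascade: the bucket at lowIndex; else the highest bucket below it (search
    continues forward); else the bucket at highIndex; else the lowest bucket
    above it (search continues backward). A final guard starts at the first
    member when every bucket lies strictly between the two indexes, a corner
    the four steps cannot reach from genomic-scale queries but which keeps
    query answers identical to the uncut tree for arbitrarily wide queries.
    """
    if forest.head is None:
        return None, "empty"
    preset = forest.preset
    keys = forest.bucket_keys
    low_idx = q_low // preset
    bucket = forest.buckets.get(low_idx)
    if bucket is not None:
        return bucket.search(q_low), "lowIndex"
    i = bisect_left(keys, low_idx)
    if i > 0:
        return forest.buckets[keys[i - 1]].search(q_low), "lowerIndex"
    high_idx = q_high // preset
    bucket = forest.buckets.get(high_idx)
    if bucket is not None:
        return bucket.search(q_low), "highIndex"
    j = bisect_right(keys, high_idx)
    if j < len(keys):
        return forest.buckets[keys[j]].search(q_low), "higherIndex"
    if forest.head.node.int_low <= q_high:
        return forest.head, "head"
    return None, "none"


def lookup_start(forest: IndexedForest, q_low: int, q_high: int) -> Optional[ForestNode]:
    return resolve_start(forest, q_low, q_high)[0]


def query_forest(forest: IndexedForest, q_low: int, q_high: int,
                 counters: Optional[QueryCounters] = None) -> list:
    """All stored intervals overlapping [q_low, q_high]; identical to the
    uncut tree's interval query (set equality by uid)."""
    if q_low > q_high:
        raise ValueError("q_low must be <= q_high")
    start, _ = resolve_start(forest, q_low, q_high)
    if start is None:
        return []
    # rewind to the leftmost member that can still overlap the query; member
    # spans are consecutive, so this backs up past at most the few members
    # between the cascade's entry point and the query's left edge
    node = start
    while node.prev is not None and node.prev.node.int_high >= q_low:
        node = node.prev

    preset = forest.preset
    low_idx = q_low // preset
    high_idx = q_high // preset
    out: list = []
    seen: set = set()
    cur: Optional[ForestNode] = node
    while cur is not None and cur.node.int_low <= q_high:
        if cur.node.int_high >= q_low:
            if counters is not None:
                counters.visited += 1
                if cur.hash_index < low_idx or cur.hash_index > high_idx:
                    counters.outside_index_range += 1
            collect_overlapping(cur.node, q_low, q_high, seen, out)
            # moved attachments fully contain this member's span, so they
            # overlap any query this member overlaps
            for g in cur.moved:
                if g.uid not in seen:
                    seen.add(g.uid)
                    out.append(g)
        cur = cur.next
    return out


def forest_stats(forest: IndexedForest) -> ForestStats:
    sizes = [len(b.nodes) for b in forest.buckets.values()]
    heights = [forest.buckets[k].height for k in forest.bucket_keys]
    return ForestStats(
        chrom=forest.chrom,
        cutoff_depth=forest.cutoff_depth,
        source_height=forest.source_height,
        n_nodes=forest.n_nodes,
        bucket_count=len(forest.buckets),
        nodes_per_bucket_mean=fmean(sizes) if sizes else 0.0,
        nodes_per_bucket_sd=pstdev(sizes) if len(sizes) > 1 else 0.0,
        bst_heights=heights,
        mean_bst_height=fmean(heights) if heights else 0.0,
        max_bst_height=max(heights) if heights else 0,
        moved_attachments=forest.moved_attachments,
    )
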