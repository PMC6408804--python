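# Methods

## Coordinates and overlap semantics

BED input is 0-based half-open; internally every interval is the inclusive
integer pair `[low, high] = [start, end-1]`. Overlap means at least one
shared base, matching `bedtools intersect` defaults. Records with
`end <= start` denote empty intervals and are dropped with a count.
Chromosome names are opaque strings compared exactly; no `chr` normalisation
is attempted. Duplicated input records are distinct objects with distinct
uids (`(set_id, ordinal)` pairs) and each is reported — counts are per
record, not per distinct coordinate.

## Segment tree

The elementary intervals of the real-line formulation are integerised: each
endpoint contributes a point leaf `[p, p]`, and each gap between consecutive
endpoints contributes `[p_i+1, p_{i+1}-1]` only when non-empty. Leaves are
paired bottom-up left-to-right; an odd node at any level is promoted
unchanged to the next level. This keeps leaves in coordinate order at every
depth and bounds the maximum leaf depth by ceil(log2 L) for L leaves.

**Height convention.** All heights count nodes: a single-node tree (or a
single-node collision BST) has height 1; an empty tree has height 0. The
convention is used consistently for the tree-height bound
(height ≤ ceil(log2 L) + 1), the point-query visit bound (≤ height + 1
nodes) and every BST-vs-tree height comparison.

Insertion walks from the root: a node whose span is contained in the
interval receives it in its canonical subset and the descent stops there;
otherwise both overlapping children are visited. This yields the standard
guarantees — each interval is stored at most twice per depth, total storage
O(n log n) — which the test suite asserts directly.

**Interval queries.** The stabbing-query generalisation to interval queries
is not uniquely determined by the structure alone, so it is fixed by an
equivalence contract: multi-branch descent emits the canonical subset of
every node overlapping the query, deduplicated by uid. No per-interval
filter is needed, because any member of I(ν) fully contains Int(ν) — overlap
with the node span implies overlap with the interval. Tests pin the result
to a linear-scan oracle across randomized adversarial inputs.

## Indexed segment tree forest

**Cut-off depth.** With percentage p (default 0.5, i.e. 0.5 %), the cut-off
is d + 1 where d is the shallowest depth at which the cumulative attachment
count (root downward) exceeds p % of all attachments; it is clamped to the
maximum leaf depth. "All attachments" counts multiplicity: an interval
stored at three nodes counts three times, the literal reading of the total
stored in the tree. Depth is root-relative; increasing p therefore moves the
cut *deeper* (toward the leaves) and moves more attachments, which is the
trend the tests assert.

**Redistribution.** Attachments stored strictly above the cut must not be
lost. Each is re-attached to every forest member inside its node's subtree —
the members being the nodes at the cut-off depth plus childless nodes above
it. This uniform rule covers the childless-source case (the source is itself
a member and keeps its attachment), the case where no descendant reaches the
cut (the deepest childless descendants receive it), and the mixed case where
only some branches reach the cut. Sources are processed deepest-first,
left-to-right within a depth, so receivers accumulate relocated attachments
in a deterministic order. Relocated attachments are stored in a separate
`moved` list on the receiving forest node rather than appended to its
canonical subset: the source tree stays intact (so both engines can run on
the same build), and the query semantics are identical because a moved
interval fully contains the receiver's span.

**Indexing.** Forest members are doubly linked in increasing coordinate
order; their spans are non-overlapping and consecutive. Each is hashed by
`int_low // preset` (preset default 1,000,000 bp). Members sharing an index
are assembled once into a balanced BST built from the sorted list; internal
nodes are artificial, holding only a routing key (the minimum `int_low` of
the right subtree). A bucket of k members has BST height ceil(log2 k) + 1,
never exceeding the source tree's height since the tree has at least k
leaves — the property the percentage-grid sweep measures.

**Query.** The starting member is resolved by a four-step cascade: the
bucket at lowIndex; else the highest bucket below it; else the bucket at
highIndex; else the lowest bucket above it. Inside a bucket, the BST descent
selects the rightmost member with `int_low ≤ q_low`, falling back to the
bucket's leftmost member. The scan then rewinds along the backward links
while the previous member can still overlap, and sweeps forward while
`int_low ≤ q_high`, querying each short tree plus its `moved` list. Because
member spans are consecutive, at most one member below lowIndex and one
above highIndex are ever touched; an instrumented counter asserts ≤ 2
members outside the bucket range per query. A fifth fallback branch starts
at the first member when every bucket lies strictly between the two indexes
— reachable only for queries that strictly contain the whole forest span
with more than a preset width of slack on both sides, a corner the four-step
cascade alone would misreport as empty; the fallback keeps forest answers
exactly equal to the uncut tree's for arbitrary queries, which is the
module's defining contract.

## n-way combination

Intermediate results are intersection *regions*, not original intervals:
this is what makes the combine associative and the n-way result well
defined. Each combine emits one record per overlapping pair with the
contributor lists concatenated (left operand first), so a finished record
carries one uid per input set in set order. The index is always built on the
smaller operand, bounding memory. Chromosomes are processed independently
(optionally in a thread pool); determinism is a contract — output is
coordinate-sorted per chromosome and concatenated in sorted chromosome
order, independent of the worker count.

## Synthetic data and the oracle

The uniform generator emulates the semi-synthetic evaluation data:
fixed-length intervals (500 bp) whose chromosome is drawn with probability
proportional to length and whose start is uniform in
`[0, length - interval_len]`, over hg19-scale lengths for the 24 nuclear
chromosomes (overridable by a chrom.sizes file). One seeded NumPy stream per
call makes outputs byte-reproducible. What it does not emulate: clustering
of regulatory elements, chromatin-domain structure, peak-length variation,
assembly gaps. Passing tests therefore demonstrate engine correctness and
the structural properties of the data structures, not biological effect
sizes; the one dataset-level claim retained is structural — eight or more
independent uniform 100,000-interval sets share no jointly covered base, so
the joint count is 0 — because a 500 bp window being hit in all eight sets
has probability small enough that the genome-wide expectation is ≪ 1 under
any uniform-like sampler. Pairwise counts (a few thousand for 2 × 100,000)
depend on the exact sampler and are reported informatively, not asserted.

The brute-force oracle shares no code with the engines: all-pairs
comparison below 250,000 candidate pairs, otherwise an endpoint-event sweep
(starts processed before ends at equal coordinates so a single shared base
counts); the two variants are cross-checked against each other and against
`intervaltree`. n-way oracle results are a strict left fold, which doubles
as the split-invariance reference for the midpoint recursion.

The randomized fixture suite mixes dense uniform draws over a small
two-chromosome genome with adversarial sets (nested chains, exact
duplicates, shared endpoints, adjacent pairs, point intervals, shuffled
order), 2–16 sets of up to 2,000 intervals. Per-set sizes are capped by a
shared budget so the per-tuple record count cannot grow geometrically with
the set count; the suite of 100 fixtures verifies in seconds.

## Problem sizes and defaults

| parameter | default | meaning |
| --- | --- | --- |
| percentage | 0.5 (%) | attachment share that fixes the cut-off depth |
| preset | 1,000,000 (bp) | hash-bucket width; smaller → more buckets, smaller BSTs |
| interval_len | 500 (bp) | generated interval length |
| workers | 1 | per-chromosome thread pool size (results invariant) |

The acceptance script measures on 100 fixtures, one 2 × 100,000 run, three
8 × 100,000 runs and one 100,000-interval percentage-grid sweep — sizes at
which the whole script completes in about a minute on one CPU while
exercising every genome-scale code path.

## Known limitations

- Inputs are BED3+; BAM/GFF/VCF and tabix-indexed access are out of scope.
- No strand awareness and no fraction-of-overlap filtering.
- Trees and forests are static; there is no incremental insertion.
- Parallelism is thread-based and chromosome-grained; it exists for the
  determinism contract rather than for speedups on CPython.
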