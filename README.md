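# joverlap

Joint overlap analysis of *n* genomic interval sets.

Given *n* BED files — DNase hotspots, histone-mark peaks, any per-sample
interval collections — `joverlap` finds every region covered by at least one
interval from *each* of the *n* sets, reporting one record per contributing
tuple of source intervals (the same per-pair semantics as chained
`bedtools intersect`). It is aimed at regulatory-genomics analyses that ask
"which regions are active in all of these samples?" for anywhere from 2 to
hundreds of sets, without writing temporary pairwise files.

## Method

Intervals are grouped per chromosome and combined by divide and conquer:
the set list is split at the midpoint until one or two sets remain, and each
pairwise combine builds a search index on the smaller collection and queries
it with the larger. Each overlapping pair (a, b) yields the region
[max(a.low, b.low), min(a.high, b.high)] carrying both sides' source ids, so
a finished record traces back to exactly one interval per input set. Because
intersection is associative, the split point never changes the result.

Two interchangeable engines answer the interval queries:

- **Segment tree (`st`).** For intervals I = {[x₁:x₁′], …, [xₙ:xₙ′]} the
  distinct endpoints p₁ < … < pₘ induce elementary intervals
  [p₁:p₁], (p₁:p₂), [p₂:p₂], …, [pₘ:pₘ]; a balanced binary tree is built
  bottom-up over them, and each input interval joins the canonical subset
  I(ν) of every node ν with Int(ν) ⊆ [x:x′] and Int(parent(ν)) ⊄ [x:x′].
  Construction is O(n log n); a stabbing query is O(log n + k).
- **Indexed segment tree forest (`istf`).** Most attachments live near the
  leaves, so the tree is cut at a data-driven *cut-off depth*: the shallowest
  depth d at which the cumulative attachment count exceeds a percentage
  (default 0.5 %) of all attachments, plus one. The nodes at that depth (and
  childless nodes above it) become roots of short trees, doubly linked in
  coordinate order and hashed by `hashIndex = int_low // preset` (default
  preset 1 Mbp); colliding roots go into a balanced collision BST. A query
  jumps to its bucket in O(1), and never touches more than two forest roots
  outside its [lowIndex..highIndex] bucket range.

The two engines return identical results, byte for byte; the forest only
changes how the search space is entered.

## Worked example

```bash
printf 'chr1\t100\t200\nchr1\t150\t400\n' > a.bed
printf 'chr1\t120\t260\n'                 > b.bed
printf 'chr1\t180\t500\n'                 > c.bed

joverlap intersect a.bed b.bed c.bed --emit-sources -o out.bed
# prints: 2
cat out.bed
# chr1    180     200     0:0,1:0,2:0
# chr1    180     260     0:1,1:0,2:0
```

Both records span bases jointly covered by all three files. `a.bed`
contributes two intervals that each overlap the single `b.bed` and `c.bed`
intervals, so two contributing tuples exist: the printed count (2) is the
number of tuples, not of merged regions. The last column names the source
interval per input set as `set:ordinal`. Re-running with `--method istf`
produces identical output.

The library API mirrors the CLI:

```python
from joverlap import read_bed, joint_overlap, count_overlaps
sets = [read_bed(p, set_id=i) for i, p in enumerate(["a.bed", "b.bed", "c.bed"])]
records = joint_overlap(sets, method="istf")
count_overlaps(records)   # 2
```

`joverlap generate` writes semi-synthetic uniform BED files over hg19-scale
chromosomes, and `joverlap stats` reports per-chromosome tree/forest
structure (heights, buckets, moved attachments) as TSV.

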