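"""Brute-force reference for joint overlap.

Independent of the tree/forest engines on purpose: this module implements the
same pairwise-record semantics by all-pairs comparison (small inputs) or a
sort-based sweep over endpoint events (larger inputs), and n-way overlap as a
plain left fold. It exists so every engine result can be checked against code
that shares nothing with the data structures under test.
"""

from __future__ import annotations

from typing import List, Sequence

from .intervals import IntervalSet, OverlapRecord

_ALL_PAIRS_LIMIT = 250_000   # switch to the sweep above this many comparisons


def _contribs(x) -> tuple:
    return x.contributors


def _record(chrom, a, b) -> OverlapRecord:
    return OverlapRecord(chrom=chrom, low=max(a.low, b.low), high=min(a.high, b.high),
                         contributors=_contribs(a) + _contribs(b))


def oracle_intersect_two(A: Sequence, B: Sequence, force: str | None = None) -> List[OverlapRecord]:
    """All overlapping pairs of two single-chromosome collections.

    ``force`` pins the algorithm to ``"pairs"`` or ``"sweep"`` for
    cross-checking; by default small inputs use all-pairs.
    """
    if not A or not B:
        return []
    chroms = {x.chrom for x in A} | {x.chrom for x in B}
    if len(chroms) > 1:
        raise ValueError("oracle_intersect_two requires a single chromosome")
    chrom = chroms.pop()
    if force == "pairs" or (force is None and len(A) * len(B) <= _ALL_PAIRS_LIMIT):
        out = [_record(chrom, a, b)
               for a in A for b in B
               if a.low <= b.high and b.low <= a.high]
    else:
        out = _sweep(chrom, A, B)
    out.sort(key=OverlapRecord.sort_key)
    return out


def _sweep(chrom, A, B) -> List[OverlapRecord]:
    """Endpoint-event sweep: starts are processed before ends at the same
    coordinate so a single shared base counts as overlap."""
    events = []   # (pos, kind, side, element); kind 0 = start, 1 = end
    for side, coll in ((0, A), (1, B)):
        for el in coll:
            events.append((el.low, 0, side, el))
            events.append((el.high, 1, side, el))
    events.sort(key=lambda e: (e[0], e[1]))
    active: tuple[dict, dict] = ({}, {})
    out: List[OverlapRecord] = []
    for _, kind, side, el in events:
        if kind == 0:
            for other in active[1 - side].values():
                a, b = (el, other) if side == 0 else (other, el)
                out.append(_record(chrom, a, b))
            active[side][id(el)] = el
        else:
            del active[side][id(el)]
    return out


def oracle_joint(sets: Sequence[IntervalSet]) -> List[OverlapRecord]:
    """Left fold of pairwise overlaps across all sets, per chromosome."""
    if not sets:
        raise ValueError("oracle_joint requires at least one interval set")
    common = set(sets[0].per_chrom)
    for s in sets[1:]:
        common &= set(s.per_chrom)
    out: List[OverlapRecord] = []
    for chrom in sorted(common):
        recs: List = [OverlapRecord(chrom=iv.chrom, low=iv.low, high=iv.high,
                                    contributors=(iv.uid,))
                      for iv in sets[0].per_chrom[chrom]]
        for s in sets[1:]:
            recs = oracle_intersect_two(recs, s.per_chrom[chrom])
            if not recs:
                break
        out.extend(recs)
    return out
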