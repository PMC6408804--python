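"""Core interval containers.

Coordinates are integer base pairs, stored inclusive on both ends:
a BED record ``[start, end)`` becomes ``[low, high] = [start, end - 1]``.
Two intervals overlap when they share at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Tuple


@dataclass(slots=True)
class GenomicInterval:
    """One input record: an inclusive integer range on a chromosome.

    ``uid`` identifies the record across a whole run (a ``(set_id, ordinal)``
    tuple for loaded/generated data); duplicates of the same coordinates keep
    distinct uids and are reported separately downstream.
    """

    chrom: str
    low: int
    high: int
    uid: Hashable
    set_id: int = 0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.low > self.high:
            raise ValueError(f"low > high for {self.chrom}:{self.low}-{self.high}")

    @property
    def contributors(self) -> Tuple[Hashable, ...]:
        return (self.uid,)


@dataclass(slots=True)
class IntervalSet:
    """All intervals of one input set, grouped per chromosome.

    Input order within each chromosome is preserved; no sortedness is assumed
    or enforced (inputs may be unsorted, nested, or duplicated).
    """

    set_id: int
    per_chrom: Dict[str, List[GenomicInterval]] = field(default_factory=dict)
    n_dropped: int = 0

    def add(self, iv: GenomicInterval) -> None:
        self.per_chrom.setdefault(iv.chrom, []).append(iv)

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.per_chrom.values())

    def chromosomes(self) -> List[str]:
        return sorted(self.per_chrom)


@dataclass(slots=True)
class OverlapRecord:
    """One jointly overlapping region.

    ``contributors`` holds exactly one source uid per original input set that
    this record derives from; ``[low, high]`` is the intersection of those
    source intervals. ``uid`` is assigned transiently when a record list is
    indexed during recursion.
    """

    chrom: str
    low: int
    high: int
    contributors: Tuple[Hashable, ...]
    uid: Optional[Hashable] = None

    def sort_key(self) -> tuple:
        return (self.low, self.high, tuple(str(u) for u in self.contributors))

    def as_triple(self) -> Tuple[str, int, int]:
        return (self.chrom, self.low, self.high)
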