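"""BED reading and writing.

BED is 0-based half-open; internally intervals are inclusive ``[start, end-1]``.
Track/browser/comment lines are skipped; extra columns beyond the third are
ignored on input. Records with ``end <= start`` denote empty intervals and are
dropped with a count rather than raising.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Union

from .intervals import GenomicInterval, IntervalSet, OverlapRecord

_SKIP_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """Malformed BED content; message names the offending line."""


def read_bed(path: Union[str, os.PathLike], set_id: int = 0) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Records keep their input order within each chromosome. ``uid`` is the
    ``(set_id, ordinal)`` pair counting retained records. An empty file yields
    an empty set; a non-integer coordinate raises :class:`BedParseError`.
    """
    iset = IntervalSet(set_id=set_id)
    ordinal = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                iset.n_dropped += 1
                continue
            iset.add(GenomicInterval(chrom=chrom, low=start, high=end - 1,
                                     uid=(set_id, ordinal), set_id=set_id))
            ordinal += 1
    return iset


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, os.PathLike]) -> None:
    """Write intervals as BED3 in their given order (half-open back-conversion)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.low}\t{iv.high + 1}\n")


def format_overlaps(records: List[OverlapRecord], emit_sources: bool = False) -> str:
    """Render overlap records as sorted BED text (see :func:`write_overlaps`)."""
    lines = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.low, r.high, r.sort_key())):
        cols = [rec.chrom, str(rec.low), str(rec.high + 1)]
        if emit_sources:
            cols.append(",".join(_uid_str(u) for u in rec.contributors))
        lines.append("\t".join(cols))
    return "".join(line + "\n" for line in lines)


def write_overlaps(records: List[OverlapRecord], path: Union[str, os.PathLike],
                   emit_sources: bool = False) -> None:
    """Write overlap records as BED, sorted by (chrom, start, end) for determinism.

    With ``emit_sources`` an extra column lists the contributing uid per input
    set, comma-separated in set order.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(format_overlaps(records, emit_sources=emit_sources))


def _uid_str(uid) -> str:
    if isinstance(uid, tuple):
        return ":".join(str(p) for p in uid)
    return str(uid)
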