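"""Semi-synthetic dataset generation.

Emulates the evaluation datasets: fixed-length intervals whose start
positions are sampled uniformly over human-genome-sized chromosomes, the
chromosome itself drawn with probability proportional to its length. The
default genome model carries hg19-scale lengths for the 24 nuclear
chromosomes; a UCSC-style chrom.sizes file can replace it.

Also provides an adversarial generator covering the input patterns the
engines must tolerate: nested chains, exact duplicates, shared endpoints,
adjacent-but-disjoint pairs, point intervals, shuffled order.

Seeds are mandatory; there is no hidden global randomness.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .bed_io import write_bed
from .intervals import GenomicInterval, IntervalSet

# hg19 nuclear chromosome lengths (bp)
HG19_CHROM_SIZES: Dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}


@dataclass(slots=True)
class GenomeModel:
    chrom_sizes: Dict[str, int] = field(default_factory=lambda: dict(HG19_CHROM_SIZES))

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("genome model needs at least one chromosome")
        for name, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_chrom_sizes(cls, path: Union[str, os.PathLike]) -> "GenomeModel":
        """Read a UCSC-style chrom.sizes file (name <tab> length)."""
        sizes: Dict[str, int] = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected name and length")
                sizes[fields[0]] = int(fields[1])
        return cls(chrom_sizes=sizes)


def generate_uniform_sets(n_files: int, n_intervals: int, interval_len: int = 500,
                          genome: Optional[GenomeModel] = None, seed: int = 0,
                          out_dir: Optional[Union[str, os.PathLike]] = None,
                          ) -> List[IntervalSet]:
    """Draw ``n_files`` sets of ``n_intervals`` fixed-length intervals.

    One NumPy generator stream, consumed file by file, makes the output a
    pure function of the arguments. With ``out_dir`` each set is also written
    as ``set_<i>.bed``.
    """
    if n_files < 1 or n_intervals < 0:
        raise ValueError("n_files must be >= 1 and n_intervals >= 0")
    if interval_len < 1:
        raise ValueError("interval_len must be >= 1")
    genome = genome or GenomeModel()
    names = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in names], dtype=np.int64)
    if interval_len > int(lengths.max()):
        raise ValueError("interval_len exceeds every chromosome length")
    usable = lengths >= interval_len
    weights = np.where(usable, lengths, 0).astype(np.float64)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    sets: List[IntervalSet] = []
    for set_id in range(n_files):
        chrom_idx = rng.choice(len(names), size=n_intervals, p=weights)
        starts = rng.integers(0, lengths[chrom_idx] - interval_len + 1)
        iset = IntervalSet(set_id=set_id)
        for ordinal, (ci, start) in enumerate(zip(chrom_idx, starts)):
            chrom = names[ci]
            s = int(start)
            iset.add(GenomicInterval(chrom=chrom, low=s, high=s + interval_len - 1,
                                     uid=(set_id, ordinal), set_id=set_id))
        sets.append(iset)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for iset in sets:
            ivs = [iv for c in sorted(iset.per_chrom) for iv in iset.per_chrom[c]]
            write_bed(ivs, os.path.join(out_dir, f"set_{iset.set_id}.bed"))
    return sets


def generate_adversarial(seed: int, size: int, set_id: int = 0,
                         chroms: Sequence[str] = ("chr1", "chr2"),
                         span: int = 50_000) -> IntervalSet:
    """A deliberately nasty interval set, shuffled out of coordinate order.

    Always contains at least one fully nested pair, an exact duplicate pair,
    a shared-endpoint pair, an adjacent-but-disjoint pair and a point
    interval; the remainder is random short intervals.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    spans: List[tuple] = []
    chrom0 = chroms[0]
    base = int(rng.integers(1_000, 10_000))
    # nested chain
    for k in range(4):
        spans.append((chrom0, base + 10 * k, base + 400 - 10 * k))
    dup_lo = base + 500
    spans.append((chrom0, dup_lo, dup_lo + 99))          # duplicates
    spans.append((chrom0, dup_lo, dup_lo + 99))
    spans.append((chrom0, dup_lo + 50, dup_lo + 99))     # shared high endpoint
    spans.append((chrom0, dup_lo + 100, dup_lo + 150))   # adjacent to [.., dup_lo+99]
    spans.append((chrom0, base + 700, base + 700))       # point interval
    while len(spans) < size:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        lo = int(rng.integers(0, span))
        spans.append((chrom, lo, lo + int(rng.integers(0, 600))))
    spans = spans[:max(size, 9)]
    order = rng.permutation(len(spans))
    iset = IntervalSet(set_id=set_id)
    for ordinal, idx in enumerate(order):
        chrom, lo, hi = spans[int(idx)]
        iset.add(GenomicInterval(chrom=chrom, low=lo, high=hi,
                                 uid=(set_id, ordinal), set_id=set_id))
    return iset


def generate_fixture_suite(seed: int, n_fixtures: int = 100) -> List[List[IntervalSet]]:
    """Seeded multi-set fixtures for engine-vs-oracle comparisons.

    Each fixture is a list of 2..16 interval sets, each up to 2,000 intervals,
    alternating between dense uniform draws over a small genome (so real
    overlaps occur) and adversarial sets (nesting, duplicates, shared
    endpoints, shuffling). Sizes are skewed small so a whole suite stays
    desk-scale.
    """
    rng = np.random.default_rng(seed)
    dense = GenomeModel(chrom_sizes={"chr1": 2_000_000, "chr2": 1_000_000})
    fixtures: List[List[IntervalSet]] = []
    for _ in range(n_fixtures):
        n_sets = int(2 + np.floor(14 * rng.random() ** 3))   # skewed toward 2-4
        # per-set cap keeps the per-tuple record count from growing
        # geometrically across many-set fixtures
        cap = min(2000, max(15, 5000 // n_sets))
        sets: List[IntervalSet] = []
        for k in range(n_sets):
            size = int(10 + np.floor((cap - 10) * rng.random() ** 2))
            if rng.random() < 0.5:
                s = generate_uniform_sets(1, size, interval_len=500, genome=dense,
                                          seed=int(rng.integers(0, 2**31)))[0]
                s.set_id = k
                for chrom in s.per_chrom:
                    for iv in s.per_chrom[chrom]:
                        iv.set_id = k
                        iv.uid = (k,) + tuple(iv.uid[1:])
            else:
                s = generate_adversarial(int(rng.integers(0, 2**31)), size,
                                         set_id=k, span=1_000_000)
            sets.append(s)
        fixtures.append(sets)
    return fixtures
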