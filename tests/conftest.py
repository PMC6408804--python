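import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from joverlap.intervals import GenomicInterval, IntervalSet

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_intervals(spans, chrom="chr1", set_id=0):
    """Build GenomicIntervals from (low, high) pairs, uids in input order."""
    return [GenomicInterval(chrom=chrom, low=lo, high=hi, uid=(set_id, i), set_id=set_id)
            for i, (lo, hi) in enumerate(spans)]


def make_set(spans_by_chrom, set_id=0):
    """Build an IntervalSet from {chrom: [(low, high), ...]}."""
    iset = IntervalSet(set_id=set_id)
    ordinal = 0
    for chrom, spans in spans_by_chrom.items():
        for lo, hi in spans:
            iset.add(GenomicInterval(chrom=chrom, low=lo, high=hi,
                                     uid=(set_id, ordinal), set_id=set_id))
            ordinal += 1
    return iset


def random_spans(rng, n, span_max=10_000, len_max=600):
    lows = rng.integers(0, span_max, size=n)
    lens = rng.integers(0, len_max, size=n)
    return [(int(lo), int(lo + ln)) for lo, ln in zip(lows, lens)]


def check_canonical_invariants(tree):
    """Assert both canonical-subset conditions at every node."""
    if tree.root is None:
        return
    stack = [(tree.root, None)]
    while stack:
        node, parent = stack.pop()
        for g in node.canonical:
            assert g.low <= node.int_low and node.int_high <= g.high, \
                f"I(v) member does not contain Int(v) at [{node.int_low},{node.int_high}]"
            if parent is not None:
                assert not (g.low <= parent.int_low and parent.int_high <= g.high), \
                    "I(v) member contains the parent's span"
        if not node.is_leaf():
            assert node.left.int_low == node.int_low
            assert node.right.int_high == node.int_high
            assert node.left.int_high + 1 == node.right.int_low
            stack.append((node.left, node))
            stack.append((node.right, node))


def record_keys(records):
    """Multiset-comparable representation of overlap records."""
    return sorted((r.chrom, r.low, r.high, tuple(r.contributors)) for r in records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
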