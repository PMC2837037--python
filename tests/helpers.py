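"""Independent oracles and instance generators for the test suite."""

from itertools import combinations

import numpy as np


def covers(subset, span_start, span_end):
    """True iff ``subset`` is an overlap-chain cover of the span.

    A tiling path must cover [span_start, span_end) with each interval
    *overlapping* (sharing at least one base with) the prefix covered so
    far — merely abutting intervals do not form a valid chain.
    """
    reach = None
    for s, e in sorted(subset):
        if reach is None:
            if s > span_start:
                return False
        elif s >= reach:  # abutment or gap: chain broken
            return False
        reach = e if reach is None else max(reach, e)
        if reach >= span_end:
            return True
    return False


def minimum_cover_size(intervals):
    """Exhaustive minimum-cardinality interval cover of the union span.

    Brute force over subsets in increasing size; only for small instances
    (<= 12 intervals) whose union is a single connected span.
    """
    span_start = min(s for s, _ in intervals)
    span_end = max(e for _, e in intervals)
    for k in range(1, len(intervals) + 1):
        for subset in combinations(intervals, k):
            if covers(subset, span_start, span_end):
                return k
    raise AssertionError("connected instance must admit a cover")


def random_connected_intervals(rng: np.random.Generator, n: int):
    """A random set of n intervals forming one connected overlap component."""
    intervals = []
    start = 0
    end = int(rng.integers(5, 30))
    intervals.append((start, end))
    covered_end = end
    for _ in range(n - 1):
        s = int(rng.integers(0, covered_end))  # overlaps the covered prefix
        e = s + int(rng.integers(5, 40))
        intervals.append((s, e))
        covered_end = max(covered_end, e)
    return intervals
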