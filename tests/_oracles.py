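"""Independent brute-force oracles used to cross-check the vectorized
implementations. These deliberately share no code with the package: everything
is O(n^2) membership/counting over explicit base sets or pooled points."""

from __future__ import annotations

import numpy as np


def brute_ks_d(a, b) -> float:
    """Max |F_a - F_b| evaluated at every pooled sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def brute_overlap_bp(iv, others) -> int:
    """Total bp of [iv.start, iv.end) covered by the union of other intervals
    on the same chromosome, by explicit base enumeration."""
    covered = set()
    for o in others:
        if o.chrom != iv.chrom:
            continue
        lo, hi = max(iv.start, o.start), min(iv.end, o.end)
        covered.update(range(lo, hi))
    return len(covered)


def brute_overlap_fraction(a_intervals, b_intervals, min_bp=1) -> float:
    hits = sum(1 for iv in a_intervals
               if brute_overlap_bp(iv, b_intervals) >= min_bp)
    return hits / len(a_intervals)


def brute_min_overlap_fraction(a_intervals, b_intervals, threshold) -> float:
    overlaps = [brute_overlap_bp(iv, b_intervals) for iv in a_intervals]
    overlapping = [o for o in overlaps if o >= 1]
    return sum(1 for o in overlapping if o >= threshold) / len(overlapping)


def brute_venn_counts(reference, other_sets):
    counts = {}
    for iv in reference:
        key = tuple(brute_overlap_bp(iv, o) >= 1 for o in other_sets)
        counts[key] = counts.get(key, 0) + 1
    return counts


def brute_coverage_percent(iv, repeat_intervals) -> float:
    return 100.0 * brute_overlap_bp(iv, repeat_intervals) / (iv.end - iv.start)


def random_intervals(rng, n, chrom="chrT", max_pos=10_000, max_len=400):
    """Small random interval fixtures for oracle comparisons."""
    from bivdom import GenomicInterval
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
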