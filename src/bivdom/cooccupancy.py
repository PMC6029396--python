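"""Interval-set algebra for co-occupancy: bivalent (co-occupied) regions,
only-A / only-B islands, overlap fractions, multiway Venn counts and breadth
statistics.

A "co-occupied region" is a merged intersection segment of the two island
sets (not the union of the parent islands); overlap fractions count islands
of the stated reference set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GenomicInterval, RegionSet


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting sorted intervals."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, s.size):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_regions(regions: RegionSet, label: str | None = None) -> RegionSet:
    """Union-merge a region set (overlapping/abutting intervals coalesced)."""
    ivs = []
    for chrom, (s, e) in regions.by_chrom().items():
        ms, me = _merge_arrays(s, e)
        ivs.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me))
    return RegionSet(ivs, label=label if label is not None else regions.label,
                     layout=regions.layout)


def _intersect_arrays(sa, ea, sb, eb) -> tuple[np.ndarray, np.ndarray]:
    """Intersection segments of two merged, sorted interval arrays (two-pointer)."""
    out_s, out_e = [], []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def intersect_sets(a: RegionSet, b: RegionSet) -> RegionSet:
    """Maximal segments present in both sets, merged if abutting."""
    ivs = []
    b_arrays = b.by_chrom()
    for chrom, (sa, ea) in a.by_chrom().items():
        if chrom not in b_arrays:
            continue
        sa, ea = _merge_arrays(sa, ea)
        sb, eb = _merge_arrays(*b_arrays[chrom])
        cs, ce = _merge_arrays(*_intersect_arrays(sa, ea, sb, eb))
        ivs.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(cs, ce))
    label = f"{a.label}&{b.label}" if a.label and b.label else "intersection"
    return RegionSet(ivs, label=label, layout=a.layout or b.layout)


def _per_interval_overlap(regions: RegionSet, other: RegionSet) -> np.ndarray:
    """Total overlap bp of each interval in *regions* with the union of *other*."""
    other_merged = {c: _merge_arrays(s, e) for c, (s, e) in other.by_chrom().items()}
    out = np.zeros(len(regions), dtype=np.int64)
    cum: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, (s, e) in other_merged.items():
        lengths = e - s
        cum[chrom] = (s, e, np.concatenate([[0], np.cumsum(lengths)]))
    for i, iv in enumerate(regions):
        if iv.chrom not in cum:
            continue
        s, e, csum = cum[iv.chrom]
        lo = np.searchsorted(e, iv.start, side="right")
        hi = np.searchsorted(s, iv.end, side="left")
        if lo >= hi:
            continue
        total = csum[hi] - csum[lo]
        # trim the flanking partial overlaps
        total -= max(iv.start - s[lo], 0)
        total -= max(e[hi - 1] - iv.end, 0)
        out[i] = total
    return out


@dataclass
class CooccupancyResult:
    """Classification of two island sets into co-occupied and exclusive regions."""

    co_regions: RegionSet     # merged intersection segments
    a_only: RegionSet         # A islands with zero B overlap
    b_only: RegionSet
    a_overlap_bp: np.ndarray  # per-A-island total overlap with B
    b_overlap_bp: np.ndarray


def classify_regions(a: RegionSet, b: RegionSet) -> CooccupancyResult:
    """Split A and B into co-occupied segments and exclusive islands.

    An island overlapping the other set by >= 1 bp is excluded from the
    exclusive ("only") class.
    """
    co = intersect_sets(a, b)
    a_ov = _per_interval_overlap(a, b)
    b_ov = _per_interval_overlap(b, a)
    a_only = RegionSet([iv for iv, ov in zip(a.intervals, a_ov) if ov == 0],
                       label=f"{a.label}_only", layout=a.layout)
    b_only = RegionSet([iv for iv, ov in zip(b.intervals, b_ov) if ov == 0],
                       label=f"{b.label}_only", layout=b.layout)
    return CooccupancyResult(co_regions=co, a_only=a_only, b_only=b_only,
                             a_overlap_bp=a_ov, b_overlap_bp=b_ov)


def overlap_fraction(a: RegionSet, b: RegionSet, min_bp: int = 1) -> float:
    """Fraction of A islands overlapping B by at least ``min_bp`` total bases."""
    if len(a) == 0:
        raise ValueError("reference set is empty")
    ov = _per_interval_overlap(a, b)
    return float(np.count_nonzero(ov >= min_bp) / len(a))


def min_overlap_fraction(a: RegionSet, b: RegionSet, threshold: int = 1000) -> float:
    """Among A islands overlapping B at all, the fraction whose total overlap
    is at least ``threshold`` bp (inclusive)."""
    ov = _per_interval_overlap(a, b)
    overlapping = ov[ov >= 1]
    if overlapping.size == 0:
        raise ValueError("no overlapping islands")
    return float(np.count_nonzero(overlapping >= threshold) / overlapping.size)


def venn_counts(sets: list[RegionSet], reference: int = 0) -> dict[tuple[bool, ...], int]:
    """Count reference islands per presence/absence combination over the others.

    Keys are tuples of booleans, one per non-reference set in input order;
    each reference island lands in exactly one cell.
    """
    if len(sets) < 2:
        raise ValueError("venn_counts requires at least two sets")
    ref = sets[reference]
    others = [s for i, s in enumerate(sets) if i != reference]
    memberships = [(_per_interval_overlap(ref, o) >= 1) for o in others]
    counts: dict[tuple[bool, ...], int] = {}
    for i in range(len(ref)):
        key = tuple(bool(m[i]) for m in memberships)
        counts[key] = counts.get(key, 0) + 1
    return counts


def breadth_histogram(islands: RegionSet, bin_width: int = 1000,
                      max_bp: int = 10000) -> dict[tuple[int, int | None], int]:
    """Island length histogram; the final bin [max_bp, inf) is open-ended."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = list(range(0, max_bp + 1, bin_width))
    hist: dict[tuple[int, int | None], int] = {
        (edges[i], edges[i + 1]): 0 for i in range(len(edges) - 1)}
    hist[(max_bp, None)] = 0
    for iv in islands:
        L = iv.length
        if L >= max_bp:
            hist[(max_bp, None)] += 1
        else:
            lo = (L // bin_width) * bin_width
            hist[(lo, lo + bin_width)] += 1
    return hist
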