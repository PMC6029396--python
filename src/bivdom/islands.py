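"""SICER-style enriched-region ("island") calling under a Poisson background.

The genome is tiled into non-overlapping windows (default 200 bp). A window is
*eligible* when its tag count clears a Poisson tail threshold at the genome-wide
background rate. Islands are maximal runs of eligible windows allowing a bounded
number of intervening ineligible windows (the gap, default 400 bp = 2 windows).
Island significance is a Poisson tail on the island's total tag count against
the background expectation for its span, controlled across all candidate
islands by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GenomeLayout, GenomicInterval, RegionSet, TagCollection
from .stats import bh_fdr, min_eligible_count, poisson_sf


@dataclass(frozen=True)
class IslandCallingParams:
    """Island-calling parameters.

    window_size / gap_size / fdr follow the published broad-domain settings
    (200 bp windows, 400 bp gap, FDR 0.001); window_p0 is the window
    eligibility tail probability, fragment_shift half the assumed fragment
    length, redundancy_threshold the per-position per-strand duplicate cap,
    and effective_genome_fraction the mappable fraction of the genome.
    """

    window_size: int = 200
    gap_size: int = 400
    fdr: float = 0.001
    window_p0: float = 0.2
    fragment_shift: int = 75
    redundancy_threshold: int = 1
    effective_genome_fraction: float = 0.74

    def __post_init__(self):
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.gap_size < 0 or self.gap_size % self.window_size != 0:
            raise ValueError("gap_size must be a non-negative multiple of window_size")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 < self.window_p0 <= 1:
            raise ValueError("window_p0 must be in (0, 1]")
        if self.redundancy_threshold < 1:
            raise ValueError("redundancy_threshold must be >= 1")
        if not 0 < self.effective_genome_fraction <= 1:
            raise ValueError("effective_genome_fraction must be in (0, 1]")

    @property
    def gap_windows(self) -> int:
        return self.gap_size // self.window_size


@dataclass(frozen=True)
class Island:
    """A called enriched region with its score and significance."""

    interval: GenomicInterval
    tag_count: int
    score: float      # sum over eligible windows of -ln P(X >= count)
    p_value: float
    q_value: float

    def __post_init__(self):
        if self.q_value < self.p_value - 1e-12:
            raise ValueError("q_value must be >= p_value")


@dataclass
class IslandSet:
    islands: list[Island]
    layout: GenomeLayout
    params: IslandCallingParams
    n_candidates: int = 0
    lambda_window: float = field(default=0.0)

    def __len__(self):
        return len(self.islands)

    def __iter__(self):
        return iter(self.islands)

    def to_region_set(self, label: str = "islands") -> RegionSet:
        ivs = [
            GenomicInterval(isl.interval.chrom, isl.interval.start, isl.interval.end,
                            name=f"island{i}", score=isl.score)
            for i, isl in enumerate(self.islands)
        ]
        return RegionSet(ivs, label=label, layout=self.layout)


def preprocess_tags(tags: TagCollection, params: IslandCallingParams,
                    layout: GenomeLayout | None = None) -> TagCollection:
    """Deduplicate and shift tags.

    Per (position, strand), tags beyond ``redundancy_threshold`` are dropped;
    survivors are shifted +fragment_shift on the + strand and -fragment_shift
    on the - strand (toward the fragment midpoint), then clipped to chromosome
    bounds when a layout is given.
    """
    out = {}
    for chrom, (pos, strand) in tags.tags.items():
        is_minus = strand == "-"
        keys = pos * 2 + is_minus
        order = np.argsort(keys, kind="stable")
        sorted_keys = keys[order]
        # rank of each tag within its (position, strand) group
        boundaries = np.flatnonzero(np.diff(sorted_keys)) + 1
        group_starts = np.concatenate([[0], boundaries])
        group_ids = np.searchsorted(group_starts, np.arange(len(sorted_keys)),
                                    side="right") - 1
        rank_in_group = np.arange(len(sorted_keys)) - group_starts[group_ids]
        keep = rank_in_group < params.redundancy_threshold
        kept = order[keep]
        new_pos = pos[kept] + np.where(is_minus[kept], -params.fragment_shift,
                                       params.fragment_shift)
        if layout is not None and chrom in layout:
            new_pos = np.clip(new_pos, 0, layout[chrom] - 1)
        else:
            new_pos = np.maximum(new_pos, 0)
        out[chrom] = (new_pos, strand[kept])
    return TagCollection.from_arrays(out)


def window_counts(tags: TagCollection, layout: GenomeLayout,
                  window_size: int) -> dict[str, np.ndarray]:
    """Non-overlapping window tiling; each tag counted in exactly one window.

    The final window of each chromosome may be partial.
    """
    counts = {}
    for chrom, length in layout.sizes.items():
        n_windows = -(-length // window_size)
        pos = tags.positions(chrom)
        counts[chrom] = np.bincount(pos // window_size, minlength=n_windows)
    return counts


def background_lambda(library_size: int, layout: GenomeLayout,
                      params: IslandCallingParams) -> float:
    """Expected tags per window under the uniform background model."""
    return (library_size * params.window_size
            / (layout.total_length * params.effective_genome_fraction))


def _candidate_runs(eligible_idx: np.ndarray, gap_windows: int):
    """Group sorted eligible-window indices into runs joined across gaps of
    at most ``gap_windows`` intervening ineligible windows.

    Returns (first_window, last_window, first_pos, last_pos) arrays, where
    *_pos index into ``eligible_idx``.
    """
    if eligible_idx.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty, empty
    breaks = np.flatnonzero(np.diff(eligible_idx) - 1 > gap_windows)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [eligible_idx.size - 1]])
    return eligible_idx[starts], eligible_idx[ends], starts, ends


def call_islands(tags: TagCollection, layout: GenomeLayout,
                 params: IslandCallingParams = IslandCallingParams(),
                 preprocess: bool = True) -> IslandSet:
    """Call enriched islands from a TagCollection.

    Set ``preprocess=False`` when the tags are already deduplicated/shifted
    (or are simulated point tags with fragment_shift 0).
    """
    if layout.total_length == 0:
        raise ValueError("empty genome layout")
    if preprocess:
        tags = preprocess_tags(tags, params, layout)
    if tags.library_size == 0:
        return IslandSet([], layout, params, n_candidates=0, lambda_window=0.0)

    lam = background_lambda(tags.library_size, layout, params)
    threshold = min_eligible_count(lam, params.window_p0)
    w = params.window_size
    counts = window_counts(tags, layout, w)

    from scipy import stats as sps

    candidates: list[tuple[str, int, int, int, float, float]] = []
    for chrom, cvec in counts.items():
        eligible = np.flatnonzero(cvec >= threshold)
        first_w, last_w, first_pos, last_pos = _candidate_runs(
            eligible, params.gap_windows)
        if first_w.size == 0:
            continue
        # per-eligible-window -ln tail probabilities, accumulated once
        window_logp = -np.log(np.clip(
            sps.poisson.sf(cvec[eligible] - 1, lam), 1e-320, None))
        score_cum = np.concatenate([[0.0], np.cumsum(window_logp)])
        count_cum = np.concatenate([[0], np.cumsum(cvec)])
        starts = first_w * w
        ends = np.minimum((last_w + 1) * w, layout[chrom])
        tag_counts = count_cum[last_w + 1] - count_cum[first_w]
        scores = score_cum[last_pos + 1] - score_cum[first_pos]
        pvals = sps.poisson.sf(tag_counts - 1, lam * (ends - starts) / w)
        for i in range(first_w.size):
            candidates.append((chrom, int(starts[i]), int(ends[i]),
                               int(tag_counts[i]), float(scores[i]),
                               float(pvals[i])))

    if not candidates:
        return IslandSet([], layout, params, n_candidates=0, lambda_window=lam)
    pvals = np.array([c[5] for c in candidates])
    qvals = bh_fdr(pvals)
    islands = [
        Island(GenomicInterval(chrom, start, end), tag_count, score, p, float(q))
        for (chrom, start, end, tag_count, score, p), q in zip(candidates, qvals)
        if q < params.fdr
    ]
    islands.sort(key=lambda isl: (isl.interval.chrom, isl.interval.start))
    return IslandSet(islands, layout, params,
                     n_candidates=len(candidates), lambda_window=lam)
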