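"""Repeat-element enrichment: percent coverage of a repeat class/family/
subfamily within region sets, length- and chromosome-matched random-region
nulls, and ECDF/KS enrichment tests.

An observed percent-coverage ECDF shifted right of its matched-random null
means the repeat is systematically denser inside the regions than expected by
chance ("enrichment").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccupancy import _merge_arrays, _per_interval_overlap
from .core_io import GenomeLayout, GenomicInterval, RegionSet, RepeatAnnotation
from .stats import KsResult, ks_two_sample


@dataclass(frozen=True)
class RepeatSelector:
    """Selects repeats at one annotation level (exact, case-sensitive label)."""

    level: str   # class | family | subfamily
    value: str

    def __post_init__(self):
        if self.level not in RepeatAnnotation.LEVELS:
            raise ValueError(f"level must be one of {RepeatAnnotation.LEVELS}")
        if not self.value:
            raise ValueError("selector value must be non-empty")


def _selected_union(repeats: RepeatAnnotation, selector: RepeatSelector) -> RegionSet:
    selected = repeats.select(selector.level, selector.value)
    ivs = []
    for chrom, (s, e) in selected.by_chrom().items():
        ms, me = _merge_arrays(s, e)
        ivs.extend(GenomicInterval(chrom, int(a), int(b)) for a, b in zip(ms, me))
    return RegionSet(ivs, label=selected.label)


def repeat_coverage_percent(region: GenomicInterval, repeats: RepeatAnnotation,
                            selector: RepeatSelector) -> float:
    """Percent of region bases covered by the union of selected repeats."""
    union = _selected_union(repeats, selector)
    ov = _per_interval_overlap(RegionSet([region]), union)
    return float(100.0 * ov[0] / region.length)


def coverage_percent_sample(regions: RegionSet, repeats: RepeatAnnotation,
                            selector: RepeatSelector) -> np.ndarray:
    """Per-region percent coverage (vectorized over the whole set)."""
    union = _selected_union(repeats, selector)
    ov = _per_interval_overlap(regions, union)
    lengths = np.array([iv.length for iv in regions], dtype=float)
    return 100.0 * ov / lengths


def fraction_containing(regions: RegionSet, repeats: RepeatAnnotation,
                        selector: RepeatSelector, min_bp: int = 1) -> float:
    """Fraction of regions overlapping selected repeats by >= min_bp."""
    if len(regions) == 0:
        raise ValueError("regions is empty")
    union = _selected_union(repeats, selector)
    ov = _per_interval_overlap(regions, union)
    return float(np.count_nonzero(ov >= min_bp) / len(regions))


def sample_matched_random_regions(regions: RegionSet, layout: GenomeLayout,
                                  seed: int, n_reps: int = 1,
                                  excluded: RegionSet | None = None,
                                  max_retries: int = 1000) -> list[RegionSet]:
    """For each observed region, a random interval of identical length on the
    same chromosome, start uniform over valid positions; one RegionSet per rep.

    Regions overlapping ``excluded`` (e.g. assembly gaps) are rejected and
    resampled up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    excl = {c: _merge_arrays(s, e) for c, (s, e) in excluded.by_chrom().items()} \
        if excluded is not None else {}
    reps = []
    for rep in range(n_reps):
        ivs = []
        for iv in regions:
            limit = layout[iv.chrom] - iv.length
            if limit < 0:
                raise ValueError(
                    f"region length {iv.length} exceeds chromosome {iv.chrom}")
            for _ in range(max_retries):
                start = int(rng.integers(0, limit + 1))
                cand = GenomicInterval(iv.chrom, start, start + iv.length)
                if not excl:
                    break
                s, e = excl.get(iv.chrom, (np.empty(0), np.empty(0)))
                lo = np.searchsorted(e, cand.start, side="right")
                if lo >= len(s) or s[lo] >= cand.end:
                    break
            else:
                raise RuntimeError("could not place a matched random region")
            ivs.append(cand)
        reps.append(RegionSet(ivs, label=f"{regions.label}_random{rep}", layout=layout))
    return reps


@dataclass
class EnrichmentReport:
    observed: np.ndarray            # percent coverage per observed region
    null: np.ndarray                # percent coverage per matched random region
    ks: KsResult
    direction: str                  # "enrichment" | "depletion" | "none"
    fraction_containing_observed: float | None = None
    fraction_containing_null: float | None = None


def enrichment_ecdf_test(observed, null) -> EnrichmentReport:
    """KS comparison of observed vs matched-null percent-coverage ECDFs.

    Direction is "enrichment" when the observed ECDF lies below the null at
    the point of maximal difference (observed values shifted right / larger).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    ks = ks_two_sample(observed, null)
    if ks.direction < 0:
        direction = "enrichment"
    elif ks.direction > 0:
        direction = "depletion"
    else:
        direction = "none"
    return EnrichmentReport(observed=observed, null=null, ks=ks, direction=direction)


def repeat_enrichment(regions: RegionSet, repeats: RepeatAnnotation,
                      selector: RepeatSelector, layout: GenomeLayout,
                      seed: int, n_reps: int = 1) -> EnrichmentReport:
    """Full enrichment workflow: coverage at regions, matched random null
    (pooled across reps), KS test, and fraction-containing summaries."""
    observed = coverage_percent_sample(regions, repeats, selector)
    nulls = sample_matched_random_regions(regions, layout, seed=seed, n_reps=n_reps)
    null_cov = np.concatenate(
        [coverage_percent_sample(ns, repeats, selector) for ns in nulls])
    report = enrichment_ecdf_test(observed, null_cov)
    report.fraction_containing_observed = fraction_containing(regions, repeats, selector)
    report.fraction_containing_null = float(np.mean(
        [fraction_containing(ns, repeats, selector) for ns in nulls]))
    return report
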