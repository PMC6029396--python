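"""Genomic feature annotation: assign regions to promoter-TSS / TTS / exon /
intron / intergenic classes and to genes within a TSS distance window.

Classification is by region midpoint with precedence
promoter-TSS > TTS > exon > intron > intergenic, using strand-aware promoter
(-1000/+100 around the TSS) and TTS (-100/+1000 around the TES) windows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import GeneModel, GenomicInterval, RegionSet

FEATURE_CLASSES = ("promoter-TSS", "TTS", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class AnnotationParams:
    promoter_upstream: int = 1000      # bp upstream of TSS
    promoter_downstream: int = 100     # bp downstream of TSS
    tts_upstream: int = 100            # bp upstream of TES
    tts_downstream: int = 1000         # bp downstream of TES
    tss_assignment_distance: int = 10000

    def __post_init__(self):
        if self.promoter_upstream + self.promoter_downstream <= 0:
            raise ValueError("degenerate promoter window")
        if self.tts_upstream + self.tts_downstream <= 0:
            raise ValueError("degenerate TTS window")
        if self.tss_assignment_distance < 0:
            raise ValueError("tss_assignment_distance must be >= 0")


def _window_around(anchor: int, strand: str, upstream: int, downstream: int) -> tuple[int, int]:
    """Inclusive [lo, hi] genomic window extending upstream/downstream of an
    anchor base, respecting strand orientation."""
    if strand == "+":
        return anchor - upstream, anchor + downstream
    return anchor - downstream, anchor + upstream


def classify_feature(region: GenomicInterval, genes: list[GeneModel],
                     params: AnnotationParams = AnnotationParams()) -> str:
    """Feature class of a region's midpoint."""
    m = region.midpoint
    in_tts = in_exon = in_intron = False
    for g in genes:
        if g.chrom != region.chrom:
            continue
        lo, hi = _window_around(g.tss, g.strand,
                                params.promoter_upstream, params.promoter_downstream)
        if lo <= m <= hi:
            return "promoter-TSS"
        lo, hi = _window_around(g.tes, g.strand,
                                params.tts_upstream, params.tts_downstream)
        if lo <= m <= hi:
            in_tts = True
        span = g.span
        if span[0] <= m < span[1]:
            if any(s <= m < e for s, e in g.exons):
                in_exon = True
            else:
                in_intron = True
    if in_tts:
        return "TTS"
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    return "intergenic"


def annotation_summary(regions: RegionSet, genes: list[GeneModel],
                       params: AnnotationParams = AnnotationParams()) -> dict:
    """Counts and percentages of regions per feature class."""
    if len(regions) == 0:
        raise ValueError("regions is empty")
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for iv in regions:
        counts[classify_feature(iv, genes, params)] += 1
    n = len(regions)
    return {
        "n": n,
        "counts": counts,
        "percent": {cls: 100.0 * c / n for cls, c in counts.items()},
    }


def genes_with_mark_near_tss(regions: RegionSet, genes: list[GeneModel],
                             params: AnnotationParams = AnnotationParams()) -> set[str]:
    """Gene ids with >= 1 bp of some region within [TSS - d, TSS + d]
    (strand-independent distance, edge-inclusive)."""
    d = params.tss_assignment_distance
    out = set()
    arrays = regions.by_chrom()
    for g in genes:
        if g.chrom not in arrays:
            continue
        starts, ends = arrays[g.chrom]
        # a region [s, e) has a base within distance d of the TSS iff
        # s <= tss + d and e - 1 >= tss - d
        hit = (starts <= g.tss + d) & (ends - 1 >= g.tss - d)
        if hit.any():
            out.add(g.gene_id)
    return out
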