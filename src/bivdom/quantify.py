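"""Density quantification: RPKM/RPBM at regions, genes and fixed genome bins,
plus cohort density contrasts scored by the two-sample KS test.

RPKM = tags * 1e9 / (length_bp * library_size)   (reads per kb per million)
RPBM = tags * 1e6 / (length_bp * library_size)   (reads per base per million)
so RPKM = 1000 * RPBM exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeLayout, GeneModel, RegionSet, TagCollection
from .stats import KsResult, ks_two_sample

DENSITY_COLUMNS = ["id", "chrom", "start", "end", "length", "tag_count", "rpkm", "rpbm"]


def _density_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=DENSITY_COLUMNS)


def _rpkm(count: int, length: int, library_size: int) -> float:
    return count * 1e9 / (length * library_size)


def region_density(tags: TagCollection, regions: RegionSet) -> pd.DataFrame:
    """Per-region tag counts and RPKM/RPBM densities.

    A tag is counted in a region iff its position lies in [start, end).
    """
    if tags.library_size <= 0:
        raise ValueError("library_size must be > 0")
    rows = []
    for i, iv in enumerate(regions):
        c = tags.count_in(iv.chrom, iv.start, iv.end)
        rpkm = _rpkm(c, iv.length, tags.library_size)
        rows.append((iv.name or f"region{i}", iv.chrom, iv.start, iv.end,
                     iv.length, c, rpkm, rpkm / 1000.0))
    return _density_frame(rows)


def genome_bin_density(tags: TagCollection, layout: GenomeLayout,
                       bin_size: int = 2000) -> pd.DataFrame:
    """RPKM per fixed non-overlapping genome bin (default 2 kb)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if tags.library_size <= 0:
        raise ValueError("library_size must be > 0")
    rows = []
    for chrom, length in layout.sizes.items():
        n_bins = -(-length // bin_size)
        counts = np.bincount(tags.positions(chrom) // bin_size, minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, length)
        for b in range(n_bins):
            c = int(counts[b])
            L = int(ends[b] - starts[b])
            rpkm = _rpkm(c, L, tags.library_size)
            rows.append((f"{chrom}:{starts[b]}-{ends[b]}", chrom, int(starts[b]),
                         int(ends[b]), L, c, rpkm, rpkm / 1000.0))
    return _density_frame(rows)


def gene_expression_rpkm(rna_tags: TagCollection, genes: list[GeneModel]) -> pd.DataFrame:
    """Exon-model RPKM per gene: tags falling in any exon over total exonic bp."""
    if rna_tags.library_size <= 0:
        raise ValueError("library_size must be > 0")
    rows = []
    for g in genes:
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")
        c = sum(rna_tags.count_in(g.chrom, s, e) for s, e in g.exons)
        L = g.exonic_length
        span = g.span
        rpkm = _rpkm(c, L, rna_tags.library_size)
        rows.append((g.gene_id, g.chrom, span[0], span[1], L, c, rpkm, rpkm / 1000.0))
    return _density_frame(rows)


def quartile_partition(values) -> list[np.ndarray]:
    """Split indices into four rank-based groups (lowest quartile first).

    Group sizes differ by at most one (extra members go to the lowest
    quartiles); ties are broken by stable input order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError(f"quartile_partition requires n >= 4, got {n}")
    order = np.argsort(v, kind="stable")
    base, extra = divmod(n, 4)
    sizes = [base + (1 if i < extra else 0) for i in range(4)]
    groups, at = [], 0
    for s in sizes:
        groups.append(order[at:at + s])
        at += s
    return groups


def five_number_summary(values) -> dict[str, float]:
    v = np.sort(np.asarray(values, dtype=float))
    return {
        "min": float(v[0]),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.percentile(v, 50)),
        "q3": float(np.percentile(v, 75)),
        "max": float(v[-1]),
    }


@dataclass
class DensityContrast:
    """Per-set density summaries and all pairwise KS comparisons."""

    summaries: dict[str, dict[str, float]]       # set label -> five-number summary + n
    densities: dict[str, np.ndarray]             # set label -> per-region RPKM sample
    ks: dict[tuple[str, str], KsResult]          # (label_a, label_b) -> KS result


def region_set_density_contrast(tags: TagCollection,
                                region_sets: list[RegionSet]) -> DensityContrast:
    """Contrast per-region RPKM distributions across >= 2 region sets."""
    if len(region_sets) < 2:
        raise ValueError("need at least two region sets")
    labels, summaries, densities = [], {}, {}
    for i, rs in enumerate(region_sets):
        if len(rs) == 0:
            raise ValueError(f"region set {rs.label!r} is empty")
        label = rs.label or f"set{i}"
        table = region_density(tags, rs)
        d = table["rpkm"].to_numpy()
        summaries[label] = {"n": len(rs), **five_number_summary(d)}
        densities[label] = d
        labels.append(label)
    ks = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            ks[(labels[i], labels[j])] = ks_two_sample(densities[labels[i]],
                                                       densities[labels[j]])
    return DensityContrast(summaries=summaries, densities=densities, ks=ks)
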