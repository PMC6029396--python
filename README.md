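# bivdom

Analysis toolkit for **bivalent chromatin domains** — genomic regions that
simultaneously carry a repressive histone mark (e.g. H4K20me3, H3K9me3) and an
activating one (H3K4me3, H3K36me3) — as studied by ChIP-seq in embryonic stem
cells. The package is aimed at computational epigenomics work where the
questions are: where are the enriched domains, which domains are co-occupied
by two marks, is the co-occupancy physically real (sequential ChIP), how does
dual marking relate to RNA polymerase II pausing, and are repeat elements
over-represented inside co-marked regions.

Everything operates on plain-text genomic formats (BED, chrom.sizes,
bedGraph) and ships with a deterministic synthetic-data generator plus a
ground-truth manifest, so every statistic in the pipeline can be validated by
parameter-recovery experiments without any external data.

## What it computes

**Island calling.** Enriched regions are called SICER-style: the genome is
tiled into `w` = 200 bp windows; a window with tag count `c` is *eligible*
when `P(X ≥ c) < p₀` for `X ~ Poisson(λ_w)`, with
`λ_w = N·w / (G·f_eff)` (library size `N`, genome length `G`, effective
mappable fraction `f_eff`). Maximal runs of eligible windows, bridging at
most `g/w` = 2 ineligible windows (a 400 bp gap), form candidate islands. An
island's significance is the Poisson tail of its total tag count against the
background expectation for its span, and Benjamini–Hochberg FDR (threshold
0.001) controls the genome-wide island list.

**Co-occupancy algebra.** Intersection segments, exclusive ("only-A")
islands, overlap fractions over a stated reference set, multiway Venn
counts, breadth histograms, ≥1 kb overlap fractions.

**Density quantification.** RPKM (`tags·10⁹ / (length·library)`) and RPBM
(`tags·10⁶ / (length·library)`) at arbitrary regions, 2 kb genome bins, and
exon models; cohort contrasts scored by the two-sample Kolmogorov–Smirnov
test on per-region density ECDFs.

**Traveling index.** Per gene, `TI = promoter density / body density` with a
1 kb promoter bin centered on the TSS and the gene body extending from the
promoter-bin edge to the TES. `TI > 2` indicates promoter-proximal pausing
dominance; cohorts are compared by ECDF, KS, and fraction above threshold.

**reChIP validation.** Sequential-ChIP tag density contrasted against an
input control at co-marked vs single-mark regions, plus the percentage of
co-occupied regions overlapping reChIP peaks.

**Repeat enrichment.** Percent coverage of a repeat class/family/subfamily
inside regions versus length- and chromosome-matched random regions, tested
by KS with an explicit enrichment/depletion direction.

## Worked example

Simulate a two-mark experiment with a 30% dual / 40% H4K20me3-only /
30% H3K4me3-only design over 500 planted loci, call islands on both marks
independently, and classify:

```python
from bivdom import (SimulationConfig, MarkConfig, plant_loci, simulate_mark_tags,
                    call_islands, classify_regions, overlap_fraction,
                    IslandCallingParams)

config = SimulationConfig(
    seed=11,
    genome={"chrS": 20_000_000},
    n_loci=500,
    marks={"H4K20me3": MarkConfig(background_rate=0.0025, enrichment_fold=8.0),
           "H3K4me3": MarkConfig(background_rate=0.0025, enrichment_fold=8.0)},
    cooccupancy_design={frozenset({"H4K20me3", "H3K4me3"}): 0.30,
                        frozenset({"H4K20me3"}): 0.40,
                        frozenset({"H3K4me3"}): 0.30},
)
manifest = plant_loci(config)
params = IslandCallingParams(fragment_shift=0)  # simulated tags are points
islands = {}
for mark in config.marks:
    tags = simulate_mark_tags(manifest, mark)
    islands[mark] = call_islands(tags, config.layout, params).to_region_set(mark)
    print(f"{mark}: {tags.library_size} tags -> {len(islands[mark])} islands")

result = classify_regions(islands["H4K20me3"], islands["H3K4me3"])
frac = overlap_fraction(islands["H4K20me3"], islands["H3K4me3"])
print(f"co-occupied regions: {len(result.co_regions)}")
print(f"H4K20me3-only islands: {len(result.a_only)}")
print(f"fraction of H4K20me3 islands overlapping H3K4me3: {frac:.2f}")
```

Output:

```
H4K20me3: 62181 tags -> 360 islands
H3K4me3: 60332 tags -> 280 islands
co-occupied regions: 142
H4K20me3-only islands: 218
fraction of H4K20me3 islands overlapping H3K4me3: 0.39
```

350 loci carry H4K20me3 (the 0.30 + 0.40 design cells) and 360 islands are
called over them; the 150 planted dual loci yield 142 recovered co-occupied
regions, and 0.39 of H4K20me3 islands touch an H3K4me3 island (the design's
conditional dual fraction is 0.30/0.70 ≈ 0.43, minus islands lost to
sampling noise at this depth).

The same pipeline is scriptable from the shell:

```sh
bivdom simulate --seed 11 --out sim/
bivdom call-islands --tags sim/tags_A.bed --chrom-sizes sim/chrom.sizes \
    --fragment-shift 0 --out islands_A.bed
bivdom cooccupy --a islands_A.bed --b islands_B.bed --out co/
```

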