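# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `bivdom`.

## Coordinate and tag conventions

All coordinates are 0-based half-open (BED convention); 1-based inputs are
not accepted. A read contributes a single *tag* at its 5′ end: `start` for +
strand reads and `end − 1` for − strand reads (BED ends are exclusive).
Interval containers are kept sorted by (chrom, start, end) through every
construction path, and all readers/writers round-trip losslessly on valid
input. Repeat annotations accept two fixed RepeatMasker-export dialects,
auto-detected by column count: BED6 with a `class/family/subfamily`
slash-joined name, or an 8-column form with explicit class and family
columns.

## Island calling

The caller follows the windows → gaps → islands → FDR structure of
broad-domain callers, with the published broad-mark settings as defaults:
200 bp windows, 400 bp gap, FDR 0.001.

Model: tags under the null fall as a homogeneous Poisson process with
per-window mean `λ_w = N·w/(G·f_eff)`, where `N` is the (preprocessed)
library size, `G` total genome length and `f_eff` the effective mappable
fraction (default 0.74). Preprocessing caps duplicates at
`redundancy_threshold` (default 1) tags per position and strand and shifts
tags by `fragment_shift` (default 75 bp, half a 150 bp fragment) toward the
fragment midpoint.

A window is eligible when its count's Poisson tail is below `p₀ = 0.2`.
Candidate islands are maximal runs of eligible windows joined across at most
`gap/w` consecutive ineligible windows; gap windows are included in the span
and contribute zero score. The island score is the sum of `−ln P(X ≥ c)`
over its eligible windows. Island significance departs from the original
score-distribution E-value machinery deliberately: each candidate's p-value
is the Poisson tail of its total tag count against `λ_w · span/w`, and
Benjamini–Hochberg FDR across all candidates (no pre-filter, so the BH
denominator is well-defined) thresholds the final list. This keeps the
calling semantics exactly testable: on background-only simulations the mean
number of called islands stays below `fdr ×` the candidate count, and
monotonicity in `fdr` and `p₀` holds by construction.

No input-library subtraction is implemented; the caller runs in no-control
mode only.

## Density and the traveling index

RPKM = `tags·10⁹/(L·N)` and RPBM = `tags·10⁶/(L·N)`, so RPKM = 1000·RPBM
exactly; both are emitted everywhere since figure conventions vary. A tag on
a region boundary belongs to the region containing its point (half-open
partition). Gene expression uses exon-model RPKM (tags in any exon over
total exonic bp). Quartile splits are rank-based with stable tie-breaking so
group sizes are deterministic (`n mod 4` extra members go to the lowest
quartiles).

The traveling index of a gene is the ratio of RNAPII RPBM in a promoter bin
to RPBM in the gene body. The promoter bin is *centered* on the TSS
(TSS ± 500 bp) — a "1 kb window around the TSS" does not pin down the
centering, so centered is adopted and exposed as a parameter. The body runs
from the promoter-bin edge toward the TES; genes with body shorter than
1 kb, zero body tags, or no promoter signal (fewer than
`min_promoter_tags = 1`, the operationalization of "marked by RNAPII") are
excluded with a recorded reason rather than erroring or receiving a
pseudocount — the TI is simply undefined there, and exclusions are data.
Whether the body should instead start at the TSS is genuinely open; the
promoter-edge convention avoids TI deflation from promoter tags leaking into
the body and is declared, not inferred.

## Statistics

Poisson tails go through the regularized incomplete gamma function (stable
for the λ ≪ 1 rates of 200 bp windows). BH-FDR is the exact step-up
`q_i = min_{p_j ≥ p_i} n·p_j/rank_j`, clipped at 1. The two-sample KS
statistic D is the exact supremum of |F_a − F_b| over pooled sample points;
the p-value uses the asymptotic Kolmogorov distribution at `√(n_eff)·D`
with `n_eff = n_a·n_b/(n_a+n_b)` — no exact small-sample enumeration, so
tests with n < 10 assert D only. The two-sided variant is used throughout,
with the direction (sign of F_a − F_b at the maximizing point) reported
separately so enrichment/depletion calls are explicit.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes, with a ground-truth manifest sufficient to compute the expected
value of every downstream statistic:

* **ChIP tags**: homogeneous Poisson background at `background_rate`
  (default 0.005 tags/bp ≈ realistic 10×-coverage tag density scaled to the
  synthetic genome), multiplied by `enrichment_fold` (default 8) inside loci
  carrying the mark. Positions are iid uniform; counts Poisson; strands
  random.
* **Loci**: sampled uniformly without overlap by rejection (1000-retry
  bound; uniform conditional on feasibility), lengths uniform in
  1.5–2.5 kb — the few-kb breadth scale typical of broad domains. Each locus
  draws its mark combination independently from the co-occupancy design, so
  planted cell counts are binomial around the design proportions.
* **RNAPII**: per gene with cohort ratio `r` and body rate `b`, the promoter
  bin (TSS ± 500 bp) receives rate `r·b` and the body rate `b`, so `r` *is*
  the true traveling index.
* **reChIP**: enrichment only at loci carrying both assayed marks
  (`dual_fold`), with single-mark loci at `single_fold` (default 1 =
  background) — the defining property of a sequential ChIP.
* **Repeats**: a genome-wide uniform process tuned to `target_density`
  coverage plus an extra process inside co-marked loci raising coverage to
  `density_inside_comarked`.

Randomness: one mandatory seed; per-purpose sub-streams are derived by
CRC-32 hashing of stable names ("mark"/"rechip"/"loci"/…), so adding a mark
never shifts another mark's draws and every artifact is byte-identical
across runs. Tags are points: fragment-length, mappability, GC and replicate
structure are *not* simulated, so pipeline runs on synthetic data use
`fragment_shift = 0`, and passing recovery tests demonstrate correctness of
the computations, not robustness to real-data artifacts.

## Validation experiments (workflows module)

Problem sizes are chosen so each experiment finishes in seconds on one CPU
while keeping the statistical targets meaningful:

* Null calibration: 20 background-only genomes (10 Mb, 10⁵ tags).
* Island recovery: 50 planted 2 kb fold-8 loci, ~40 expected tags each
  (recall ≥ 0.95, precision ≥ 0.90).
* Co-occupancy recovery: 500 loci under a 0.30/0.40/0.30 design on 20 Mb;
  the recovered dual fraction is the fraction of planted loci overlapping a
  co-occupied segment after independent island calling on both marks.
* TI recovery: cohorts of 300 genes (11–13 kb) at true ratios 1/1.5/2/6
  with body rate 0.02 tags/bp (≥ 200 expected body tags per gene).
* Repeat enrichment: 1000 co-marked loci with inside coverage 0.30 vs 0.10
  genome-wide for power; 100 seeds of uniform planting for calibration. The
  per-locus effect is lumpy (a 2 kb locus gains a whole repeat or none), so
  power at small region counts is limited by design.
* reChIP: 200 loci per class on a 200 Mb genome at 0.02 tags/bp. The genome
  is deliberately large relative to the domains: reChIP enrichment mass
  inflates the reChIP library, and per-million normalization alone shifts
  background RPKM by that fraction. Two further subtleties make the
  single-mark "null" honest: locus lengths are varied (identical lengths
  put RPKM on an integer lattice, where *any* library-size difference
  offsets the two staircases and KS reports D ≈ the largest count
  probability), and the enrichment mass is kept below ~1% of the library so
  the residual shift is far below KS resolution at n = 200.

## Annotation

Region midpoints are classified with precedence promoter-TSS > TTS > exon >
intron > intergenic, using HOMER-like strand-aware windows (promoter
−1000/+100 around the TSS, TTS −100/+1000 around the TES; the tool that
inspired them does not publish exact settings, so these are defaults, not a
reproduction). UTR and non-coding subclasses are collapsed into exon.
Gene-to-mark assignment uses a strand-independent, edge-inclusive ±10 kb TSS
window.

## Matched random regions

For each observed region the null draws an interval of identical length on
the same chromosome with a uniform start; GC content and gap structure are
not matched (synthetic genomes have neither; for real genomes an exclusion
BED can be supplied, with rejected-and-resampled draws). One matched set per
observed set by default, pooled across replicates when more are requested.

## Known limitations

* No control-library subtraction or replicate handling in the caller.
* The KS p-value is asymptotic; at very small n it is conservative.
* The annotation percentages depend on the promoter/TTS window defaults;
  external published percentages are not expected to reproduce exactly.
* The generator's uniform-background model contains no chromatin
  accessibility or copy-number structure, so calibration results bound
  false-discovery behavior only under the stated Poisson null.
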