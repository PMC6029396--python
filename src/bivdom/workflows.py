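"""Canned simulation studies: end-to-end workflows that generate synthetic
data under a declared design, run the pipeline, and measure how well the
planted truth is recovered.

These are the package's self-validation experiments (null calibration of the
island caller, island/co-occupancy recovery, traveling-index parameter
recovery, repeat-enrichment power and calibration, reChIP specificity). Each
function takes a seed and returns a flat dict of measured quantities.

Simulated tags are points, so the pipeline runs with fragment_shift=0
throughout these studies.
"""

from __future__ import annotations

import numpy as np

from .cooccupancy import classify_regions, overlap_fraction
from .core_io import GenomicInterval, RegionSet
from .islands import IslandCallingParams, call_islands
from .rechip import rechip_contrast, rechip_peak_overlap
from .repeats import RepeatSelector, repeat_enrichment
from .synthetic import (MarkConfig, RechipConfig, RepeatFamilyConfig,
                        RnapiiCohortConfig, RnapiiConfig, SimulationConfig,
                        plant_loci, simulate_input_tags, simulate_mark_tags,
                        simulate_rechip_tags, simulate_rnapii_tags)
from .traveling_index import ti_cohort_compare, ti_table

NOSHIFT = IslandCallingParams(fragment_shift=0)


def printed_counts_overlap_percent(n_overlapping: int = 7729,
                                   n_reference: int = 8224) -> float:
    """Overlap percentage implied by printed island counts, recomputed by
    building a region configuration with exactly those counts and running
    overlap_fraction on it."""
    step = 3000
    ref, other = [], []
    for i in range(n_reference):
        start = i * step
        ref.append(GenomicInterval("chrW", start, start + 1000))
        if i < n_overlapping:
            other.append(GenomicInterval("chrW", start + 500, start + 1500))
    frac = overlap_fraction(RegionSet(ref, label="reference"),
                            RegionSet(other, label="other"))
    return 100.0 * frac


def island_null_calibration(seed: int, n_seeds: int = 20,
                            genome_bp: int = 10_000_000,
                            n_tags: int = 100_000) -> dict:
    """Background-only simulations (fold 1): the mean number of called
    islands should not exceed fdr * mean candidate count."""
    rate = n_tags / genome_bp
    called, candidates = [], []
    for i in range(n_seeds):
        config = SimulationConfig(
            seed=seed + i, genome={"chrS": genome_bp}, n_loci=10,
            marks={"A": MarkConfig(background_rate=rate, enrichment_fold=1.0)},
            cooccupancy_design={frozenset("A"): 1.0})
        manifest = plant_loci(config)
        tags = simulate_mark_tags(manifest, "A")
        result = call_islands(tags, config.layout, NOSHIFT)
        called.append(len(result))
        candidates.append(result.n_candidates)
    return {
        "mean_called": float(np.mean(called)),
        "mean_candidates": float(np.mean(candidates)),
        "fdr": NOSHIFT.fdr,
        "bound": NOSHIFT.fdr * float(np.mean(candidates)),
    }


def island_recovery(seed: int, n_loci: int = 50, fold: float = 8.0,
                    genome_bp: int = 10_000_000,
                    background_rate: float = 0.0025) -> dict:
    """Recall/precision of island calling against planted fold-enriched loci
    (>= 1 bp overlap counts as a hit)."""
    config = SimulationConfig(
        seed=seed, genome={"chrS": genome_bp}, n_loci=n_loci,
        locus_length_range=(2000, 2000),
        marks={"A": MarkConfig(background_rate, fold)},
        cooccupancy_design={frozenset("A"): 1.0})
    manifest = plant_loci(config)
    tags = simulate_mark_tags(manifest, "A")
    called = call_islands(tags, config.layout, NOSHIFT).to_region_set("called")
    truth = manifest.region_set("A", label="truth")
    recall = overlap_fraction(truth, called) if len(called) else 0.0
    precision = overlap_fraction(called, truth) if len(called) else 0.0
    return {"recall": float(recall), "precision": float(precision),
            "n_called": len(called), "n_planted": len(truth)}


def cooccupancy_recovery(seed: int, n_loci: int = 500,
                         genome_bp: int = 20_000_000,
                         background_rate: float = 0.0025,
                         fold: float = 8.0) -> dict:
    """Plant a {dual: 0.30, A-only: 0.40, B-only: 0.30} design, call islands
    independently per mark, classify, and measure the fraction of planted
    loci recovered as co-occupied."""
    config = SimulationConfig(
        seed=seed, genome={"chrS": genome_bp}, n_loci=n_loci,
        locus_length_range=(1500, 2500),
        marks={"A": MarkConfig(background_rate, fold),
               "B": MarkConfig(background_rate, fold)},
        cooccupancy_design={frozenset("AB"): 0.30, frozenset("A"): 0.40,
                            frozenset("B"): 0.30})
    manifest = plant_loci(config)
    layout = config.layout
    a_islands = call_islands(simulate_mark_tags(manifest, "A"), layout,
                             NOSHIFT).to_region_set("A")
    b_islands = call_islands(simulate_mark_tags(manifest, "B"), layout,
                             NOSHIFT).to_region_set("B")
    co = classify_regions(a_islands, b_islands).co_regions
    all_loci = manifest.region_set(label="planted")
    recovered_dual = overlap_fraction(all_loci, co)
    planted_dual = len(manifest.loci_with(["A", "B"])) / len(manifest.loci)
    return {
        "recovered_dual_fraction": float(recovered_dual),
        "planted_dual_fraction": float(planted_dual),
        "design_dual_proportion": 0.30,
        "n_co_regions": len(co),
    }


def ti_recovery(seed: int, genes_per_cohort: int = 300,
                ratios: tuple = (1.0, 1.5, 2.0, 6.0),
                body_rate: float = 0.02) -> dict:
    """Traveling-index parameter recovery over gene cohorts with known
    promoter:body ratios, plus the KS separation of the extreme cohorts."""
    cohorts = tuple(RnapiiCohortConfig(f"r{r:g}", r, genes_per_cohort)
                    for r in ratios)
    n = genes_per_cohort * len(ratios)
    config = SimulationConfig(
        seed=seed, genome={"chrS": max(40_000_000, n * 32_000)},
        n_loci=0, marks={}, cooccupancy_design={},
        n_genes=n, gene_length_range=(11_000, 13_000),
        rnapii_config=RnapiiConfig(cohorts=cohorts, body_rate=body_rate,
                                   background_rate=0.0002))
    manifest = plant_loci(config)
    tags, _ = simulate_rnapii_tags(manifest)
    by_cohort: dict[str, list] = {c.name: [] for c in cohorts}
    for g in manifest.genes:
        by_cohort[manifest.gene_truth[g.gene_id][0]].append(g)

    out: dict = {"ratios": ratios}
    medians, fractions = {}, {}
    for r in ratios:
        tab = ti_table(tags, by_cohort[f"r{r:g}"])
        included = tab[tab["included"]]
        medians[r] = float(included["ti"].median())
        fractions[r] = float((included["ti"] > 2.0).mean())
    out["median_ti"] = medians
    out["fraction_above_2"] = fractions
    cmp_ = ti_cohort_compare(tags, by_cohort["r6"], by_cohort["r1.5"])
    out["ks_p_r6_vs_r1.5"] = cmp_.ks.p_value
    out["ks_d_r6_vs_r1.5"] = cmp_.ks.d
    return out


_LINE = RepeatSelector(level="class", value="LINE")


def _repeat_config(seed, inside, n_loci, genome_bp=30_000_000):
    return SimulationConfig(
        seed=seed, genome={"chrS": genome_bp}, n_loci=n_loci,
        locus_length_range=(2000, 2000),
        marks={"A": MarkConfig(0.0025, 8.0), "B": MarkConfig(0.0025, 8.0)},
        cooccupancy_design={frozenset("AB"): 1.0},
        repeat_config=(RepeatFamilyConfig("LINE", "L1", "L1Md_T",
                                          target_density=0.10,
                                          density_inside_comarked=inside),))


def repeat_enrichment_power(seed: int, n_loci: int = 1000,
                            inside_density: float = 0.30) -> dict:
    """Power: repeats planted 3x denser inside co-marked loci must be
    reported as enrichment with a very small KS p-value."""
    config = _repeat_config(seed, inside_density, n_loci)
    manifest = plant_loci(config)
    regions = manifest.region_set(["A", "B"], label="dual")
    report = repeat_enrichment(regions, manifest.repeats, _LINE,
                               config.layout, seed=seed)
    return {
        "direction": report.direction,
        "ks_p": report.ks.p_value,
        "ks_d": report.ks.d,
        "fraction_containing_observed": report.fraction_containing_observed,
        "fraction_containing_null": report.fraction_containing_null,
    }


def repeat_enrichment_calibration(seed: int, n_seeds: int = 100,
                                  n_loci: int = 200, alpha: float = 0.01) -> dict:
    """Calibration: with uniform planting (no enrichment) the test should
    reject at level alpha in roughly alpha of seeded runs."""
    rejections = 0
    for i in range(n_seeds):
        config = _repeat_config(seed + i, inside=0.10, n_loci=n_loci,
                                genome_bp=10_000_000)
        manifest = plant_loci(config)
        regions = manifest.region_set(["A", "B"], label="dual")
        report = repeat_enrichment(regions, manifest.repeats, _LINE,
                                   config.layout, seed=seed + i)
        if report.ks.p_value < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_seeds, "alpha": alpha,
            "n_seeds": n_seeds}


def rechip_validation(seed: int, loci_per_class: int = 200,
                      genome_bp: int = 200_000_000,
                      dual_fold: float = 5.0,
                      background_rate: float = 0.02) -> dict:
    """reChIP specificity: significant reChIP-vs-input contrast at co-marked
    regions, background at single-mark regions, and high overlap of
    co-occupied regions with reChIP peaks.

    The genome is large relative to the planted domains so the reChIP
    enrichment mass is a sub-percent fraction of the library, as in real
    data; otherwise per-million normalization alone shifts the background
    RPKM distribution detectably.
    """
    config = SimulationConfig(
        seed=seed, genome={"chrS": genome_bp}, n_loci=3 * loci_per_class,
        locus_length_range=(1500, 2500),
        marks={"A": MarkConfig(background_rate, 8.0),
               "B": MarkConfig(background_rate, 8.0)},
        cooccupancy_design={frozenset("AB"): 1 / 3, frozenset("A"): 1 / 3,
                            frozenset("B"): 1 / 3},
        rechip_config=RechipConfig(background_rate=background_rate,
                                   dual_fold=dual_fold))
    manifest = plant_loci(config)
    layout = config.layout
    re_tags = simulate_rechip_tags(manifest, "A", "B")
    in_tags = simulate_input_tags(manifest)
    sets = {
        "co_marked": manifest.region_set(["A", "B"], label="co_marked"),
        "a_only": manifest.region_set("A", exact=True, label="a_only"),
        "b_only": manifest.region_set("B", exact=True, label="b_only"),
    }
    report = rechip_contrast(re_tags, in_tags, sets)

    a_islands = call_islands(simulate_mark_tags(manifest, "A"), layout,
                             NOSHIFT).to_region_set("A")
    b_islands = call_islands(simulate_mark_tags(manifest, "B"), layout,
                             NOSHIFT).to_region_set("B")
    co = classify_regions(a_islands, b_islands).co_regions
    rechip_islands = call_islands(re_tags, layout, NOSHIFT).to_region_set("re")
    overlap = rechip_peak_overlap(co, rechip_islands) if len(co) else 0.0
    return {
        "ks_p_co_marked": report.ks["co_marked"].p_value,
        "ks_p_a_only": report.ks["a_only"].p_value,
        "ks_p_b_only": report.ks["b_only"].p_value,
        "peak_overlap_percent": float(overlap),
        "n_co_regions": len(co),
    }
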