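"""Synthetic genomes, gene models, repeats and ChIP/reChIP/RNAPII tag sets.

The generator emulates the statistical structure the analysis assumes:

* background reads as a homogeneous Poisson process over the genome;
* enriched loci where the rate is multiplied by a per-mark fold;
* a co-occupancy design assigning each planted locus a mark combination;
* RNAPII read profiles with a configurable promoter:body density ratio per
  gene cohort (the quantity the traveling index estimates);
* reChIP reads enriched only at loci carrying both assayed marks;
* repeat elements placed denser inside co-marked loci than genome-wide.

Everything is deterministic given the config seed; per-purpose RNG sub-streams
are derived by stable hashing so adding a mark never shifts another mark's
draws. Tags are points (read 5' ends); fragment-length effects are not
simulated.
"""

from __future__ import annotations

import bisect
import zlib
from dataclasses import dataclass, field

import numpy as np

from .core_io import (GenomeLayout, GenomicInterval, GeneModel, RegionSet,
                      RepeatAnnotation, RepeatElement, TagCollection)

_MAX_PLACEMENT_RETRIES = 1000


@dataclass(frozen=True)
class MarkConfig:
    """Per-mark simulation parameters."""

    background_rate: float = 0.005   # tags per bp genome-wide
    enrichment_fold: float = 8.0     # rate multiplier inside loci carrying the mark

    def __post_init__(self):
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")


@dataclass(frozen=True)
class RepeatFamilyConfig:
    """Placement targets for one repeat subfamily.

    Densities are expected fractions of bases covered; inside co-marked loci
    the density may differ from the genome-wide target.
    """

    repeat_class: str
    family: str
    subfamily: str
    target_density: float = 0.10
    density_inside_comarked: float = 0.10
    length_range: tuple[int, int] = (500, 3000)


@dataclass(frozen=True)
class RnapiiCohortConfig:
    """One gene cohort with a true promoter:body density ratio r."""

    name: str
    ratio: float          # promoter-bin rate = ratio * body_rate
    n_genes: int


@dataclass(frozen=True)
class RnapiiConfig:
    cohorts: tuple[RnapiiCohortConfig, ...] = ()
    body_rate: float = 0.02            # tags per bp in gene bodies
    promoter_halfwidth: int = 500      # promoter bin = TSS +/- halfwidth
    background_rate: float = 0.0005    # intergenic rate


@dataclass(frozen=True)
class RechipConfig:
    background_rate: float = 0.005
    dual_fold: float = 10.0    # fold at loci carrying BOTH assayed marks
    single_fold: float = 1.0   # fold at loci carrying exactly one of them

    def __post_init__(self):
        if self.dual_fold < 1 or self.single_fold < 1:
            raise ValueError("reChIP folds must be >= 1")


@dataclass
class SimulationConfig:
    """Full study design for one synthetic experiment."""

    seed: int
    genome: dict[str, int] = field(default_factory=lambda: {"chrS": 20_000_000})
    n_loci: int = 500
    locus_length_range: tuple[int, int] = (1500, 2500)
    marks: dict[str, MarkConfig] = field(default_factory=dict)
    # mark-combination (frozenset of mark names) -> proportion of loci
    cooccupancy_design: dict[frozenset, float] = field(default_factory=dict)
    repeat_config: tuple[RepeatFamilyConfig, ...] = ()
    rnapii_config: RnapiiConfig = field(default_factory=RnapiiConfig)
    rechip_config: RechipConfig = field(default_factory=RechipConfig)
    n_genes: int = 0
    gene_length_range: tuple[int, int] = (8000, 12000)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.cooccupancy_design.values())
        if total > 1 + 1e-9:
            raise ValueError(f"cooccupancy proportions sum to {total} > 1")
        for combo in self.cooccupancy_design:
            unknown = set(combo) - set(self.marks)
            if unknown:
                raise ValueError(f"design names unknown marks {unknown}")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout(dict(self.genome))


def _stream(seed: int, *names: str) -> np.random.Generator:
    """Derive a named RNG sub-stream; stable across runs and mark additions."""
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass
class TruthManifest:
    """Ground truth for one simulated experiment.

    ``loci`` carry mark-combination labels; ``gene_truth`` maps gene_id ->
    (cohort name, true promoter:body ratio). Downstream recovery tests consume
    only this object.
    """

    config: SimulationConfig
    loci: list[GenomicInterval]
    locus_labels: list[frozenset]
    genes: list[GeneModel] = field(default_factory=list)
    gene_truth: dict[str, tuple[str, float]] = field(default_factory=dict)
    repeats: RepeatAnnotation = field(default_factory=lambda: RepeatAnnotation([]))

    def loci_with(self, marks, exact: bool = False) -> list[GenomicInterval]:
        """Planted loci whose label contains (or equals, if exact) the mark set."""
        want = frozenset([marks]) if isinstance(marks, str) else frozenset(marks)
        out = []
        for iv, label in zip(self.loci, self.locus_labels):
            if (label == want) if exact else (want <= label):
                out.append(iv)
        return out

    def comarked_loci(self) -> list[GenomicInterval]:
        """Loci carrying at least two marks."""
        return [iv for iv, lab in zip(self.loci, self.locus_labels) if len(lab) >= 2]

    def region_set(self, marks=None, exact: bool = False, label: str = "truth") -> RegionSet:
        ivs = self.loci if marks is None else self.loci_with(marks, exact=exact)
        return RegionSet(ivs, label=label, layout=self.config.layout)


def _place_nonoverlapping(rng: np.random.Generator, genome: dict[str, int],
                          lengths: np.ndarray) -> list[GenomicInterval]:
    """Uniform rejection-sampled placement of non-overlapping intervals."""
    chroms = list(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=float)
    if lengths.sum() >= 0.5 * sizes.sum():
        raise ValueError("requested locus length exceeds 50% of the genome")
    weights = sizes / sizes.sum()
    # sorted start/end lists per chromosome for O(log n) overlap checks
    occ_starts: dict[str, list[int]] = {c: [] for c in chroms}
    occ_ends: dict[str, list[int]] = {c: [] for c in chroms}
    placed = []
    for length in lengths.tolist():
        for attempt in range(_MAX_PLACEMENT_RETRIES):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            limit = genome[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            ss, es = occ_starts[chrom], occ_ends[chrom]
            i = bisect.bisect_left(ss, start)
            clash = (i < len(ss) and ss[i] < end) or (i > 0 and es[i - 1] > start)
            if not clash:
                ss.insert(i, start)
                es.insert(i, end)
                placed.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place a {length}-bp locus after "
                f"{_MAX_PLACEMENT_RETRIES} attempts")
    return sorted(placed, key=lambda iv: (iv.chrom, iv.start))


def plant_loci(config: SimulationConfig) -> TruthManifest:
    """Plant non-overlapping loci, assign mark combinations, place repeats and genes."""
    rng = _stream(config.seed, "loci")
    lo, hi = config.locus_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_loci)
    loci = _place_nonoverlapping(rng, config.genome, lengths)

    combos = list(config.cooccupancy_design)
    probs = np.array([config.cooccupancy_design[c] for c in combos], dtype=float)
    p_none = max(0.0, 1.0 - probs.sum())
    choices = rng.choice(len(combos) + 1, size=len(loci),
                         p=np.append(probs, p_none))
    labels = [combos[i] if i < len(combos) else frozenset() for i in choices]

    manifest = TruthManifest(config=config, loci=loci, locus_labels=labels)
    if config.repeat_config:
        manifest.repeats = _plant_repeats(config, manifest)
    if config.n_genes > 0 and config.rnapii_config.cohorts:
        _plant_genes(config, manifest)
    return manifest


def _plant_repeats(config: SimulationConfig, manifest: TruthManifest) -> RepeatAnnotation:
    """Place repeats genome-wide at target density, plus extra mass inside
    co-marked loci to reach the inside density."""
    rng = _stream(config.seed, "repeats")
    genome_bp = sum(config.genome.values())
    chroms = list(config.genome)
    sizes = np.array([config.genome[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    comarked = manifest.comarked_loci()
    elements = []
    for fam in config.repeat_config:
        mean_len = 0.5 * (fam.length_range[0] + fam.length_range[1])
        n_bg = rng.poisson(fam.target_density * genome_bp / mean_len)
        for _ in range(int(n_bg)):
            length = int(rng.integers(fam.length_range[0], fam.length_range[1] + 1))
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            limit = max(config.genome[chrom] - length, 1)
            start = int(rng.integers(0, limit))
            elements.append(RepeatElement(chrom, start, start + length,
                                          fam.repeat_class, fam.family, fam.subfamily))
        extra_density = fam.density_inside_comarked - fam.target_density
        if extra_density > 0:
            for locus in comarked:
                n_extra = rng.poisson(extra_density * locus.length / mean_len)
                for _ in range(int(n_extra)):
                    length = int(rng.integers(fam.length_range[0],
                                              fam.length_range[1] + 1))
                    # center the repeat inside the locus so the extra mass
                    # lands where the coverage is measured
                    lo = max(locus.start - length + 1, 0)
                    hi = min(locus.end, config.genome[locus.chrom] - length)
                    start = int(rng.integers(lo, max(hi, lo + 1)))
                    elements.append(RepeatElement(locus.chrom, start, start + length,
                                                  fam.repeat_class, fam.family,
                                                  fam.subfamily))
    return RepeatAnnotation(elements)


def _plant_genes(config: SimulationConfig, manifest: TruthManifest) -> None:
    """Place non-overlapping single-exon genes and assign RNAPII cohorts."""
    rng = _stream(config.seed, "genes")
    cohorts = config.rnapii_config.cohorts
    n_wanted = sum(c.n_genes for c in cohorts)
    n = min(config.n_genes, n_wanted) if n_wanted else config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    spans = _place_nonoverlapping(rng, config.genome, lengths)
    assignments = []
    for c in cohorts:
        assignments.extend([c] * c.n_genes)
    assignments = assignments[:n]
    rng.shuffle(spans)
    for i, (span, cohort) in enumerate(zip(spans, assignments)):
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{i:05d}"
        if strand == "+":
            g = GeneModel(gid, span.chrom, "+", tss=span.start, tes=span.end,
                          exons=((span.start, span.end),))
        else:
            g = GeneModel(gid, span.chrom, "-", tss=span.end - 1, tes=span.start,
                          exons=((span.start, span.end),))
        manifest.genes.append(g)
        manifest.gene_truth[gid] = (cohort.name, cohort.ratio)
    manifest.genes.sort(key=lambda g: (g.chrom, g.span[0]))


def _uniform_tags(rng: np.random.Generator, chrom_len: int, n: int,
                  offset: int = 0) -> np.ndarray:
    return offset + rng.integers(0, chrom_len, size=n)


def _assemble(per_chrom: dict[str, list[np.ndarray]],
              rng: np.random.Generator) -> TagCollection:
    tags = {}
    for chrom, chunks in per_chrom.items():
        pos = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        tags[chrom] = (pos.astype(np.int64), strand)
    return TagCollection.from_arrays(tags)


def _simulate_track(manifest: TruthManifest, rng: np.random.Generator,
                    background_rate: float,
                    locus_folds: list[tuple[GenomicInterval, float]]) -> TagCollection:
    """Poisson background plus extra Poisson mass inside fold-enriched loci."""
    config = manifest.config
    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in config.genome}
    for chrom, length in config.genome.items():
        n_bg = rng.poisson(background_rate * length)
        per_chrom[chrom].append(_uniform_tags(rng, length, int(n_bg)))
    for locus, fold in locus_folds:
        if fold <= 1:
            continue
        n_extra = rng.poisson((fold - 1) * background_rate * locus.length)
        per_chrom[locus.chrom].append(
            _uniform_tags(rng, locus.length, int(n_extra), offset=locus.start))
    return _assemble(per_chrom, rng)


def simulate_mark_tags(manifest: TruthManifest, mark: str) -> TagCollection:
    """ChIP tags for one mark: uniform background, fold-enriched at loci
    whose label includes the mark."""
    config = manifest.config
    if mark not in config.marks:
        raise ValueError(f"unknown mark {mark!r}")
    mc = config.marks[mark]
    rng = _stream(config.seed, "mark", mark)
    folds = [(iv, mc.enrichment_fold)
             for iv, lab in zip(manifest.loci, manifest.locus_labels) if mark in lab]
    return _simulate_track(manifest, rng, mc.background_rate, folds)


def simulate_rechip_tags(manifest: TruthManifest, mark_a: str, mark_b: str) -> TagCollection:
    """Sequential-ChIP tags: enrichment only at loci carrying BOTH marks
    (single-mark loci receive the configured single fold, default background)."""
    config = manifest.config
    for m in (mark_a, mark_b):
        if m not in config.marks:
            raise ValueError(f"unknown mark {m!r}")
    rc = config.rechip_config
    rng = _stream(config.seed, "rechip", mark_a, mark_b)
    folds = []
    pair = frozenset((mark_a, mark_b))
    for iv, lab in zip(manifest.loci, manifest.locus_labels):
        inter = lab & pair
        if len(inter) == 2:
            folds.append((iv, rc.dual_fold))
        elif len(inter) == 1:
            folds.append((iv, rc.single_fold))
    return _simulate_track(manifest, rng, rc.background_rate, folds)


def simulate_input_tags(manifest: TruthManifest,
                        background_rate: float | None = None) -> TagCollection:
    """Input (control) track: pure background at the reChIP background rate."""
    config = manifest.config
    rate = background_rate if background_rate is not None \
        else config.rechip_config.background_rate
    rng = _stream(config.seed, "input")
    return _simulate_track(manifest, rng, rate, [])


def simulate_rnapii_tags(manifest: TruthManifest) -> tuple[TagCollection, int]:
    """RNAPII tags: per-gene promoter-bin rate = r * body_rate, body rate = b.

    Returns (tags, n_skipped) where n_skipped counts genes shorter than the
    promoter bin (skipped with a warning count rather than an error).
    """
    config = manifest.config
    rc = config.rnapii_config
    rng = _stream(config.seed, "rnapii")
    per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in config.genome}
    for chrom, length in config.genome.items():
        n_bg = rng.poisson(rc.background_rate * length)
        per_chrom[chrom].append(_uniform_tags(rng, length, int(n_bg)))
    h = rc.promoter_halfwidth
    n_skipped = 0
    for g in manifest.genes:
        _, ratio = manifest.gene_truth[g.gene_id]
        span_start, span_end = g.span
        if span_end - span_start <= 2 * h:
            n_skipped += 1
            continue
        prom_start = max(g.tss - h, 0)
        prom_end = min(g.tss + h, config.genome[g.chrom])
        if g.strand == "+":
            body_start, body_end = g.tss + h, g.tes
        else:
            body_start, body_end = g.tes, g.tss - h
        n_prom = rng.poisson(ratio * rc.body_rate * (prom_end - prom_start))
        per_chrom[g.chrom].append(
            _uniform_tags(rng, prom_end - prom_start, int(n_prom), offset=prom_start))
        if body_end > body_start:
            n_body = rng.poisson(rc.body_rate * (body_end - body_start))
            per_chrom[g.chrom].append(
                _uniform_tags(rng, body_end - body_start, int(n_body),
                              offset=body_start))
    return _assemble(per_chrom, rng), n_skipped
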