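"""Domain types and readers/writers for the genomic text formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) everywhere internally.
Tab-delimited outputs carry ``#``-prefixed header lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""

    def __init__(self, path, lineno: int | None, message: str):
        self.path = path
        self.lineno = lineno
        where = f"{path}" + (f", line {lineno}" if lineno is not None else "")
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome name -> length (bp) map defining the coordinate space."""

    sizes: dict[str, int]

    def __post_init__(self):
        if not self.sizes:
            raise ValueError("genome layout must contain at least one chromosome")
        for name, length in self.sizes.items():
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length!r}")

    @property
    def chroms(self) -> list[str]:
        return list(self.sizes)

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class RegionSet:
    """A labelled, sorted collection of genomic intervals.

    Intervals are kept sorted by (chrom, start, end); per-chromosome start/end
    arrays are exposed for vectorized interval algebra.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "",
                 layout: GenomeLayout | None = None):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if layout is not None:
            for iv in ivs:
                if iv.chrom not in layout:
                    raise ValueError(f"interval chrom {iv.chrom!r} absent from layout")
                if iv.end > layout[iv.chrom]:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                        f"length {layout[iv.chrom]}")
        self.label = label
        self.layout = layout
        self.intervals: list[GenomicInterval] = ivs
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) int64 arrays, sorted by start."""
        if self._arrays is None:
            arrays: dict[str, tuple[list, list]] = {}
            for iv in self.intervals:
                arrays.setdefault(iv.chrom, ([], []))
                arrays[iv.chrom][0].append(iv.start)
                arrays[iv.chrom][1].append(iv.end)
            self._arrays = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in arrays.items()
            }
        return self._arrays

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)


@dataclass
class TagCollection:
    """Strand-aware 5' read positions per chromosome.

    ``tags`` maps chromosome -> (positions, strands) where positions is a sorted
    int64 array of read 5'-end coordinates and strands a parallel array of
    '+'/'-' codes. ``library_size`` equals the total tag count.
    """

    tags: dict[str, tuple[np.ndarray, np.ndarray]]
    library_size: int

    def __post_init__(self):
        n = sum(len(p) for p, _ in self.tags.values())
        if n != self.library_size:
            raise ValueError(
                f"library_size {self.library_size} != total tag count {n}")

    @classmethod
    def from_arrays(cls, tags: dict[str, tuple[np.ndarray, np.ndarray]]) -> "TagCollection":
        clean = {}
        for chrom, (pos, strand) in tags.items():
            pos = np.asarray(pos, dtype=np.int64)
            strand = np.asarray(strand)
            order = np.argsort(pos, kind="stable")
            clean[chrom] = (pos[order], strand[order])
        n = sum(len(p) for p, _ in clean.values())
        return cls(tags=clean, library_size=n)

    def positions(self, chrom: str) -> np.ndarray:
        if chrom not in self.tags:
            return np.empty(0, dtype=np.int64)
        return self.tags[chrom][0]

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Tags with position in [start, end)."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end, side="left")
                   - np.searchsorted(pos, start, side="left"))


@dataclass(frozen=True)
class GeneModel:
    """Gene with TSS/TES anchors and exon structure.

    For + strand genes tss < tes; for - strand genes tss > tes (both are bp
    coordinates of the first/last transcribed base). Exons are half-open and
    non-overlapping, contained in [min(tss,tes), max(tss,tes)+1).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss > tes")
        ex = sorted(self.exons)
        lo, hi = (self.tss, self.tes) if self.strand == "+" else (self.tes, self.tss + 1)
        prev_end = -1
        for s, e in ex:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            if s < lo or e > hi:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            prev_end = e
        object.__setattr__(self, "exons", tuple(ex))

    @property
    def span(self) -> tuple[int, int]:
        """Half-open genomic span covering the gene.

        For + strand genes the TES is the exclusive span end; for - strand
        genes the TSS is the last covered base.
        """
        if self.strand == "+":
            return self.tss, self.tes
        return self.tes, self.tss + 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class RepeatElement:
    chrom: str
    start: int
    end: int
    repeat_class: str
    family: str
    subfamily: str

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid repeat {self.chrom}:{self.start}-{self.end}")
        if not (self.repeat_class and self.family and self.subfamily):
            raise ValueError("repeat class/family/subfamily must be non-empty")


class RepeatAnnotation:
    """Class/family/subfamily-labelled repeat intervals (RepeatMasker-style)."""

    LEVELS = ("class", "family", "subfamily")

    def __init__(self, elements: Iterable[RepeatElement]):
        self.elements: list[RepeatElement] = sorted(
            elements, key=lambda r: (r.chrom, r.start, r.end))

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def select(self, level: str, value: str) -> RegionSet:
        """All intervals whose label at *level* equals *value* (exact, case-sensitive)."""
        if level not in self.LEVELS:
            raise ValueError(f"level must be one of {self.LEVELS}, got {level!r}")
        attr = {"class": "repeat_class", "family": "family", "subfamily": "subfamily"}[level]
        ivs = [GenomicInterval(r.chrom, r.start, r.end, name=getattr(r, attr))
               for r in self.elements if getattr(r, attr) == value]
        return RegionSet(ivs, label=f"{level}={value}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_chrom_sizes(path) -> GenomeLayout:
    """Parse a UCSC chrom.sizes file (name<TAB>length)."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected two tab-separated columns")
        name = fields[0]
        try:
            length = int(fields[1])
        except ValueError:
            raise ParseError(path, lineno, f"non-integer length {fields[1]!r}") from None
        if length <= 0:
            raise ParseError(path, lineno, f"non-positive length {length}")
        if name in sizes:
            raise ParseError(path, lineno, f"duplicate chromosome {name!r}")
        sizes[name] = length
    return GenomeLayout(sizes)


def _parse_bed_fields(path, lineno, fields, layout: GenomeLayout | None):
    if len(fields) < 3:
        raise ParseError(path, lineno, "fewer than 3 BED columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(path, lineno, "non-integer coordinates") from None
    if start >= end:
        raise ParseError(path, lineno, f"start {start} >= end {end}")
    if start < 0:
        raise ParseError(path, lineno, f"negative start {start}")
    if layout is not None:
        if chrom not in layout:
            raise ParseError(path, lineno, f"chromosome {chrom!r} absent from layout")
        if end > layout[chrom]:
            raise ParseError(path, lineno, f"end {end} exceeds {chrom} length {layout[chrom]}")
    name = fields[3] if len(fields) > 3 and fields[3] != "." else None
    score = None
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
    strand = fields[5] if len(fields) > 5 else "."
    return chrom, start, end, name, score, strand


def read_bed(path, layout: GenomeLayout | None = None, label: str = "") -> RegionSet:
    """Read a BED3+ file into a sorted RegionSet."""
    ivs = []
    for lineno, line in _data_lines(path):
        chrom, start, end, name, score, strand = _parse_bed_fields(
            path, lineno, line.split("\t"), layout)
        ivs.append(GenomicInterval(chrom, start, end, name=name, score=score, strand=strand))
    return RegionSet(ivs, label=label or str(path), layout=layout)


def write_bed(regions: RegionSet | Sequence[GenomicInterval], path,
              header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in regions:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_tags_bed(path, layout: GenomeLayout | None = None) -> TagCollection:
    """Read aligned reads (BED6) into a TagCollection of 5' positions.

    The recorded tag position is the read's 5' end: ``start`` for + reads and
    ``end - 1`` (the last aligned base, since BED ends are exclusive) for - reads.
    """
    per_chrom: dict[str, tuple[list, list]] = {}
    n = 0
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(path, lineno, "tag BED requires 6 columns (strand missing)")
        chrom, start, end, _, _, strand = _parse_bed_fields(path, lineno, fields, layout)
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"read strand must be +/-, got {strand!r}")
        pos = start if strand == "+" else end - 1
        per_chrom.setdefault(chrom, ([], []))
        per_chrom[chrom][0].append(pos)
        per_chrom[chrom][1].append(strand)
        n += 1
    return TagCollection.from_arrays(
        {c: (np.asarray(p, dtype=np.int64), np.asarray(s)) for c, (p, s) in per_chrom.items()})


def write_tags_bed(tags: TagCollection, path, read_length: int = 1) -> None:
    """Write tags back as BED6 point reads (length ``read_length``)."""
    with open(path, "w") as fh:
        i = 0
        for chrom in sorted(tags.tags):
            pos, strand = tags.tags[chrom]
            for p, s in zip(pos.tolist(), strand.tolist()):
                if s == "+":
                    start, end = p, p + read_length
                else:
                    start, end = p - read_length + 1, p + 1
                start = max(start, 0)
                fh.write(f"{chrom}\t{start}\t{end}\ttag{i}\t0\t{s}\n")
                i += 1


def read_genes(path, layout: GenomeLayout | None = None) -> list[GeneModel]:
    """Read gene models from BED12 (TSS/TES derived from strand)."""
    genes = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 12:
            raise ParseError(path, lineno, "BED12 requires 12 columns")
        chrom, start, end, name, _, strand = _parse_bed_fields(path, lineno, fields, layout)
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, "gene strand must be + or -")
        try:
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError:
            raise ParseError(path, lineno, "malformed block columns") from None
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ParseError(path, lineno, "block count mismatch")
        exons = []
        for bs, sz in zip(starts, sizes):
            es, ee = start + bs, start + bs + sz
            if es < start or ee > end:
                raise ParseError(path, lineno, f"exon block ({es},{ee}) outside gene span")
            exons.append((es, ee))
        tss, tes = (start, end) if strand == "+" else (end - 1, start)
        try:
            genes.append(GeneModel(name or f"gene_line{lineno}", chrom, strand,
                                   tss=tss, tes=tes, exons=tuple(exons)))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return genes


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.span
            # span end for + strand genes is tes (exclusive already)
            if g.strand == "+":
                start, end = g.tss, g.tes
            else:
                start, end = g.tes, g.tss + 1
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - start) for s, e in g.exons)
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{start}\t{end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")


def read_repeats(path, layout: GenomeLayout | None = None) -> RepeatAnnotation:
    """Read RepeatMasker-style repeats.

    Two dialects, auto-detected by column count:
      * 6 columns — BED6 whose name field is "class/family/subfamily";
      * 8 columns — chrom, start, end, name, score, strand, then explicit
        class, family columns with the name field holding the subfamily.
    """
    elements = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        chrom, start, end, name, _, _ = _parse_bed_fields(path, lineno, fields, layout)
        if len(fields) >= 8:
            rclass, family = fields[6], fields[7]
            subfamily = name or ""
        elif len(fields) >= 6:
            parts = (name or "").split("/")
            if len(parts) != 3:
                raise ParseError(path, lineno,
                                 f"name field {name!r} is not class/family/subfamily")
            rclass, family, subfamily = parts
        else:
            raise ParseError(path, lineno, "repeat BED requires 6 or 8 columns")
        try:
            elements.append(RepeatElement(chrom, start, end, rclass, family, subfamily))
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from None
    return RepeatAnnotation(elements)


def write_repeats(repeats: RepeatAnnotation, path) -> None:
    """Write repeats in the 6-column slash-joined dialect."""
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{r.repeat_class}/{r.family}/{r.subfamily}\t0\t.\n")


def write_bedgraph(track: pd.DataFrame, path, header: str | None = None) -> None:
    """Write a 4-column bedGraph from a DataFrame with chrom/start/end/value columns."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(path, lineno, "bedGraph requires 4 columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise ParseError(path, lineno, "malformed bedGraph line") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
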