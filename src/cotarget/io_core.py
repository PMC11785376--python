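"""Domain types and readers/writers for the flat files the pipeline consumes.

Coordinates are 0-based, half-open (BED convention) throughout.  All readers
validate against a :class:`GenomeBuild` or annotation where one applies, and
all emitted collections are sorted deterministically (chromosome
lexicographic, then start, then end / gene id) so outputs are reproducible
byte for byte.

File formats:

* chromosome sizes — two-column TSV ``name<TAB>length``;
* peaks — BED with >= 3 columns;
* genes — TSV with header ``gene_id  chrom  strand  tss``;
* DEG contrast — TSV with header ``gene_id  log2fc  pvalue  fdr``.

``#``-prefixed lines are treated as comments everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class ValidationError(ValueError):
    """An input violated a structural invariant (bad coordinates, duplicate
    ids, references to unknown chromosomes or genes)."""


class ParseError(ValueError):
    """A line could not be parsed; the message carries the file and line
    number."""


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome name -> length (bp).  Names unique, lengths >= 1."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if not isinstance(length, int) or length < 1:
                raise ValidationError(
                    f"chromosome {name!r} has invalid length {length!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return self.sizes[chrom]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.sizes)

    @property
    def total_length(self) -> int:
        return sum(self.sizes.values())


@dataclass(frozen=True, order=True)
class Peak:
    """A genomic interval on a named chromosome, half-open [start, end)."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"peak {self.name or ''} {self.chrom}:{self.start}-{self.end}: "
                f"require 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def validate(self, genome: GenomeBuild) -> None:
        if self.chrom not in genome:
            raise ValidationError(
                f"peak {self.name or ''} on unknown chromosome {self.chrom!r}"
            )
        if self.end > genome[self.chrom]:
            raise ValidationError(
                f"peak {self.name or ''} {self.chrom}:{self.start}-{self.end} "
                f"extends beyond chromosome end ({genome[self.chrom]})"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene id, chromosome, strand and transcription start site.

    Strand is carried for provenance only: the TSS column is already the
    strand-resolved start, and every downstream distance is measured from it.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS")

    def validate(self, genome: GenomeBuild) -> None:
        if self.chrom not in genome:
            raise ValidationError(
                f"gene {self.gene_id} on unknown chromosome {self.chrom!r}"
            )
        if self.tss >= genome[self.chrom]:
            raise ValidationError(
                f"gene {self.gene_id}: TSS {self.tss} beyond chromosome "
                f"end ({genome[self.chrom]})"
            )


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression summary in one mutant-vs-wild-type
    contrast: log2 fold change, raw p-value, and BH-adjusted FDR."""

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValidationError(
                f"gene {self.gene_id}: p-value {self.pvalue} outside [0, 1]"
            )
        if not 0.0 <= self.fdr <= 1.0:
            raise ValidationError(
                f"gene {self.gene_id}: FDR {self.fdr} outside [0, 1]"
            )


@dataclass(frozen=True)
class PeakSetPair:
    """Two peak sets (factor A and factor B) sharing one genome build."""

    peaks_a: tuple[Peak, ...]
    peaks_b: tuple[Peak, ...]
    genome: GenomeBuild

    def __post_init__(self) -> None:
        for peak in (*self.peaks_a, *self.peaks_b):
            peak.validate(self.genome)


def sort_peaks(peaks: Iterable[Peak]) -> list[Peak]:
    """Canonical order: (chromosome, start, end)."""
    return sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: str | Path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_chrom_sizes(path: str | Path) -> GenomeBuild:
    """Read a two-column ``name<TAB>length`` TSV into a GenomeBuild."""
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        name = fields[0]
        if name in sizes:
            raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        try:
            sizes[name] = int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return GenomeBuild(sizes)


def read_bed(path: str | Path, genome: GenomeBuild) -> list[Peak]:
    """Read a BED (>= 3 columns, 0-based half-open) into validated peaks.

    Peaks are validated against the genome build and returned in canonical
    sorted order.  Malformed lines raise :class:`ParseError` with the line
    number; out-of-bounds peaks raise :class:`ValidationError` naming the
    offending peak.
    """
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score: float | None = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
        try:
            peak = Peak(fields[0], start, end, name=name, score=score)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        peak.validate(genome)
        peaks.append(peak)
    return sort_peaks(peaks)


def read_gene_table(path: str | Path, genome: GenomeBuild) -> list[GeneModel]:
    """Read the gene annotation TSV (header: gene_id, chrom, strand, tss)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    header_done = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_done:
            if fields[:4] != ["gene_id", "chrom", "strand", "tss"]:
                raise ParseError(
                    f"{path}:{lineno}: expected header 'gene_id chrom strand tss'"
                )
            header_done = True
            continue
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        gene_id = fields[0]
        if gene_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        try:
            tss = int(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad tss {fields[3]!r}") from exc
        gene = GeneModel(gene_id, fields[1], fields[2], tss)
        gene.validate(genome)
        genes.append(gene)
    if not header_done:
        raise ParseError(f"{path}: empty gene table")
    return sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id))


def read_deg_table(path: str | Path) -> dict[str, DEGRecord]:
    """Read a DEG contrast TSV (header: gene_id, log2fc, pvalue, fdr), keyed
    by gene id."""
    records: dict[str, DEGRecord] = {}
    header_done = False
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if not header_done:
            if fields[:4] != ["gene_id", "log2fc", "pvalue", "fdr"]:
                raise ParseError(
                    f"{path}:{lineno}: expected header 'gene_id log2fc pvalue fdr'"
                )
            header_done = True
            continue
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        gene_id = fields[0]
        if gene_id in records:
            raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        try:
            log2fc, pvalue, fdr = (float(x) for x in fields[1:4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
        try:
            records[gene_id] = DEGRecord(gene_id, log2fc, pvalue, fdr)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if not header_done:
        raise ParseError(f"{path}: empty DEG table")
    return records


def check_deg_universe(records: Mapping[str, DEGRecord],
                       genes: Iterable[GeneModel]) -> None:
    """Reject DEG records whose gene ids are absent from the annotation."""
    known = {g.gene_id for g in genes}
    unknown = sorted(set(records) - known)
    if unknown:
        raise ValidationError(
            f"{len(unknown)} DEG gene ids absent from annotation "
            f"(first: {unknown[:5]})"
        )


# ---------------------------------------------------------------------------
# writers (canonical forms; write(read(x)) round-trips byte-identically)


def write_chrom_sizes(genome: GenomeBuild, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in genome.chromosomes:
            fh.write(f"{name}\t{genome[name]}\n")


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sort_peaks(peaks):
            cols = [p.chrom, str(p.start), str(p.end)]
            if p.name is not None or p.score is not None:
                cols.append(p.name if p.name is not None else ".")
            if p.score is not None:
                cols.append(f"{p.score:g}")
            fh.write("\t".join(cols) + "\n")


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tss, g.gene_id)):
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def write_deg_table(records: Mapping[str, DEGRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tfdr\n")
        for gene_id in sorted(records):
            r = records[gene_id]
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t{r.fdr:.6g}\n")
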