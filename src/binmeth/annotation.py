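"""Genome annotation: CpG islands, gene models, and bin classification.

All coordinates are 0-based half-open internally.  BED input is consumed
natively; refFlat is natively 0-based half-open as well.  CpG islands (CGIs)
are consumed as a fixed interval list (BED3+) — there is no de novo CGI
detection here.  Gene models come from a refFlat-style table (one row per
transcript); isoforms of a gene are collapsed to the union of their exons
before any region classification, and "first"/"last" exon are taken in
transcription orientation on the collapsed model.

A 200-bp bin overlapping a gene is assigned exactly one region category per
gene it touches:

* ``THREE_PRIME`` — last exon and 3' UTR,
* ``FIVE_PRIME``  — an upstream promoter window, first exon and 5' UTR,
* ``GENE_BODY``   — everything else inside the transcript span
  (internal exons and introns),
* ``INTERGENIC``  — overlaps no gene (not even a promoter window).

When a bin straddles sub-regions the category is chosen by a strand-aware
precedence, by default THREE_PRIME > FIVE_PRIME > GENE_BODY, so that 3'-end
signal is never diluted into the gene body.  Both the promoter span and the
precedence are configurable.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .errors import ParseError, ValidationError


class CgiStatus(str, Enum):
    """Whether a bin overlaps a CpG island by at least one base."""

    CGI = "CGI"
    NON_CGI = "non-CGI"


class RegionCategory(str, Enum):
    FIVE_PRIME = "5'"
    GENE_BODY = "gene body"
    THREE_PRIME = "3'"
    INTERGENIC = "intergenic"


#: Default tie-break when a bin spans several sub-regions of one gene.
DEFAULT_PRECEDENCE: tuple[RegionCategory, ...] = (
    RegionCategory.THREE_PRIME,
    RegionCategory.FIVE_PRIME,
    RegionCategory.GENE_BODY,
)

#: Default upstream promoter extension in bases (see module docstring).
DEFAULT_PROMOTER_SPAN = 2000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    id: str


@dataclass(frozen=True)
class GeneModel:
    """One transcript (or one collapsed gene) from a refFlat table.

    Exons are stored sorted in ascending genomic order regardless of strand;
    transcription orientation is recovered from ``strand`` where needed.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"unknown strand {self.strand!r} for {self.name}")
        if not self.exons:
            raise ValidationError(f"gene {self.name} has no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValidationError(f"empty exon [{s}, {e}) in {self.name}")
            if s < self.tx_start or e > self.tx_end:
                raise ValidationError(
                    f"exon [{s}, {e}) outside transcript bounds in {self.name}"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"exons overlap or unsorted in {self.name}")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValidationError(f"cds bounds outside transcript in {self.name}")

    @property
    def coding(self) -> bool:
        return self.cds_start < self.cds_end


def _as_lines(source: str | Iterable[str]) -> Iterable[str]:
    if isinstance(source, str):
        return source.splitlines()
    return source


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or book-ended intervals are merged."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def load_cgis(bed_text: str | Iterable[str]) -> list[CpGIsland]:
    """Parse a BED3+ CGI list.

    Overlapping or adjacent islands on one chromosome are merged at load
    time, so downstream code can assume a sorted, non-overlapping list.
    Returns islands sorted by (chrom, start) with stable synthetic ids.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for lineno, raw in enumerate(_as_lines(bed_text), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"expected >=3 BED columns, got {len(fields)}", lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"non-integer coordinate: {exc}", lineno) from exc
        if start < 0 or end <= start:
            raise ParseError(f"invalid interval [{start}, {end})", lineno)
        by_chrom.setdefault(chrom, []).append((start, end))

    cgis: list[CpGIsland] = []
    for chrom in sorted(by_chrom):
        for s, e in _merge_intervals(by_chrom[chrom]):
            cgis.append(
                CpGIsland(GenomicInterval(chrom, s, e), f"CGI_{len(cgis) + 1:05d}")
            )
    return cgis


def load_gene_models(refflat_text: str | Iterable[str]) -> list[GeneModel]:
    """Parse refFlat lines (11 columns: geneName, name, chrom, strand,
    txStart, txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds).

    Returns one :class:`GeneModel` per transcript, named after the *gene*
    symbol (column 1); collapse isoforms with :func:`collapse_isoforms`.
    """
    models: list[GeneModel] = []
    for lineno, raw in enumerate(_as_lines(refflat_text), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 11:
            raise ParseError(f"expected 11 refFlat columns, got {len(fields)}", lineno)
        gene, _tx, chrom, strand = fields[0], fields[1], fields[2], fields[3]
        try:
            tx_start, tx_end = int(fields[4]), int(fields[5])
            cds_start, cds_end = int(fields[6]), int(fields[7])
            exon_count = int(fields[8])
            starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
        except ValueError as exc:
            raise ParseError(f"non-integer field: {exc}", lineno) from exc
        if len(starts) != exon_count or len(ends) != exon_count:
            raise ParseError(
                f"exonCount={exon_count} but {len(starts)} starts / "
                f"{len(ends)} ends",
                lineno,
            )
        exons = tuple(sorted(zip(starts, ends)))
        try:
            models.append(
                GeneModel(gene, chrom, strand, tx_start, tx_end, cds_start, cds_end, exons)
            )
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from exc
    return models


def collapse_isoforms(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Collapse transcripts sharing (gene name, chrom, strand) into one
    model: exon union, outermost transcript bounds, outermost CDS bounds."""
    groups: dict[tuple[str, str, str], list[GeneModel]] = {}
    for m in models:
        groups.setdefault((m.name, m.chrom, m.strand), []).append(m)
    collapsed = []
    for (name, chrom, strand), ms in groups.items():
        exons = _merge_intervals([ex for m in ms for ex in m.exons])
        tx_start = min(m.tx_start for m in ms)
        tx_end = max(m.tx_end for m in ms)
        coding = [m for m in ms if m.coding]
        if coding:
            cds_start = min(m.cds_start for m in coding)
            cds_end = max(m.cds_end for m in coding)
        else:
            cds_start = cds_end = tx_start
        collapsed.append(
            GeneModel(name, chrom, strand, tx_start, tx_end, cds_start, cds_end, tuple(exons))
        )
    collapsed.sort(key=lambda m: (m.chrom, m.tx_start, m.name))
    return collapsed


class CgiIndex:
    """Sorted-array overlap index over a merged CGI list."""

    def __init__(self, cgis: Sequence[CpGIsland]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c in cgis:
            by_chrom.setdefault(c.interval.chrom, []).append(
                (c.interval.start, c.interval.end)
            )
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in by_chrom.items():
            merged = _merge_intervals(ivs)
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    def status(self, bin: GenomicInterval) -> CgiStatus:
        starts = self._starts.get(bin.chrom)
        if not starts:
            return CgiStatus.NON_CGI
        ends = self._ends[bin.chrom]
        i = bisect_left(starts, bin.end)  # first island starting at/after bin end
        if i > 0 and ends[i - 1] > bin.start:
            return CgiStatus.CGI
        return CgiStatus.NON_CGI


def cgi_status(
    bin: GenomicInterval, cgis: Sequence[CpGIsland] | CgiIndex
) -> CgiStatus:
    """CGI iff the bin overlaps any island by >= 1 bp (half-open semantics).

    Accepts a raw island list (an index is built ad hoc) or a prebuilt
    :class:`CgiIndex` for repeated queries.
    """
    index = cgis if isinstance(cgis, CgiIndex) else CgiIndex(cgis)
    return index.status(bin)


def _exonic_within(
    exons: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    """Portions of exons intersecting [lo, hi)."""
    out = []
    for s, e in exons:
        a, b = max(s, lo), min(e, hi)
        if a < b:
            out.append((a, b))
    return out


@dataclass(frozen=True)
class _GeneRegions:
    gene: GeneModel
    ext_start: int  # transcript span extended by the promoter window
    ext_end: int
    three: tuple[tuple[int, int], ...]
    five: tuple[tuple[int, int], ...]


def _build_regions(g: GeneModel, promoter_span: int) -> _GeneRegions:
    exons = g.exons
    if g.strand == "+":
        five = [exons[0]]
        if promoter_span > 0 and g.tx_start > 0:
            five.append((max(0, g.tx_start - promoter_span), g.tx_start))
        three = [exons[-1]]
        if g.coding:
            five += _exonic_within(exons, g.tx_start, g.cds_start)   # 5' UTR
            three += _exonic_within(exons, g.cds_end, g.tx_end)      # 3' UTR
        ext_start = max(0, g.tx_start - promoter_span)
        ext_end = g.tx_end
    else:
        five = [exons[-1]]
        if promoter_span > 0:
            five.append((g.tx_end, g.tx_end + promoter_span))
        three = [exons[0]]
        if g.coding:
            five += _exonic_within(exons, g.cds_end, g.tx_end)       # 5' UTR
            three += _exonic_within(exons, g.tx_start, g.cds_start)  # 3' UTR
        ext_start = g.tx_start
        ext_end = g.tx_end + promoter_span
    return _GeneRegions(
        g,
        ext_start,
        ext_end,
        tuple(_merge_intervals(three)),
        tuple(_merge_intervals(five)),
    )


def _any_overlap(ivs: Sequence[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in ivs)


class GeneIndex:
    """Interval index over collapsed gene models for bin classification."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        promoter_span: int = DEFAULT_PROMOTER_SPAN,
        precedence: tuple[RegionCategory, ...] = DEFAULT_PRECEDENCE,
        collapse: bool = True,
    ):
        if promoter_span < 0:
            raise ValidationError("promoter_span must be >= 0")
        if set(precedence) != {
            RegionCategory.THREE_PRIME,
            RegionCategory.FIVE_PRIME,
            RegionCategory.GENE_BODY,
        }:
            raise ValidationError(
                "precedence must order THREE_PRIME, FIVE_PRIME, GENE_BODY"
            )
        self.promoter_span = promoter_span
        self.precedence = precedence
        models = collapse_isoforms(genes) if collapse else list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in models:
            regions = _build_regions(g, promoter_span)
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(regions.ext_start, regions.ext_end, regions)

    def classify(self, bin: GenomicInterval) -> set[tuple[str | None, RegionCategory]]:
        """Per-gene region categories for every gene the bin overlaps.

        Returns ``{(None, INTERGENIC)}`` when the bin overlaps no gene.
        """
        tree = self._trees.get(bin.chrom)
        hits = tree.overlap(bin.start, bin.end) if tree is not None else ()
        out: set[tuple[str | None, RegionCategory]] = set()
        for hit in hits:
            regions: _GeneRegions = hit.data
            g = regions.gene
            category = None
            for cat in self.precedence:
                if cat is RegionCategory.THREE_PRIME:
                    if _any_overlap(regions.three, bin.start, bin.end):
                        category = cat
                        break
                elif cat is RegionCategory.FIVE_PRIME:
                    if _any_overlap(regions.five, bin.start, bin.end):
                        category = cat
                        break
                else:  # GENE_BODY: remainder of the transcript span
                    if bin.start < g.tx_end and g.tx_start < bin.end:
                        category = cat
                        break
            if category is not None:
                out.add((g.name, category))
        if not out:
            out.add((None, RegionCategory.INTERGENIC))
        return out


def classify_bin_region(
    bin: GenomicInterval,
    genes: Sequence[GeneModel] | GeneIndex,
    promoter_span: int = DEFAULT_PROMOTER_SPAN,
) -> set[tuple[str | None, RegionCategory]]:
    """Convenience wrapper over :meth:`GeneIndex.classify`.

    Builds a throwaway index when given a raw gene list; pass a prebuilt
    :class:`GeneIndex` when classifying many bins.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, promoter_span)
    return index.classify(bin)
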