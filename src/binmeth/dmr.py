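"""Differentially methylated region (DMR) calling and eight-group tables.

A DMR here is a 200-bp bin whose methylation level differs by strictly more
than a threshold (default 15 percentage points) between two profiles, with
both profiles passing the coverage/CpG filter in that bin.  The comparison
is oriented a -> b: for a maturation contrast (mDMR) a is the earlier age
(P0) and b the later (P21); for a differentiation contrast (dDMR) a is the
stem-cell profile and b its differentiated progeny.  ``direction`` is GAIN
when the level rises from a to b.

Calling is a deterministic threshold rule — the profiles being compared are
pooled-sample methylomes without biological replicates, so no per-bin test
statistic is attached.  Gene-associated DMRs are partitioned into eight
groups: {gain, loss} x {CGI, non-CGI} x {5', gene body or 3'}; intergenic
DMRs belong to no group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .annotation import (
    CgiIndex,
    CgiStatus,
    GeneIndex,
    GenomicInterval,
    RegionCategory,
)
from .errors import ConfigurationError, UndefinedResultError, ValidationError
from .quantify import MethylationProfile

DEFAULT_DMR_THRESHOLD = 15.0

#: Canonical labels of the eight gene-associated DMR groups.
GROUP_LABELS: tuple[str, ...] = (
    "gain at 5' CGI",
    "gain at gene body or 3' CGI",
    "loss at 5' CGI",
    "loss at gene body or 3' CGI",
    "gain at 5' non-CGI",
    "gain at gene body or 3' non-CGI",
    "loss at 5' non-CGI",
    "loss at gene body or 3' non-CGI",
)


@dataclass(frozen=True)
class DMR:
    """A differential bin, optionally annotated with CGI status and
    per-gene region assignments."""

    chrom: str
    start: int
    end: int
    level_a: float
    level_b: float
    delta: float                     # level_b - level_a
    direction: str                   # "gain" | "loss"
    contrast: str                    # e.g. "mDMR" | "dDMR"
    cgi: CgiStatus | None = None
    assignments: tuple[tuple[str | None, RegionCategory], ...] | None = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.start)

    @property
    def genes(self) -> tuple[str, ...]:
        if not self.assignments:
            return ()
        return tuple(sorted({g for g, _ in self.assignments if g is not None}))


def call_dmrs(
    profile_a: MethylationProfile,
    profile_b: MethylationProfile,
    threshold: float = DEFAULT_DMR_THRESHOLD,
    contrast: str = "mDMR",
) -> list[DMR]:
    """Call DMRs between two binned profiles.

    Only bins passing the filter in *both* profiles are compared; a DMR is
    emitted iff ``|level_b - level_a| > threshold`` (strictly greater — a
    bin changing by exactly the threshold is not a DMR).
    """
    if profile_a.bin_size != profile_b.bin_size:
        raise ConfigurationError(
            f"bin size mismatch: {profile_a.bin_size} vs {profile_b.bin_size}"
        )
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    dmrs: list[DMR] = []
    for key in sorted(set(profile_a.bins) & set(profile_b.bins)):
        a, b = profile_a.bins[key], profile_b.bins[key]
        if not (a.passes_filter and b.passes_filter):
            continue
        delta = b.level - a.level
        if abs(delta) > threshold:
            dmrs.append(
                DMR(
                    chrom=a.chrom,
                    start=a.start,
                    end=a.end,
                    level_a=a.level,
                    level_b=b.level,
                    delta=delta,
                    direction="gain" if delta > 0 else "loss",
                    contrast=contrast,
                )
            )
    return dmrs


def annotate_dmrs(
    dmrs: Sequence[DMR], cgi_index: CgiIndex, gene_index: GeneIndex
) -> list[DMR]:
    """Attach CGI status and per-gene region assignments to each DMR.

    A DMR overlapping several genes is assigned to every one of them
    (region distributions count bin-gene assignments, not unique genes).
    """
    out = []
    for d in dmrs:
        iv = GenomicInterval(d.chrom, d.start, d.end)
        out.append(
            replace(
                d,
                cgi=cgi_index.status(iv),
                assignments=tuple(sorted(
                    gene_index.classify(iv),
                    key=lambda a: (a[0] or "", a[1].value),
                )),
            )
        )
    return out


def group_label(direction: str, cgi: CgiStatus, region: RegionCategory) -> str:
    """Map (direction, CGI status, region) to one of the eight group labels."""
    if region is RegionCategory.INTERGENIC:
        raise ValidationError("intergenic assignments belong to no group")
    bucket = "5'" if region is RegionCategory.FIVE_PRIME else "gene body or 3'"
    island = "CGI" if cgi is CgiStatus.CGI else "non-CGI"
    return f"{direction} at {bucket} {island}"


@dataclass
class DmrGroupTable:
    """Counts of gene-associated DMR assignments in the eight groups."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for label in GROUP_LABELS:
            self.counts.setdefault(label, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def as_tsv(self) -> str:
        lines = ["group\tcount"]
        lines += [f"{label}\t{self.counts[label]}" for label in GROUP_LABELS]
        return "\n".join(lines) + "\n"


def classify_eight_groups(dmrs: Sequence[DMR]) -> DmrGroupTable:
    """Partition annotated, gene-associated DMRs into the eight groups.

    Each (DMR, gene) region assignment contributes exactly one count;
    intergenic DMRs are excluded.  Raises if a DMR lacks annotation.
    """
    counts: dict[str, int] = {label: 0 for label in GROUP_LABELS}
    for d in dmrs:
        if d.cgi is None or d.assignments is None:
            raise ValidationError(
                f"DMR {d.chrom}:{d.start} is missing CGI/region annotation"
            )
        for gene, region in d.assignments:
            if region is RegionCategory.INTERGENIC:
                continue
            counts[group_label(d.direction, d.cgi, region)] += 1
    return DmrGroupTable(counts)


def dmr_gene_lists(dmrs: Sequence[DMR]) -> dict[str, set[str]]:
    """Deduplicated gene sets per group; a gene with DMRs in two groups
    appears in both."""
    lists: dict[str, set[str]] = {label: set() for label in GROUP_LABELS}
    for d in dmrs:
        if d.cgi is None or d.assignments is None:
            raise ValidationError(
                f"DMR {d.chrom}:{d.start} is missing CGI/region annotation"
            )
        for gene, region in d.assignments:
            if gene is None or region is RegionCategory.INTERGENIC:
                continue
            lists[group_label(d.direction, d.cgi, region)].add(gene)
    return lists


def overlap_percentage(
    list_a: Iterable[str], list_b: Iterable[str]
) -> tuple[int, int, int]:
    """Shared-gene overlap of list_a with list_b as a floored integer
    percent of |list_a|.  Returns (shared, |list_a|, percent)."""
    a, b = set(list_a), set(list_b)
    if not a:
        raise UndefinedResultError("overlap percentage undefined for empty list_a")
    shared = len(a & b)
    return shared, len(a), (100 * shared) // len(a)


def merge_adjacent_dmrs(dmrs: Sequence[DMR]) -> list[DMR]:
    """Optionally merge book-ended same-direction bins into wider regions.

    Off by default in the pipeline — DMRs are counted at bin resolution —
    but provided for region-level reporting.  Levels of a merged run are
    unweighted means of its bins; delta is recomputed from them.
    """
    merged: list[DMR] = []
    run: list[DMR] = []

    def flush():
        if not run:
            return
        la = sum(d.level_a for d in run) / len(run)
        lb = sum(d.level_b for d in run) / len(run)
        merged.append(
            replace(
                run[0],
                end=run[-1].end,
                level_a=la,
                level_b=lb,
                delta=lb - la,
            )
        )
        run.clear()

    for d in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
        if (
            run
            and d.chrom == run[-1].chrom
            and d.start == run[-1].end
            and d.direction == run[-1].direction
        ):
            run.append(d)
        else:
            flush()
            run.append(d)
    flush()
    return merged


def dmrs_from_bed(bed_text: str) -> list[DMR]:
    """Re-load un-annotated DMRs from a persisted BED6+ track (inverse of
    :func:`dmrs_to_bed` up to annotation, which can be re-attached with
    :func:`annotate_dmrs`)."""
    out = []
    for lineno, raw in enumerate(bed_text.splitlines(), start=1):
        if not raw.strip():
            continue
        f = raw.split("\t")
        if len(f) < 8:
            raise ValidationError(f"line {lineno}: expected >= 8 BED columns")
        contrast, direction = f[3].split("|")[:2]
        la, lb = float(f[6]), float(f[7])
        out.append(
            DMR(
                chrom=f[0],
                start=int(f[1]),
                end=int(f[2]),
                level_a=la,
                level_b=lb,
                delta=lb - la,
                direction=direction,
                contrast=contrast,
            )
        )
    return out


def dmrs_to_bed(dmrs: Sequence[DMR]) -> str:
    """BED6+ track: name = contrast|direction|CGI|genes, score = |delta|
    (capped at 1000), strand '.'; extra columns carry the two levels."""
    lines = []
    for d in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
        genes = ",".join(d.genes) if d.genes else "."
        cgi = d.cgi.value if d.cgi is not None else "."
        name = f"{d.contrast}|{d.direction}|{cgi}|{genes}"
        score = min(1000, round(abs(d.delta)))
        lines.append(
            f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score}\t.\t"
            f"{d.level_a:.4f}\t{d.level_b:.4f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
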