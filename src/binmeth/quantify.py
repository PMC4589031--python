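"""Per-CpG bisulfite call counts and 200-bp bin methylation levels.

The quantification follows the bin rule used throughout this package: the
genome is tiled with fixed-phase 200-bp bins anchored at coordinate 0; a bin
is retained for analysis only if it contains at least two covered CpG sites
and at least ten calls in total, and its methylation level is the percentage
of methylated calls among all calls in the bin.  Bins with no covered CpG
are omitted rather than reported as 0% — absence of data is not
hypomethylation.

Input dialects: Bismark coverage files (1-based, start == end) and
bedGraph-with-counts (0-based, end == start + 1); the dialect is
auto-detected.  CpGs are palindromic, so by default the reverse-strand (G)
record at pos+1 is folded into the forward-strand C record.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UndefinedResultError, ValidationError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 200
DEFAULT_MIN_CPGS = 2
DEFAULT_MIN_CALLS = 10


@dataclass(frozen=True)
class CpGSiteCounts:
    """Methylated/unmethylated call counts at one CpG (forward-strand C)."""

    chrom: str
    pos: int
    meth: int
    unmeth: int

    def __post_init__(self) -> None:
        if self.meth < 0 or self.unmeth < 0:
            raise ValidationError(
                f"negative call count at {self.chrom}:{self.pos}"
            )

    @property
    def total(self) -> int:
        return self.meth + self.unmeth


@dataclass(frozen=True)
class BinMethylation:
    """One fixed-phase genomic bin with pooled CpG call counts."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    meth_calls: int
    total_calls: int
    level: float          # percent in [0, 100]
    passes_filter: bool

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.start)


@dataclass
class MethylationProfile:
    """A per-sample methylome: bins keyed by (chrom, start)."""

    sample: str
    bins: dict[tuple[str, int], BinMethylation]
    bin_size: int = DEFAULT_BIN_SIZE
    age: str | None = None
    cell_type: str | None = None

    def passing_bins(self) -> list[BinMethylation]:
        return [b for b in self.bins.values() if b.passes_filter]


def read_text(path) -> str:
    """Read a (possibly gzip-compressed) text file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return fh.read()


def _as_lines(source: str | Iterable[str]) -> Iterable[str]:
    if isinstance(source, str):
        return source.splitlines()
    return source


def read_cpg_counts(
    coverage_text: str | Iterable[str], merge_strands: bool = True
) -> list[CpGSiteCounts]:
    """Parse per-CpG counts from Bismark-coverage or bedGraph lines.

    Bismark coverage rows are 1-based with start == end; bedGraph rows are
    0-based half-open with end == start + 1.  The dialect is detected from
    the first data row.  With ``merge_strands`` (default), a record at
    pos+1 — the G of the palindromic CpG — is folded into the forward-strand
    record at pos, doubling effective depth.  Duplicate positions are summed
    with a logged warning.
    """
    records: list[tuple[str, int, int, int]] = []
    one_based: bool | None = None
    for lineno, raw in enumerate(_as_lines(coverage_text), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ParseError(f"expected 6 columns, got {len(fields)}", lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            meth, unmeth = int(fields[4]), int(fields[5])
        except ValueError as exc:
            raise ParseError(f"non-integer field: {exc}", lineno) from exc
        if meth < 0 or unmeth < 0:
            raise ParseError("negative call count", lineno)
        if one_based is None:
            one_based = start == end
        pos = start - 1 if one_based else start
        if pos < 0:
            raise ParseError(f"invalid position {start}", lineno)
        records.append((chrom, pos, meth, unmeth))

    records.sort(key=lambda r: (r[0], r[1]))

    # collapse exact duplicates first (warn), then fold pos+1 onto pos
    deduped: list[list] = []
    for chrom, pos, m, u in records:
        if deduped and deduped[-1][0] == chrom and deduped[-1][1] == pos:
            logger.warning("duplicate CpG record at %s:%d; summing counts", chrom, pos)
            deduped[-1][2] += m
            deduped[-1][3] += u
        else:
            deduped.append([chrom, pos, m, u])

    out: list[CpGSiteCounts] = []
    for chrom, pos, m, u in deduped:
        if (
            merge_strands
            and out
            and out[-1].chrom == chrom
            and pos == out[-1].pos + 1
        ):
            prev = out[-1]
            out[-1] = CpGSiteCounts(chrom, prev.pos, prev.meth + m, prev.unmeth + u)
        else:
            out.append(CpGSiteCounts(chrom, pos, m, u))
    return out


def bin_methylation(
    sites: Sequence[CpGSiteCounts],
    bin_size: int = DEFAULT_BIN_SIZE,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_calls: int = DEFAULT_MIN_CALLS,
) -> list[BinMethylation]:
    """Pool per-CpG counts into fixed-phase bins tiled from coordinate 0.

    A site at ``pos`` belongs to bin ``floor(pos / bin_size)``.  The level is
    ``100 * meth_calls / total_calls``; a bin passes the filter iff it has at
    least ``min_cpgs`` covered CpGs and ``min_calls`` total calls.  Bins with
    zero covered CpGs are omitted.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    acc: dict[tuple[str, int], list[int]] = {}
    for s in sites:
        if s.total == 0:
            continue
        key = (s.chrom, (s.pos // bin_size) * bin_size)
        slot = acc.setdefault(key, [0, 0, 0])  # n_cpgs, meth, total
        slot[0] += 1
        slot[1] += s.meth
        slot[2] += s.total
    bins = []
    for (chrom, start) in sorted(acc):
        n, m, t = acc[(chrom, start)]
        bins.append(
            BinMethylation(
                chrom=chrom,
                start=start,
                end=start + bin_size,
                n_cpgs=n,
                meth_calls=m,
                total_calls=t,
                level=100.0 * m / t,
                passes_filter=(n >= min_cpgs and t >= min_calls),
            )
        )
    return bins


def profile_from_coverage(
    source,
    sample: str,
    age: str | None = None,
    cell_type: str | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    min_calls: int = DEFAULT_MIN_CALLS,
    merge_strands: bool = True,
    is_path: bool = False,
) -> MethylationProfile:
    """Build a :class:`MethylationProfile` from coverage text or a file path."""
    text = read_text(source) if is_path else source
    sites = read_cpg_counts(text, merge_strands=merge_strands)
    bins = bin_methylation(sites, bin_size, min_cpgs, min_calls)
    return MethylationProfile(
        sample=sample,
        bins={b.key: b for b in bins},
        bin_size=bin_size,
        age=age,
        cell_type=cell_type,
    )


def global_methylation(profile: MethylationProfile, mode: str = "site") -> float:
    """Genome-wide average methylation over passing bins, in percent.

    ``site`` mode pools calls (100 * sum meth / sum total) and so weights
    each CpG call equally; ``bin`` mode is the unweighted mean of bin levels
    and weights each bin equally.
    """
    passing = profile.passing_bins()
    if not passing:
        raise UndefinedResultError("no passing bins in profile")
    if mode == "site":
        meth = sum(b.meth_calls for b in passing)
        total = sum(b.total_calls for b in passing)
        return 100.0 * meth / total
    if mode == "bin":
        return sum(b.level for b in passing) / len(passing)
    raise ValidationError(f"unknown mode {mode!r}; use 'site' or 'bin'")


def category_mean(
    profile: MethylationProfile, members: Iterable[tuple[str, int]]
) -> tuple[float, int]:
    """Mean methylation level of a gene/CGI category.

    ``members`` are bin keys; the value is the unweighted mean of levels of
    the passing member bins.  Returns (mean percent, contributing bin count).
    """
    members = list(members)
    if not members:
        raise UndefinedResultError("empty member set")
    levels = [
        profile.bins[k].level
        for k in members
        if k in profile.bins and profile.bins[k].passes_filter
    ]
    if not levels:
        raise UndefinedResultError("no passing member bins")
    return sum(levels) / len(levels), len(levels)


def profile_from_bin_table(
    text: str,
    sample: str,
    age: str | None = None,
    cell_type: str | None = None,
) -> MethylationProfile:
    """Reconstruct a profile from a persisted bin table (inverse of
    :func:`bins_to_table`); bin size is inferred from the first row."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("chrom\t"):
        raise ParseError("bin table must start with its header row", 1)
    bins: dict[tuple[str, int], BinMethylation] = {}
    bin_size = DEFAULT_BIN_SIZE
    for lineno, ln in enumerate(lines[1:], start=2):
        f = ln.split("\t")
        if len(f) != 8:
            raise ParseError(f"expected 8 columns, got {len(f)}", lineno)
        b = BinMethylation(
            chrom=f[0],
            start=int(f[1]),
            end=int(f[2]),
            n_cpgs=int(f[3]),
            meth_calls=int(f[4]),
            total_calls=int(f[5]),
            level=float(f[6]),
            passes_filter=bool(int(f[7])),
        )
        bin_size = b.end - b.start
        bins[b.key] = b
    return MethylationProfile(sample, bins, bin_size, age, cell_type)


def bins_to_table(profile: MethylationProfile) -> str:
    """Tab-separated bin table (chrom, start, end, n_cpgs, meth_calls,
    total_calls, level, passes_filter)."""
    lines = ["chrom\tstart\tend\tn_cpgs\tmeth_calls\ttotal_calls\tlevel\tpasses_filter"]
    for key in sorted(profile.bins):
        b = profile.bins[key]
        lines.append(
            f"{b.chrom}\t{b.start}\t{b.end}\t{b.n_cpgs}\t{b.meth_calls}\t"
            f"{b.total_calls}\t{b.level:.4f}\t{int(b.passes_filter)}"
        )
    return "\n".join(lines) + "\n"
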