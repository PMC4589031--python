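"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(per-base marking, exhaustive enumeration) so the implementation is checked
against logic that shares none of its code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from binmeth.annotation import GeneModel, GenomicInterval, RegionCategory
from binmeth.quantify import BinMethylation, CpGSiteCounts, MethylationProfile
from binmeth.synthetic import SyntheticConfig


@pytest.fixture
def small_config() -> SyntheticConfig:
    """A reduced synthetic study (~0.6 Mb, 30 genes) for fast tests."""
    return SyntheticConfig(
        seed=7,
        n_chroms=1,
        chrom_length=600_000,
        n_genes=30,
        n_cgis=60,
        n_mat_3cgi_gain=4,
        n_mat_bodycgi_gain=2,
        n_mat_5cgi_gain=2,
        n_mat_3cgi_loss=1,
        n_mat_bodycgi_loss=1,
        n_mat_5cgi_loss=1,
        n_mat_shore5_loss=3,
        n_mat_shore3_loss=3,
        n_mat_noncgi_gain=2,
        n_diff_3cgi_gain=2,
        n_diff_shore_loss=2,
        n_uncoupled_genes=5,
    )


# ---------------------------------------------------------------------------
# per-base oracles


def union_by_marking(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Interval union computed by marking individual bases."""
    marked = np.zeros(length, dtype=bool)
    for s, e in intervals:
        marked[s:e] = True
    out, start = [], None
    for i, m in enumerate(marked):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


def cgi_overlap_by_marking(
    bin_iv: tuple[int, int], cgis: list[tuple[int, int]], length: int
) -> bool:
    marked = np.zeros(length, dtype=bool)
    for s, e in cgis:
        marked[s:e] = True
    s, e = bin_iv
    return bool(marked[s:e].any())


def region_marks(
    gene: GeneModel, promoter_span: int, length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-base boolean marks (3'-end, 5'-end, gene-or-promoter span) for
    one gene, derived from first principles."""
    three = np.zeros(length, dtype=bool)
    five = np.zeros(length, dtype=bool)
    span = np.zeros(length, dtype=bool)
    span[gene.tx_start:gene.tx_end] = True

    exons = list(gene.exons)
    if gene.strand == "+":
        first_exon, last_exon = exons[0], exons[-1]
        promoter = (max(0, gene.tx_start - promoter_span), gene.tx_start)
        utr5 = (gene.tx_start, gene.cds_start)
        utr3 = (gene.cds_end, gene.tx_end)
    else:
        first_exon, last_exon = exons[-1], exons[0]
        promoter = (gene.tx_end, min(length, gene.tx_end + promoter_span))
        utr5 = (gene.cds_end, gene.tx_end)
        utr3 = (gene.tx_start, gene.cds_start)

    three[last_exon[0]:last_exon[1]] = True
    five[first_exon[0]:first_exon[1]] = True
    five[promoter[0]:promoter[1]] = True
    span[promoter[0]:promoter[1]] = True
    if gene.cds_start < gene.cds_end:  # UTRs exist only for coding genes
        for s, e in exons:
            a, b = max(s, utr5[0]), min(e, utr5[1])
            if a < b:
                five[a:b] = True
            a, b = max(s, utr3[0]), min(e, utr3[1])
            if a < b:
                three[a:b] = True
    return three, five, span


def region_from_marks(
    bin_iv: tuple[int, int], marks: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> RegionCategory | None:
    """Apply the THREE > FIVE > BODY precedence to per-base marks; None
    when the bin misses the gene (and its promoter window) entirely."""
    three, five, span = marks
    s, e = bin_iv
    if three[s:e].any():
        return RegionCategory.THREE_PRIME
    if five[s:e].any():
        return RegionCategory.FIVE_PRIME
    if span[s:e].any():
        return RegionCategory.GENE_BODY
    return None


def region_oracle(
    bin_iv: tuple[int, int], gene: GeneModel, promoter_span: int, length: int
) -> RegionCategory | None:
    """Per-base region classification of one bin against one gene."""
    return region_from_marks(bin_iv, region_marks(gene, promoter_span, length))


def binning_oracle(
    sites: list[CpGSiteCounts], bin_size: int
) -> dict[tuple[str, int], tuple[int, int, int]]:
    """Brute-force binning: scan every bin range and collect its sites."""
    out: dict[tuple[str, int], tuple[int, int, int]] = {}
    chroms = {s.chrom for s in sites}
    for chrom in chroms:
        chrom_sites = [s for s in sites if s.chrom == chrom and s.total > 0]
        if not chrom_sites:
            continue
        top = max(s.pos for s in chrom_sites) + bin_size
        for start in range(0, top, bin_size):
            inside = [s for s in chrom_sites if start <= s.pos < start + bin_size]
            if inside:
                out[(chrom, start)] = (
                    len(inside),
                    sum(s.meth for s in inside),
                    sum(s.total for s in inside),
                )
    return out


def fisher_two_sided_oracle(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all 2x2 tables with
    the observed margins, summing hypergeometric probabilities not
    exceeding the observed table's (minimum-likelihood rule)."""
    denom = math.comb(N, n)

    def prob(x: int) -> float:
        return math.comb(K, x) * math.comb(N - K, n - x) / denom

    p_obs = prob(k)
    lo, hi = max(0, n - (N - K)), min(K, n)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def make_profile(
    levels: dict[tuple[str, int], float],
    sample: str = "s",
    total_calls: int = 100,
    n_cpgs: int = 4,
    passes: dict[tuple[str, int], bool] | None = None,
    bin_size: int = 200,
) -> MethylationProfile:
    """Fabricate a profile with prescribed bin levels for statistics tests."""
    bins = {}
    for (chrom, start), level in levels.items():
        meth = round(level / 100.0 * total_calls)
        bins[(chrom, start)] = BinMethylation(
            chrom=chrom,
            start=start,
            end=start + bin_size,
            n_cpgs=n_cpgs,
            meth_calls=meth,
            total_calls=total_calls,
            level=level,
            passes_filter=True if passes is None else passes[(chrom, start)],
        )
    return MethylationProfile(sample, bins, bin_size)
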