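"""Synthetic WGBS study generator with ground truth.

Generates, from a single seed, everything the pipeline consumes: a
CGI-structured toy genome annotation (genes + CpG islands placed
preferentially at gene 5' and 3' ends), per-CpG bisulfite call counts for
four pooled samples (stem cells and differentiated epithelium at birth and
weaning), gene-set files, a methylation/expression time course, and
CpG-panel matrices for a conventional and a germ-free condition — plus a
machine-readable truth set of every planted differential region.

The statistical structure emulates the developing-intestine methylome the
pipeline is built for:

* non-CGI background is highly methylated (75%), CGIs are lowly
  methylated (10%);
* maturation (age) plants are dominated by CGI gains at gene-body/3'
  islands and non-CGI losses at island shores;
* differentiation plants are few, so age contrasts yield more DMRs than
  cell-type contrasts;
* genes whose 3' CGI gains methylation with age have expression positively
  coupled to that methylation;
* panel matrices separate cleanly by age under the conventional condition,
  while under germ-free conditions a block of 3'-CGI rows fails to gain
  methylation after birth; two constant high-methylation rows emulate
  generic repeat elements (Line1, IAP).

Counts are beta-binomially overdispersed: per CpG and sample, depth ~
Poisson(coverage_mean) and methylated calls ~ BetaBinomial(depth, level,
dispersion); dispersion=0 recovers pure binomial sampling for analytic
checks.  Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GenomicInterval, load_cgis
from .errors import ConfigurationError, ValidationError
from .stats import ExprMethSeries, SamplePanel, write_gmt


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic generator.

    Defaults describe a desk-scale study: a 2 x 2 Mb genome with ~200 genes
    and ~300 CGIs at 20x coverage, runnable in seconds on one CPU.
    """

    seed: int = 0

    # genome layout
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (400, 2000)
    gene_gap_range: tuple[int, int] = (4000, 12000)

    # CpG islands
    n_cgis: int = 300
    cgi_length_range: tuple[int, int] = (600, 1500)
    cgi_5prime_frac: float = 0.45
    cgi_3prime_frac: float = 0.30
    cgi_body_frac: float = 0.10      # remainder is intergenic

    # CpG density (mean bases between consecutive CpGs)
    cpg_spacing_cgi: float = 10.0
    cpg_spacing_background: float = 100.0

    # counts
    coverage_mean: float = 20.0
    dispersion: float = 0.05         # beta-binomial rho in [0, 1)
    baseline_noncgi: float = 75.0    # percent
    baseline_cgi: float = 10.0
    elevated_cgi_baseline: float = 55.0   # start level of CGIs planted to lose
    diff_global_shift: float = -3.0  # non-CGI shift in differentiated cells

    # planted DMRs (maturation = P0 -> P21 in both cell types;
    # differentiation = ISC -> differentiated at both ages)
    dmr_delta: float = 30.0
    noncgi_gain_delta: float = 20.0  # headroom-limited (see docs)
    shore_length: int = 500
    noncgi_window: int = 400
    n_mat_3cgi_gain: int = 30
    n_mat_bodycgi_gain: int = 12
    n_mat_5cgi_gain: int = 8
    n_mat_3cgi_loss: int = 3
    n_mat_bodycgi_loss: int = 3
    n_mat_5cgi_loss: int = 4
    n_mat_shore5_loss: int = 20
    n_mat_shore3_loss: int = 20
    n_mat_noncgi_gain: int = 15
    n_diff_3cgi_gain: int = 8
    n_diff_shore_loss: int = 10

    ages: tuple[str, ...] = ("P0", "P21")
    cell_types: tuple[str, ...] = ("ISC", "Diff")

    # expression time course
    expression_ages: tuple[tuple[str, float], ...] = (
        ("P0", 0.0), ("P21", 21.0), ("P100", 100.0), ("P300", 300.0),
    )
    expression_replicates: int = 3
    expression_coupling: float = 0.04   # expression units per methylation point
    expression_noise_sd: float = 0.10
    expression_intercept: float = 0.20
    expression_age_slope: float = 0.0005
    meth_obs_noise_sd: float = 3.0
    meth_gain_tau_days: float = 7.0     # half-rise time of postnatal gains
    n_uncoupled_genes: int = 20

    # CpG panels
    panel_ages: tuple[str, ...] = ("P0", "P21", "P100")
    panel_samples_per_age: int = 3
    panel_sites_per_gene: int = 6
    panel_gain_genes: int = 6
    panel_loss_genes: int = 4
    panel_stable_genes: int = 5
    panel_blocked_genes: int = 4        # gain genes that fail to gain under GF
    panel_noise_sd: float = 2.0
    panel_site_offset_sd: float = 3.0

    def validate(self) -> None:
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ConfigurationError("genome dimensions must be positive")
        if not (0 <= self.dispersion < 1):
            raise ConfigurationError("dispersion must be in [0, 1)")
        if self.coverage_mean < 1:
            raise ConfigurationError("coverage_mean must be >= 1")
        if not (0 < self.dmr_delta < 100):
            raise ConfigurationError("dmr_delta must be in (0, 100)")


# ---------------------------------------------------------------------------
# internal layout


@dataclass(frozen=True)
class _Gene:
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class _Cgi:
    chrom: str
    start: int
    end: int
    kind: str            # "5prime" | "3prime" | "body" | "intergenic"
    gene: str | None


@dataclass
class _Layout:
    genes: list[_Gene]
    cgis: list[_Cgi]


def _build_layout(config: SyntheticConfig) -> _Layout:
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes: list[_Gene] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    gi = 0
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        cursor = 5000
        for _ in range(per_chrom[ci]):
            n_ex = int(rng.integers(config.exon_count_range[0],
                                    config.exon_count_range[1] + 1))
            ex_lens = rng.integers(config.exon_length_range[0],
                                   config.exon_length_range[1] + 1, n_ex)
            in_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1,
                                   max(0, n_ex - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for j in range(n_ex):
                exons.append((pos, pos + int(ex_lens[j])))
                pos = exons[-1][1]
                if j < n_ex - 1:
                    pos += int(in_lens[j])
            tx_start, tx_end = exons[0][0], exons[-1][1]
            if tx_end > config.chrom_length - 5000:
                raise ConfigurationError(
                    "infeasible packing: too many/large genes for chrom_length"
                )
            cds_start = tx_start + int(rng.integers(30, 91))
            cds_end = tx_end - int(rng.integers(30, 91))
            gi += 1
            genes.append(
                _Gene(f"g{gi:04d}", chrom, strand, tx_start, tx_end,
                      cds_start, cds_end, tuple(exons))
            )
            cursor = tx_end + int(rng.integers(config.gene_gap_range[0],
                                               config.gene_gap_range[1] + 1))

    cgis: list[_Cgi] = []
    n5 = round(config.n_cgis * config.cgi_5prime_frac)
    n3 = round(config.n_cgis * config.cgi_3prime_frac)
    nb = round(config.n_cgis * config.cgi_body_frac)
    ni = max(0, config.n_cgis - n5 - n3 - nb)
    if n5 > len(genes) or n3 > len(genes) or nb > len(genes):
        raise ConfigurationError("more gene-end CGIs requested than genes")

    def pick(n: int) -> list[int]:
        return sorted(rng.choice(len(genes), size=n, replace=False).tolist())

    for idx in pick(n5):
        g = genes[idx]
        L = int(rng.integers(*config.cgi_length_range))
        if g.strand == "+":
            start = max(0, g.tx_start - round(0.4 * L))
        else:
            start = max(0, g.tx_end + round(0.4 * L) - L)
        cgis.append(_Cgi(g.chrom, start, start + L, "5prime", g.name))
    for idx in pick(n3):
        g = genes[idx]
        L = int(rng.integers(*config.cgi_length_range))
        if g.strand == "+":
            end = g.tx_end + round(0.3 * L)
            start = end - L
        else:
            start = max(0, g.tx_start - round(0.3 * L))
        cgis.append(_Cgi(g.chrom, start, start + L, "3prime", g.name))
    for idx in pick(nb):
        g = genes[idx]
        lo, hi = g.exons[0][1] + 100, g.exons[-1][0] - 100
        if hi - lo < 400:
            continue
        L = min(int(rng.integers(*config.cgi_length_range)), hi - lo)
        mid = (lo + hi) // 2
        start = max(lo, mid - L // 2)
        cgis.append(_Cgi(g.chrom, start, min(hi, start + L), "body", g.name))

    # intergenic CGIs in the gaps between extended gene spans
    gaps = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        spans = sorted(
            (g.tx_start - 2500, g.tx_end + 2500)
            for g in genes if g.chrom == chrom
        )
        prev = 2000
        for s, e in spans:
            if s - prev > 4000:
                gaps.append((chrom, prev, s))
            prev = max(prev, e)
    for j in range(ni):
        if not gaps:
            break
        chrom, s, e = gaps[j % len(gaps)]
        L = int(rng.integers(*config.cgi_length_range))
        mid = (s + e) // 2 + (j // len(gaps)) * 3000
        if mid + L // 2 >= e - 500:
            continue
        cgis.append(_Cgi(chrom, mid - L // 2, mid - L // 2 + L, "intergenic", None))

    cgis.sort(key=lambda c: (c.chrom, c.start))
    return _Layout(genes, cgis)


# ---------------------------------------------------------------------------
# annotation output


def generate_annotation(config: SyntheticConfig) -> tuple[str, str]:
    """Return (CGI BED text, refFlat text) for the configured genome."""
    layout = _build_layout(config)
    bed_lines = [
        f"{c.chrom}\t{c.start}\t{c.end}\tCGI_{i + 1:05d}"
        for i, c in enumerate(layout.cgis)
    ]
    rf_lines = []
    for g in layout.genes:
        starts = ",".join(str(s) for s, _ in g.exons) + ","
        ends = ",".join(str(e) for _, e in g.exons) + ","
        rf_lines.append(
            f"{g.name}\t{g.name}.1\t{g.chrom}\t{g.strand}\t{g.tx_start}\t"
            f"{g.tx_end}\t{g.cds_start}\t{g.cds_end}\t{len(g.exons)}\t"
            f"{starts}\t{ends}"
        )
    return "\n".join(bed_lines) + "\n", "\n".join(rf_lines) + "\n"


# ---------------------------------------------------------------------------
# truth planning


@dataclass(frozen=True)
class PlantedDmr:
    chrom: str
    start: int
    end: int
    kind: str           # 5cgi | 3cgi | bodycgi | shore5 | shore3 | noncgi_body
    direction: str      # gain | loss
    delta: float        # signed percentage points
    contrast: str       # maturation | differentiation
    gene: str
    base_override: float | None = None   # elevated starting level, if any


@dataclass
class TruthSet:
    """Planted differential regions plus the expression gene roles."""

    dmrs: list[PlantedDmr]
    coupled_genes: list[str]
    uncoupled_genes: list[str]

    def planted_bins(self, contrast: str, bin_size: int = 200) -> set[tuple[str, int]]:
        """Bins fully contained in a planted interval of the contrast —
        the bins whose every CpG carries the planted shift."""
        out: set[tuple[str, int]] = set()
        for d in self.dmrs:
            if d.contrast != contrast:
                continue
            start = math.ceil(d.start / bin_size) * bin_size
            while start + bin_size <= d.end:
                out.add((d.chrom, start))
                start += bin_size
        return out

    def disturbed_bins(self, bin_size: int = 200) -> set[tuple[str, int]]:
        """Bins overlapping *any* planted or baseline-overridden interval
        by >= 1 bp; everything else is a clean null bin."""
        out: set[tuple[str, int]] = set()
        for d in self.dmrs:
            start = (d.start // bin_size) * bin_size
            while start < d.end:
                out.add((d.chrom, start))
                start += bin_size
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "dmrs": [asdict(d) for d in self.dmrs],
                "coupled_genes": self.coupled_genes,
                "uncoupled_genes": self.uncoupled_genes,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        obj = json.loads(text)
        return cls(
            dmrs=[PlantedDmr(**d) for d in obj["dmrs"]],
            coupled_genes=list(obj["coupled_genes"]),
            uncoupled_genes=list(obj["uncoupled_genes"]),
        )


def _interior_window(cgi: _Cgi, gene: _Gene, length: int) -> tuple[int, int]:
    """A shore window on the gene-interior side of a gene-end CGI."""
    gene_mid = (gene.tx_start + gene.tx_end) // 2
    cgi_mid = (cgi.start + cgi.end) // 2
    if cgi_mid <= gene_mid:
        return cgi.end, cgi.end + length
    return cgi.start - length, cgi.start


def plan_truth(config: SyntheticConfig) -> TruthSet:
    """Deterministically select planted DMR intervals from the layout."""
    layout = _build_layout(config)
    rng = np.random.default_rng([config.seed, 6])
    genes_by_name = {g.name: g for g in layout.genes}
    pools = {
        kind: [c for c in layout.cgis if c.kind == kind]
        for kind in ("5prime", "3prime", "body")
    }
    for pool in pools.values():
        rng.shuffle(pool)  # in-place deterministic shuffle

    def take(kind: str, n: int) -> list[_Cgi]:
        pool = pools[kind]
        if len(pool) < n:
            raise ConfigurationError(
                f"not enough {kind} CGIs for requested plants"
            )
        picked, pools[kind] = pool[:n], pool[n:]
        return picked

    delta = config.dmr_delta
    plants: list[PlantedDmr] = []

    def add_cgi(cgi: _Cgi, kind: str, direction: str, contrast: str) -> None:
        d = delta if direction == "gain" else -delta
        override = config.elevated_cgi_baseline if direction == "loss" else None
        plants.append(
            PlantedDmr(cgi.chrom, cgi.start, cgi.end, kind, direction, d,
                       contrast, cgi.gene or "", base_override=override)
        )

    gain3 = take("3prime", config.n_mat_3cgi_gain)
    for c in gain3:
        add_cgi(c, "3cgi", "gain", "maturation")
    for c in take("body", config.n_mat_bodycgi_gain):
        add_cgi(c, "bodycgi", "gain", "maturation")
    for c in take("5prime", config.n_mat_5cgi_gain):
        add_cgi(c, "5cgi", "gain", "maturation")
    for c in take("3prime", config.n_mat_3cgi_loss):
        add_cgi(c, "3cgi", "loss", "maturation")
    for c in take("body", config.n_mat_bodycgi_loss):
        add_cgi(c, "bodycgi", "loss", "maturation")
    for c in take("5prime", config.n_mat_5cgi_loss):
        add_cgi(c, "5cgi", "loss", "maturation")
    for c in take("3prime", config.n_diff_3cgi_gain):
        add_cgi(c, "3cgi", "gain", "differentiation")

    all_cgi_ivs = [(c.chrom, c.start, c.end) for c in layout.cgis]

    def clear_of_cgis(chrom: str, s: int, e: int) -> bool:
        return not any(
            ch == chrom and cs < e and s < ce for ch, cs, ce in all_cgi_ivs
        )

    def add_shores(kind_cgi: str, kind_name: str, n: int, contrast: str) -> None:
        added = 0
        while added < n and pools[kind_cgi]:
            c = take(kind_cgi, 1)[0]
            g = genes_by_name[c.gene]
            s, e = _interior_window(c, g, config.shore_length)
            if s < 0 or not clear_of_cgis(c.chrom, s, e):
                continue
            plants.append(
                PlantedDmr(c.chrom, s, e, kind_name, "loss", -delta,
                           contrast, c.gene or "")
            )
            added += 1
        if added < n:
            raise ConfigurationError("could not place requested shore plants")

    add_shores("5prime", "shore5", config.n_mat_shore5_loss, "maturation")
    add_shores("3prime", "shore3", config.n_mat_shore3_loss, "maturation")
    add_shores("3prime", "shore3", config.n_diff_shore_loss, "differentiation")

    # non-CGI gains inside internal introns of genes without body CGIs
    used_genes = {p.gene for p in plants}
    body_hosts = {c.gene for c in layout.cgis if c.kind == "body"}
    candidates = [
        g for g in layout.genes
        if g.name not in used_genes and g.name not in body_hosts
    ]
    rng.shuffle(candidates)
    added = 0
    for g in candidates:
        if added >= config.n_mat_noncgi_gain:
            break
        introns = [
            (g.exons[i][1], g.exons[i + 1][0])
            for i in range(len(g.exons) - 1)
            if g.exons[i + 1][0] - g.exons[i][1] >= config.noncgi_window + 100
        ]
        if not introns:
            continue
        s0, e0 = introns[len(introns) // 2]
        mid = (s0 + e0) // 2
        s = mid - config.noncgi_window // 2
        e = s + config.noncgi_window
        if not clear_of_cgis(g.chrom, s, e):
            continue
        plants.append(
            PlantedDmr(g.chrom, s, e, "noncgi_body", "gain",
                       config.noncgi_gain_delta, "maturation", g.name)
        )
        added += 1
    if added < config.n_mat_noncgi_gain:
        raise ConfigurationError("could not place requested intronic gains")

    coupled = sorted(c.gene for c in gain3 if c.gene)
    used = {p.gene for p in plants}
    free = [g.name for g in layout.genes if g.name not in used]
    rng.shuffle(free)
    uncoupled = sorted(free[: config.n_uncoupled_genes])
    return TruthSet(plants, coupled, uncoupled)


# ---------------------------------------------------------------------------
# counts


def _cpg_positions(config: SyntheticConfig, cgi_ivs: dict[str, list[tuple[int, int]]],
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """CpG coordinates per chromosome: sparse background plus dense CGIs.

    Inter-CpG gaps are 2 + Exponential(mean - 2) bases, so sites never
    collide (a CpG occupies two bases)."""
    out: dict[str, np.ndarray] = {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n_bg = int(config.chrom_length / max(config.cpg_spacing_background, 3) * 1.3) + 10
        gaps = 2 + rng.exponential(config.cpg_spacing_background - 2, n_bg)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos < config.chrom_length - 2]
        ivs = cgi_ivs.get(chrom, [])
        if ivs:
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            pos = pos[~inside]
            dense = []
            for s, e in ivs:
                m = int((e - s) / max(config.cpg_spacing_cgi, 3) * 1.5) + 5
                g = 2 + rng.exponential(config.cpg_spacing_cgi - 2, m)
                p = s + np.cumsum(g).astype(np.int64)
                dense.append(p[p < e])
            pos = np.concatenate([pos, *dense])
        pos = np.unique(pos)
        out[chrom] = pos
    return out


def _sample_names(config: SyntheticConfig) -> list[tuple[str, str, str]]:
    """(sample name, cell type, age) in a fixed deterministic order."""
    return [
        (f"{cell}_{age}", cell, age)
        for cell in config.cell_types
        for age in config.ages
    ]


def generate_counts(
    config: SyntheticConfig,
    annotation: tuple[str, str] | None = None,
    truth: TruthSet | None = None,
) -> tuple[dict[str, str], list[dict[str, str]]]:
    """Simulate per-sample Bismark-coverage files.

    Returns (sample name -> coverage text, sample metadata records).  The
    emitted counts are already strand-merged onto the forward-strand C.
    Maturation plants shift every age after the first, in both cell types;
    differentiation plants shift the differentiated cell type at all ages.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    if truth is None:
        truth = plan_truth(config)
    cgi_bed, _ = annotation
    cgis = load_cgis(cgi_bed)
    cgi_ivs: dict[str, list[tuple[int, int]]] = {}
    for c in cgis:
        cgi_ivs.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end)
        )
    for ivs in cgi_ivs.values():
        ivs.sort()

    pos_rng = np.random.default_rng([config.seed, 1])
    positions = _cpg_positions(config, cgi_ivs, pos_rng)

    # per-chromosome compartment baselines and plant masks
    base: dict[str, np.ndarray] = {}
    in_cgi: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        ivs = cgi_ivs.get(chrom, [])
        mask = np.zeros(len(pos), dtype=bool)
        if ivs:
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            idx = np.searchsorted(starts, pos, side="right") - 1
            mask = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        in_cgi[chrom] = mask
        b = np.where(mask, config.baseline_cgi, config.baseline_noncgi).astype(float)
        base[chrom] = b
    for d in truth.dmrs:
        if d.base_override is not None and d.chrom in positions:
            pos = positions[d.chrom]
            sel = (pos >= d.start) & (pos < d.end)
            base[d.chrom][sel] = d.base_override

    later_ages = set(config.ages[1:])
    diff_cell = config.cell_types[1] if len(config.cell_types) > 1 else None

    count_rng = np.random.default_rng([config.seed, 2])
    samples: dict[str, str] = {}
    meta: list[dict[str, str]] = []
    for name, cell, age in _sample_names(config):
        lines: list[str] = []
        for chrom in sorted(positions):
            pos = positions[chrom]
            mu = base[chrom].copy()
            if cell == diff_cell:
                mu[~in_cgi[chrom]] += config.diff_global_shift
            for d in truth.dmrs:
                if d.chrom != chrom:
                    continue
                applies = (
                    d.contrast == "maturation" and age in later_ages
                ) or (
                    d.contrast == "differentiation" and cell == diff_cell
                )
                if applies:
                    sel = (pos >= d.start) & (pos < d.end)
                    mu[sel] += d.delta
            p = np.clip(mu, 0.5, 99.5) / 100.0
            depth = count_rng.poisson(config.coverage_mean, len(pos))
            if config.dispersion > 0:
                conc = (1.0 - config.dispersion) / config.dispersion
                ps = count_rng.beta(p * conc, (1.0 - p) * conc)
            else:
                ps = p
            meth = count_rng.binomial(depth, ps)
            keep = depth > 0
            for pi, di, mi in zip(pos[keep], depth[keep], meth[keep]):
                pct = 100.0 * mi / di
                lines.append(
                    f"{chrom}\t{pi + 1}\t{pi + 1}\t{pct:.4f}\t{mi}\t{di - mi}"
                )
        samples[name] = "\n".join(lines) + "\n"
        meta.append({"sample": name, "cell_type": cell, "age": age})
    return samples, meta


# ---------------------------------------------------------------------------
# expression


def _meth_trajectory(age_days: float, base: float, gain: float, tau: float) -> float:
    return base + gain * age_days / (age_days + tau)


def simulate_expression_series(
    coupling: float,
    seed: int | Sequence[int],
    config: SyntheticConfig | None = None,
    gene: str = "g",
) -> ExprMethSeries:
    """One gene's methylation/expression time course.

    Methylation follows the postnatal 3'-CGI gain trajectory (saturating
    rise from the CGI baseline) with per-observation noise; expression is
    ``intercept + coupling * methylation + age_slope * age + noise``.
    Used both by :func:`generate_expression` and for calibration
    replicates.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    ages, meths, exprs = [], [], []
    for _, day in cfg.expression_ages:
        for _ in range(cfg.expression_replicates):
            mu = _meth_trajectory(day, cfg.baseline_cgi, cfg.dmr_delta,
                                  cfg.meth_gain_tau_days)
            m = float(np.clip(mu + rng.normal(0, cfg.meth_obs_noise_sd), 0, 100))
            e = (
                cfg.expression_intercept
                + coupling * m
                + cfg.expression_age_slope * day
                + rng.normal(0, cfg.expression_noise_sd)
            )
            ages.append(day)
            meths.append(m)
            exprs.append(float(e))
    return ExprMethSeries(gene, tuple(ages), tuple(meths), tuple(exprs))


def generate_expression(
    config: SyntheticConfig, truth: TruthSet | None = None
) -> pd.DataFrame:
    """Expression/methylation time-course table for coupled (planted 3'-CGI
    gain) and uncoupled control genes.

    Expression values are relative to a simulated reference gene: each
    sample's raw value is divided by a reference factor near 1.
    Columns: gene, age_label, age_days, replicate, methylation, expression,
    coupled.
    """
    if truth is None:
        truth = plan_truth(config)
    rng = np.random.default_rng([config.seed, 3])
    rows = []
    roles = [(g, True) for g in truth.coupled_genes] + [
        (g, False) for g in truth.uncoupled_genes
    ]
    for gene, coupled in roles:
        for label, day in config.expression_ages:
            for rep in range(config.expression_replicates):
                if coupled:
                    mu = _meth_trajectory(day, config.baseline_cgi,
                                          config.dmr_delta,
                                          config.meth_gain_tau_days)
                else:
                    mu = config.baseline_cgi
                m = float(np.clip(mu + rng.normal(0, config.meth_obs_noise_sd),
                                  0, 100))
                raw = (
                    config.expression_intercept
                    + (config.expression_coupling * m if coupled else
                       config.expression_coupling * config.baseline_cgi)
                    + config.expression_age_slope * day
                    + rng.normal(0, config.expression_noise_sd)
                )
                ref = 1.0 + rng.normal(0, 0.02)
                rows.append(
                    (gene, label, day, rep + 1, round(m, 4),
                     round(raw / ref, 6), coupled)
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "age_label", "age_days", "replicate",
                 "methylation", "expression", "coupled"],
    )


# ---------------------------------------------------------------------------
# panels


def generate_panel(
    config: SyntheticConfig, condition: str = "CNV"
) -> tuple[SamplePanel, dict[str, str]]:
    """A CpG-site x sample percent-methylation panel for one condition.

    Conditions: ``CNV`` (conventional — full developmental trajectories)
    or ``GF`` (germ-free — a planted block of gain-type rows fails to gain
    methylation after the first age).  Two repeat-element rows (Line1,
    IAP) have identical, age-invariant means under both conditions.
    Returns (panel, row -> role map); roles are ``gain``, ``gf_blocked``
    (gain rows that stall under GF), ``loss``, ``stable``, ``repeat``.
    """
    if condition not in ("CNV", "GF"):
        raise ValidationError("condition must be 'CNV' or 'GF'")
    if len(config.panel_ages) < 2 or config.panel_samples_per_age < 2:
        raise ValidationError("panel needs >= 2 ages and >= 2 samples per age")
    n_ages = len(config.panel_ages)

    def ramp(levels: Sequence[float]) -> list[float]:
        # interpolate a per-age trajectory onto however many ages are set
        xs = np.linspace(0, 1, len(levels))
        xq = np.linspace(0, 1, n_ages)
        return list(np.interp(xq, xs, levels))

    trajectories = {
        "gain": ramp([12.0, 35.0, 42.0]),
        "loss": ramp([75.0, 52.0, 45.0]),
        "stable": ramp([60.0, 60.0, 60.0]),
    }

    site_rng = np.random.default_rng([config.seed, 4])
    rows: list[tuple[str, str, np.ndarray]] = []  # (row id, role, age means)
    gene_i = 0
    for role, n_genes in (
        ("gain", config.panel_gain_genes),
        ("loss", config.panel_loss_genes),
        ("stable", config.panel_stable_genes),
    ):
        for k in range(n_genes):
            gene_i += 1
            gene = f"pg{gene_i:03d}"
            blocked = role == "gain" and k < config.panel_blocked_genes
            row_role = "gf_blocked" if blocked else role
            for s in range(config.panel_sites_per_gene):
                offset = site_rng.normal(0, config.panel_site_offset_sd)
                means = np.array(trajectories[role]) + offset
                if blocked and condition == "GF":
                    means = np.full(n_ages, means[0])
                rows.append((f"{gene}_s{s + 1}", row_role, means))
    for rep, level in (("Line1", 80.0), ("IAP", 85.0)):
        rows.append((rep, "repeat", np.full(n_ages, level)))

    noise_rng = np.random.default_rng(
        [config.seed, 5, 0 if condition == "CNV" else 1]
    )
    cols, ages, conds, data = [], [], [], []
    for ai, age in enumerate(config.panel_ages):
        for r in range(config.panel_samples_per_age):
            cols.append(f"{condition}_{age}_r{r + 1}")
            ages.append(age)
            conds.append(condition)
            col = np.array([m[ai] for _, _, m in rows])
            col = np.clip(col + noise_rng.normal(0, config.panel_noise_sd,
                                                 len(rows)), 0, 100)
            data.append(col)
    values = pd.DataFrame(
        np.column_stack(data), index=[rid for rid, _, _ in rows], columns=cols
    )
    roles = {rid: role for rid, role, _ in rows}
    return SamplePanel(values, tuple(ages), tuple(conds)), roles


# ---------------------------------------------------------------------------
# whole-dataset writer


def _term_sets(truth: TruthSet, all_genes: list[str],
               rng: np.random.Generator) -> dict[str, set[str]]:
    """Gene-set terms for enrichment: one term per planted-gene group plus
    random decoys."""
    shore_genes = sorted({
        d.gene for d in truth.dmrs if d.kind.startswith("shore") and d.gene
    })
    decoy_pool = [g for g in all_genes if g not in set(truth.coupled_genes)]
    sets: dict[str, set[str]] = {
        "GLYCAN_BIOSYNTHESIS": set(truth.coupled_genes)
        | set(rng.choice(decoy_pool, size=5, replace=False).tolist()),
        "SHORE_LOSS_PROGRAM": set(shore_genes),
    }
    for i in range(8):
        sets[f"DECOY_{i + 1:02d}"] = set(
            rng.choice(all_genes, size=15, replace=False).tolist()
        )
    return sets


def generate_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic study to ``outdir`` and return the paths.

    Emits: per-sample Bismark coverage files, CGI BED, refFlat, GMT gene
    sets, expression TSV, CNV/GF panel TSVs, truth JSON, a sample sheet,
    and a config snapshot.
    """
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    cgi_bed, refflat = generate_annotation(config)
    truth = plan_truth(config)
    samples, meta = generate_counts(config, (cgi_bed, refflat), truth)

    paths: dict[str, Path] = {}

    def write(name: str, rel: str, text: str) -> None:
        p = outdir / rel
        p.write_text(text)
        paths[name] = p

    write("cgi_bed", "cgi.bed", cgi_bed)
    write("refflat", "genes.refflat", refflat)
    for name, text in samples.items():
        write(f"coverage:{name}", f"coverage/{name}.cov", text)
    sheet = ["sample\tpath\tcell_type\tage"]
    for m in meta:
        sheet.append(
            f"{m['sample']}\tcoverage/{m['sample']}.cov\t{m['cell_type']}\t{m['age']}"
        )
    write("samples", "samples.tsv", "\n".join(sheet) + "\n")

    all_genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    gmt_rng = np.random.default_rng([config.seed, 7])
    write("gmt", "genesets.gmt", write_gmt(_term_sets(truth, all_genes, gmt_rng)))

    expr = generate_expression(config, truth)
    write("expression", "expression.tsv",
          expr.to_csv(sep="\t", index=False))

    for cond in ("CNV", "GF"):
        panel, roles = generate_panel(config, cond)
        write(f"panel:{cond}", f"panel_{cond}.tsv", panel.to_tsv())
    _, roles = generate_panel(config, "CNV")
    write("panel_roles", "panel_roles.json", json.dumps(roles, indent=1))

    write("truth", "truth.json", truth.to_json())
    write("config", "config.json", json.dumps(asdict(config), indent=1))
    return paths
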