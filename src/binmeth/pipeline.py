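"""End-to-end orchestration of the two headline analyses.

``run_dmr_analysis`` drives DMR discovery: per-sample bin quantification,
maturation (age) and differentiation (cell-type) DMR calling, CGI/region
annotation, the eight-group tables, gene lists, optional gene-set
enrichment, and optional methylation-expression regression with BH FDR.

``run_panel_analysis`` drives the developmental-panel comparison:
unsupervised hierarchical clustering of the reference-condition samples,
transfer of the resulting site/age ordering onto the comparison condition,
and per-CpG condition comparisons (two-tailed t tests with BH FDR).

Every run writes its intermediate tables under the configured output
directory and returns a :class:`RunReport` whose JSON carries a provenance
block (parameters, seed, package version), so any reported count can be
traced to, and re-derived from, persisted inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    CgiIndex,
    GeneIndex,
    load_cgis,
    load_gene_models,
)
from .dmr import (
    annotate_dmrs,
    call_dmrs,
    classify_eight_groups,
    dmr_gene_lists,
    dmrs_to_bed,
    overlap_percentage,
)
from .errors import ConfigurationError, UndefinedResultError
from .quantify import (
    MethylationProfile,
    bins_to_table,
    global_methylation,
    profile_from_coverage,
    read_text,
)
from .stats import (
    ExprMethSeries,
    SamplePanel,
    age_adjusted_regression,
    bh_fdr,
    fisher_enrichment,
    global_proportion_test,
    hierarchical_cluster,
    read_gmt,
    two_sample_ttest,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Relative input paths are resolved against the directory of the sample
    sheet (or of the YAML file the config was loaded from).
    """

    outdir: Path = Path("binmeth_out")
    # DMR analysis inputs
    samples_tsv: Path | None = None       # sample, path, cell_type, age
    cgi_bed: Path | None = None
    refflat: Path | None = None
    gmt: Path | None = None
    expression_tsv: Path | None = None
    # panel analysis inputs
    panel_reference_tsv: Path | None = None
    panel_comparison_tsv: Path | None = None
    # parameters
    bin_size: int = 200
    min_cpgs: int = 2
    min_calls: int = 10
    dmr_threshold: float = 15.0
    promoter_span: int = 2000
    proportion_method: str = "sign"
    clustering_metric: str = "euclidean"
    clustering_method: str = "average"
    fdr_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for name in ("samples_tsv", "cgi_bed", "refflat", "gmt",
                     "expression_tsv", "panel_reference_tsv",
                     "panel_comparison_tsv"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.bin_size <= 0 or self.min_cpgs < 0 or self.min_calls < 0:
            raise ConfigurationError("bin parameters out of range")
        if self.dmr_threshold < 0 or self.promoter_span < 0:
            raise ConfigurationError("threshold/promoter_span must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        obj = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**obj)
        base = path.parent
        for name in ("samples_tsv", "cgi_bed", "refflat", "gmt",
                     "expression_tsv", "panel_reference_tsv",
                     "panel_comparison_tsv"):
            v = getattr(cfg, name)
            if v is not None and not v.is_absolute():
                setattr(cfg, name, base / v)
        return cfg

    def provenance(self) -> dict[str, Any]:
        d = {k: (str(v) if isinstance(v, Path) else v)
             for k, v in asdict(self).items()}
        d["version"] = __version__
        return d


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    analysis: str
    provenance: dict[str, Any]
    sections: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"analysis": self.analysis, "provenance": self.provenance,
             "sections": self.sections},
            indent=1,
            sort_keys=True,
        )


def _read_sample_sheet(path: Path) -> list[dict[str, str]]:
    rows = []
    lines = path.read_text().splitlines()
    if not lines:
        raise ConfigurationError(f"empty sample sheet {path}")
    header = lines[0].split("\t")
    required = {"sample", "path", "cell_type", "age"}
    if not required.issubset(header):
        raise ConfigurationError(
            f"sample sheet needs columns {sorted(required)}, got {header}"
        )
    for ln in lines[1:]:
        if not ln.strip():
            continue
        rec = dict(zip(header, ln.split("\t")))
        p = Path(rec["path"])
        rec["path"] = str(p if p.is_absolute() else path.parent / p)
        rows.append(rec)
    return rows


def _ordered_unique(values: Sequence[str]) -> list[str]:
    seen: list[str] = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def run_dmr_analysis(config: RunConfig) -> RunReport:
    """Quantify -> call DMRs -> classify -> (enrich, regress); see module
    docstring.  Raises :class:`ConfigurationError` before any compute when
    the sample metadata supports no age or cell-type contrast."""
    for name in ("samples_tsv", "cgi_bed", "refflat"):
        if getattr(config, name) is None:
            raise ConfigurationError(f"{name} is required for the DMR analysis")
    sheet = _read_sample_sheet(config.samples_tsv)
    ages = _ordered_unique([r["age"] for r in sheet])
    cells = _ordered_unique([r["cell_type"] for r in sheet])
    mat_contrasts = [
        (cell, ages[0], ages[-1])
        for cell in cells
        if len({r["age"] for r in sheet if r["cell_type"] == cell}) >= 2
    ]
    diff_contrasts = [
        (age, cells[0], cells[-1])
        for age in ages
        if len({r["cell_type"] for r in sheet if r["age"] == age}) >= 2
    ]
    if not mat_contrasts and not diff_contrasts:
        raise ConfigurationError(
            "sample metadata supports no maturation or differentiation contrast"
        )

    out = config.outdir
    (out / "bins").mkdir(parents=True, exist_ok=True)
    (out / "dmrs").mkdir(exist_ok=True)

    profiles: dict[tuple[str, str], MethylationProfile] = {}
    global_section = {}
    for rec in sheet:
        prof = profile_from_coverage(
            rec["path"],
            sample=rec["sample"],
            age=rec["age"],
            cell_type=rec["cell_type"],
            bin_size=config.bin_size,
            min_cpgs=config.min_cpgs,
            min_calls=config.min_calls,
            is_path=True,
        )
        profiles[(rec["cell_type"], rec["age"])] = prof
        (out / "bins" / f"{rec['sample']}.tsv").write_text(bins_to_table(prof))
        n_pass = len(prof.passing_bins())
        logger.info("%s: %d bins, %d passing", rec["sample"], len(prof.bins), n_pass)
        global_section[rec["sample"]] = {
            "site_mode_percent": round(global_methylation(prof, "site"), 4),
            "bin_mode_percent": round(global_methylation(prof, "bin"), 4),
            "bins": len(prof.bins),
            "passing_bins": n_pass,
        }

    cgi_index = CgiIndex(load_cgis(read_text(config.cgi_bed)))
    gene_models = load_gene_models(read_text(config.refflat))
    gene_index = GeneIndex(gene_models, promoter_span=config.promoter_span)
    universe = sorted({g.name for g in gene_models})

    dmr_section: dict[str, Any] = {}
    proportion_section: dict[str, Any] = {}
    gene_lists_by_contrast: dict[str, dict[str, set[str]]] = {}
    for label, (fixed, a_key, b_key, kind) in {
        **{
            f"mDMR_{cell}": (cell, (cell, a0), (cell, a1), "mDMR")
            for cell, a0, a1 in mat_contrasts
        },
        **{
            f"dDMR_{age}": (age, (c0, age), (c1, age), "dDMR")
            for age, c0, c1 in diff_contrasts
        },
    }.items():
        pa, pb = profiles[a_key], profiles[b_key]
        dmrs = annotate_dmrs(
            call_dmrs(pa, pb, threshold=config.dmr_threshold, contrast=kind),
            cgi_index,
            gene_index,
        )
        table = classify_eight_groups(dmrs)
        lists = dmr_gene_lists(dmrs)
        gene_lists_by_contrast[label] = lists
        (out / "dmrs" / f"{label}.bed").write_text(dmrs_to_bed(dmrs))
        (out / "dmrs" / f"{label}_groups.tsv").write_text(table.as_tsv())
        logger.info("%s: %d DMRs, %d gene-associated assignments",
                    label, len(dmrs), table.total())
        dmr_section[label] = {
            "n_dmrs": len(dmrs),
            "eight_groups": dict(table.counts),
            "gene_assigned_total": table.total(),
            "genes_per_group": {k: sorted(v) for k, v in lists.items()},
        }
        try:
            pt = global_proportion_test(pa, pb, method=config.proportion_method)
            proportion_section[label] = {
                "prop_bins_higher_in_a": round(pt.statistic, 6),
                "pvalue": pt.pvalue,
                "n_informative_bins": pt.n_informative,
                "method": pt.method,
            }
        except UndefinedResultError as exc:
            proportion_section[label] = {"skipped": str(exc)}

    sections: dict[str, Any] = {
        "global_methylation": global_section,
        "dmrs": dmr_section,
        "proportion_tests": proportion_section,
    }

    # overlap of maturation-DMR genes in differentiated cells with the
    # differentiation-DMR genes at the final age
    diff_cell = cells[-1] if len(cells) > 1 else None
    m_label, d_label = f"mDMR_{diff_cell}", f"dDMR_{ages[-1]}"
    if m_label in gene_lists_by_contrast and d_label in gene_lists_by_contrast:
        m_genes = set().union(*gene_lists_by_contrast[m_label].values())
        d_genes = set().union(*gene_lists_by_contrast[d_label].values())
        if m_genes:
            shared, size, pct = overlap_percentage(m_genes, d_genes)
            sections["mdmr_ddmr_gene_overlap"] = {
                "shared": shared, "mdmr_genes": size, "percent": pct,
            }

    # gene-set enrichment of the headline group (gain at gene body or 3' CGI)
    if config.gmt is not None:
        gene_sets = read_gmt(read_text(config.gmt))
        enr_section = {}
        for label in (f"mDMR_{cells[0]}",):
            if label not in gene_lists_by_contrast:
                continue
            group = "gain at gene body or 3' CGI"
            dmr_genes = gene_lists_by_contrast[label][group]
            results = fisher_enrichment(dmr_genes, gene_sets, universe)
            tsv = ["term\tk\tK\tn\tN\todds_ratio\tp\tp_bonf"]
            tsv += [
                f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.odds_ratio:.4g}\t"
                f"{r.p:.4g}\t{r.p_bonf:.4g}"
                for r in results
            ]
            (out / f"enrichment_{label}.tsv").write_text("\n".join(tsv) + "\n")
            enr_section[label] = {
                "group": group,
                "results": [asdict(r) for r in results],
            }
        sections["enrichment"] = enr_section
    else:
        sections["enrichment"] = {"skipped": "no gene-set (GMT) file supplied"}

    if config.expression_tsv is not None:
        sections["regression"] = _regression_section(config, out)

    report = RunReport("dmr", config.provenance(), sections)
    (out / "report.json").write_text(report.to_json())
    return report


def _regression_section(config: RunConfig, out: Path) -> dict[str, Any]:
    df = pd.read_csv(config.expression_tsv, sep="\t")
    needed = {"gene", "age_days", "methylation", "expression"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(
            f"expression table needs columns {sorted(needed)}"
        )
    rows = []
    for gene, sub in df.groupby("gene", sort=True):
        if len(sub) < 4:
            continue
        series = ExprMethSeries(
            str(gene),
            tuple(sub["age_days"].astype(float)),
            tuple(sub["methylation"].astype(float)),
            tuple(sub["expression"].astype(float)),
        )
        try:
            r = age_adjusted_regression(series)
        except UndefinedResultError:
            continue
        rows.append((r.gene, r.coefficient, r.stderr, r.pvalue, r.direction, r.nobs))
    if not rows:
        return {"skipped": "no gene had enough observations"}
    tab = pd.DataFrame(
        rows, columns=["gene", "coefficient", "stderr", "pvalue",
                       "direction", "nobs"],
    )
    tab["fdr"] = bh_fdr(tab["pvalue"].to_numpy())
    tab.to_csv(out / "regression.tsv", sep="\t", index=False)
    sig = tab[tab["fdr"] < config.fdr_alpha]
    return {
        "n_genes_tested": len(tab),
        "n_significant_fdr": int(len(sig)),
        "n_positive_significant": int((sig["direction"] == "positive").sum()),
        "table": "regression.tsv",
    }


def run_panel_analysis(config: RunConfig) -> RunReport:
    """Cluster the reference-condition panel, transfer its ordering to the
    comparison condition, and flag rows whose post-first-age methylation
    differs between conditions (t test + BH FDR)."""
    if config.panel_reference_tsv is None:
        raise ConfigurationError("panel_reference_tsv is required")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    ref = SamplePanel.from_tsv(read_text(config.panel_reference_tsv))
    n_ages = len(_ordered_unique(list(ref.ages)))

    sample_cl = hierarchical_cluster(
        ref, axis="samples",
        metric=config.clustering_metric, method=config.clustering_method,
    )
    site_cl = hierarchical_cluster(
        ref, axis="sites",
        metric=config.clustering_metric, method=config.clustering_method,
    )
    cut = sample_cl.cut(n_ages)
    # cluster/age agreement: each cluster should contain exactly one age
    cluster_ages: dict[int, set[str]] = {}
    for cid, age in zip(cut, ref.ages):
        cluster_ages.setdefault(int(cid), set()).add(age)
    pure = all(len(a) == 1 for a in cluster_ages.values())
    sections: dict[str, Any] = {
        "reference": {
            "n_sites": int(ref.values.shape[0]),
            "n_samples": int(ref.values.shape[1]),
            "sample_leaf_order": list(sample_cl.ordered_labels()),
            "site_leaf_order": list(site_cl.ordered_labels()),
            "cut_matches_ages": bool(pure),
            "clusters": {
                str(c): sorted(a) for c, a in sorted(cluster_ages.items())
            },
        }
    }

    if config.panel_comparison_tsv is None:
        sections["comparison"] = {"skipped": "single condition supplied"}
        logger.warning("no comparison panel; condition comparison skipped")
    else:
        cmp_panel = SamplePanel.from_tsv(read_text(config.panel_comparison_tsv))
        if list(cmp_panel.values.index) != list(ref.values.index):
            raise ConfigurationError("comparison panel rows differ from reference")
        first_age = ref.ages[0]
        ref_cols = [i for i, a in enumerate(ref.ages) if a != first_age]
        cmp_cols = [i for i, a in enumerate(cmp_panel.ages) if a != first_age]
        rows = []
        for site in ref.values.index:
            x = ref.values.loc[site].to_numpy()[ref_cols]
            y = cmp_panel.values.loc[site].to_numpy()[cmp_cols]
            try:
                t, p = two_sample_ttest(x, y)
            except UndefinedResultError:
                t, p = float("nan"), 1.0
            rows.append((site, float(np.mean(x) - np.mean(y)), t, p))
        tab = pd.DataFrame(
            rows, columns=["site", "mean_difference", "t", "pvalue"]
        )
        tab["fdr"] = bh_fdr(tab["pvalue"].to_numpy())
        tab["significant"] = tab["fdr"] < config.fdr_alpha
        # rows rendered in the order learned from the reference condition
        tab = tab.set_index("site").loc[list(site_cl.ordered_labels())].reset_index()
        tab.to_csv(out / "panel_comparison.tsv", sep="\t", index=False)
        sections["comparison"] = {
            "ages_compared": _ordered_unique(
                [a for a in ref.ages if a != first_age]
            ),
            "n_significant_fdr": int(tab["significant"].sum()),
            "significant_sites": tab.loc[tab["significant"], "site"].tolist(),
            "table": "panel_comparison.tsv",
        }

    report = RunReport("panel", config.provenance(), sections)
    (out / "panel_report.json").write_text(report.to_json())
    return report


def write_heatmap(
    panel: SamplePanel,
    path: str | Path,
    site_order: Sequence[str] | None = None,
    sample_order: Sequence[str] | None = None,
) -> None:
    """Render a blue-to-red percent-methylation heatmap (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = panel.values
    if site_order is not None:
        df = df.loc[list(site_order)]
    if sample_order is not None:
        df = df[list(sample_order)]
    fig, ax = plt.subplots(
        figsize=(max(4, df.shape[1] * 0.5), max(4, df.shape[0] * 0.12))
    )
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="coolwarm",
                   vmin=0, vmax=100)
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]), df.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="% methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
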