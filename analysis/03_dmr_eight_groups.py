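#!/usr/bin/env python
"""DMR discovery, eight-group classification, and gene-set enrichment.

Calls maturation DMRs (P0 -> P21 within stem cells) and differentiation
DMRs (stem -> differentiated at P21), annotates them by CGI status and
gene region, tabulates the eight {gain, loss} x {CGI, non-CGI} x
{5', gene body or 3'} groups, measures truth recovery against the planted
regions, and runs Fisher enrichment of the headline group (methylation
gain at gene body or 3' CGI) over the generated gene sets.
"""

from common import dataset_dir, ensure_results, load_profiles
from binmeth.annotation import CgiIndex, GeneIndex, load_cgis, load_gene_models
from binmeth.dmr import (
    annotate_dmrs,
    call_dmrs,
    classify_eight_groups,
    dmr_gene_lists,
    overlap_percentage,
)
from binmeth.quantify import read_text
from binmeth.stats import fisher_enrichment, read_gmt
from binmeth.synthetic import TruthSet


def main() -> None:
    root = dataset_dir()
    results = ensure_results()
    profiles = load_profiles()
    truth = TruthSet.from_json((root / "truth.json").read_text())
    cgi_index = CgiIndex(load_cgis(read_text(root / "cgi.bed")))
    gene_models = load_gene_models(read_text(root / "genes.refflat"))
    gene_index = GeneIndex(gene_models)

    contrasts = {
        "mDMR": (profiles["ISC_P0"], profiles["ISC_P21"]),
        "dDMR": (profiles["ISC_P21"], profiles["Diff_P21"]),
    }
    lists = {}
    for label, (a, b) in contrasts.items():
        dmrs = annotate_dmrs(call_dmrs(a, b, contrast=label), cgi_index, gene_index)
        table = classify_eight_groups(dmrs)
        lists[label] = dmr_gene_lists(dmrs)
        (results / f"eight_groups_{label}.tsv").write_text(table.as_tsv())
        n_cgi = sum(d.cgi.value == "CGI" for d in dmrs)
        print(f"{label}: {len(dmrs)} DMRs ({n_cgi} at CGIs), "
              f"{table.total()} gene-region assignments")
        for group, n in table.counts.items():
            print(f"    {group:32s} {n}")

    planted = truth.planted_bins("maturation")
    called = {
        (d.chrom, d.start)
        for d in call_dmrs(profiles["ISC_P0"], profiles["ISC_P21"])
    }
    recall = len(called & planted) / len(planted)
    print(f"planted maturation bins recovered: {recall:.1%} of {len(planted)}")

    m_genes = set().union(*lists["mDMR"].values())
    d_genes = set().union(*lists["dDMR"].values())
    shared, size, pct = overlap_percentage(m_genes, d_genes)
    print(f"mDMR genes overlapping dDMR genes: {shared}/{size} = {pct}%")

    gene_sets = read_gmt(read_text(root / "genesets.gmt"))
    universe = {g.name for g in gene_models}
    enr = fisher_enrichment(
        lists["mDMR"]["gain at gene body or 3' CGI"], gene_sets, universe
    )
    lines = ["term\tk\tK\tn\tN\todds_ratio\tp\tp_bonf"]
    lines += [
        f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.odds_ratio:.4g}\t"
        f"{r.p:.4g}\t{r.p_bonf:.4g}"
        for r in enr
    ]
    (results / "enrichment_gain_body3_cgi.tsv").write_text("\n".join(lines) + "\n")
    top = enr[0]
    print(f"top enriched term for 3'/body CGI gains: {top.term} "
          f"(k={top.k}/{top.K}, Bonferroni p = {top.p_bonf:.3g})")


if __name__ == "__main__":
    main()
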