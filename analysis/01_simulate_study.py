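#!/usr/bin/env python
"""Generate the synthetic WGBS study that the remaining drivers analyse.

Emulates the study design: pooled Lgr5+ stem-cell (ISC) and differentiated
epithelium samples at birth (P0) and weaning (P21), with CGI-structured
annotation, planted maturation/differentiation DMRs, a methylation-coupled
expression time course, and conventional/germ-free CpG panels.
"""

import json

from common import dataset_dir, ensure_results, study_config
from binmeth.synthetic import TruthSet


def main() -> None:
    cfg = study_config()
    root = dataset_dir()
    truth = TruthSet.from_json((root / "truth.json").read_text())
    by_kind: dict[str, int] = {}
    for d in truth.dmrs:
        key = f"{d.contrast}:{d.kind}:{d.direction}"
        by_kind[key] = by_kind.get(key, 0) + 1

    lines = ["quantity\tvalue"]
    lines.append(f"chromosomes\t{cfg.n_chroms} x {cfg.chrom_length // 10**6} Mb")
    lines.append(f"genes\t{cfg.n_genes}")
    lines.append(f"cgis\t{cfg.n_cgis}")
    lines.append(f"coverage_mean_calls_per_cpg\t{cfg.coverage_mean:g}")
    lines.append(f"beta_binomial_dispersion\t{cfg.dispersion:g}")
    lines.append(f"planted_dmr_regions\t{len(truth.dmrs)}")
    for key in sorted(by_kind):
        lines.append(f"planted:{key}\t{by_kind[key]}")
    out = ensure_results() / "study_design.tsv"
    out.write_text("\n".join(lines) + "\n")

    print(f"synthetic study written to {root}")
    print(f"planted differential regions: {len(truth.dmrs)} "
          f"({sum(d.contrast == 'maturation' for d in truth.dmrs)} maturation, "
          f"{sum(d.contrast == 'differentiation' for d in truth.dmrs)} differentiation)")
    print(f"design table -> {out}")


if __name__ == "__main__":
    main()
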