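"""Synthetic study generator: determinism, format contracts, truth
structure, and statistical moment recovery."""

import dataclasses
import json

import numpy as np
import pytest

from binmeth.annotation import (
    CgiIndex,
    CgiStatus,
    GeneIndex,
    GenomicInterval,
    RegionCategory,
    load_cgis,
    load_gene_models,
)
from binmeth.dmr import call_dmrs
from binmeth.errors import ConfigurationError
from binmeth.quantify import profile_from_coverage
from binmeth.stats import age_adjusted_regression
from binmeth.synthetic import (
    SyntheticConfig,
    TruthSet,
    generate_annotation,
    generate_counts,
    generate_dataset,
    generate_expression,
    generate_panel,
    plan_truth,
    simulate_expression_series,
)


class TestDeterminism:
    def test_annotation_byte_identical_across_runs(self, small_config):
        assert generate_annotation(small_config) == generate_annotation(small_config)

    def test_counts_byte_identical_across_runs(self, small_config):
        s1, m1 = generate_counts(small_config)
        s2, m2 = generate_counts(small_config)
        assert s1 == s2 and m1 == m2

    def test_expression_and_panel_reproducible(self, small_config):
        e1 = generate_expression(small_config)
        e2 = generate_expression(small_config)
        assert e1.equals(e2)
        p1, r1 = generate_panel(small_config, "GF")
        p2, r2 = generate_panel(small_config, "GF")
        assert p1.to_tsv() == p2.to_tsv() and r1 == r2

    def test_different_seeds_differ(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert generate_annotation(small_config) != generate_annotation(other)


class TestAnnotationContracts:
    def test_no_cgis_still_emits_genes(self, small_config):
        cfg = dataclasses.replace(
            small_config, n_cgis=0, cgi_5prime_frac=0, cgi_3prime_frac=0,
            cgi_body_frac=0,
        )
        bed, refflat = generate_annotation(cfg)
        assert bed.strip() == ""
        assert len(refflat.strip().splitlines()) == cfg.n_genes

    def test_single_gene_refflat_contract(self):
        cfg = SyntheticConfig(
            seed=2, n_chroms=1, chrom_length=100_000, n_genes=1, n_cgis=0,
            cgi_5prime_frac=0, cgi_3prime_frac=0, cgi_body_frac=0,
        )
        _, refflat = generate_annotation(cfg)
        (g,) = load_gene_models(refflat)
        assert len(g.exons) >= cfg.exon_count_range[0]
        assert g.tx_start == g.exons[0][0] and g.tx_end == g.exons[-1][1]

    def test_infeasible_packing_rejected(self):
        cfg = SyntheticConfig(seed=0, n_chroms=1, chrom_length=60_000, n_genes=50)
        with pytest.raises(ConfigurationError):
            generate_annotation(cfg)

    def test_cgis_parse_and_merge_cleanly(self, small_config):
        bed, _ = generate_annotation(small_config)
        cgis = load_cgis(bed)
        assert len(cgis) > 0
        for a, b in zip(cgis, cgis[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end < b.interval.start  # disjoint after merge


class TestTruthStructure:
    def test_truth_intervals_lie_within_annotation(self, small_config):
        truth = plan_truth(small_config)
        bed, refflat = generate_annotation(small_config)
        cgi_index = CgiIndex(load_cgis(bed))
        genes = {g.name for g in load_gene_models(refflat)}
        for d in truth.dmrs:
            iv = GenomicInterval(d.chrom, d.start, d.end)
            status = cgi_index.status(iv)
            if d.kind in ("5cgi", "3cgi", "bodycgi"):
                assert status is CgiStatus.CGI
            else:
                # shores/intronic windows must not touch any island
                assert status is CgiStatus.NON_CGI
            assert d.gene in genes

    def test_cgi_plants_classify_to_their_intended_region(self, small_config):
        truth = plan_truth(small_config)
        _, refflat = generate_annotation(small_config)
        index = GeneIndex(load_gene_models(refflat))
        intended = {
            "5cgi": RegionCategory.FIVE_PRIME,
            "3cgi": RegionCategory.THREE_PRIME,
            "bodycgi": RegionCategory.GENE_BODY,
        }
        for d in truth.dmrs:
            if d.kind not in intended:
                continue
            got = index.classify(GenomicInterval(d.chrom, d.start, d.end))
            assert (d.gene, intended[d.kind]) in got

    def test_truth_json_round_trip(self, small_config):
        truth = plan_truth(small_config)
        back = TruthSet.from_json(truth.to_json())
        assert back.dmrs == truth.dmrs
        assert back.coupled_genes == truth.coupled_genes

    def test_planted_bins_subset_of_disturbed(self, small_config):
        truth = plan_truth(small_config)
        mat = truth.planted_bins("maturation")
        diff = truth.planted_bins("differentiation")
        assert mat and diff
        assert (mat | diff) <= truth.disturbed_bins()


class TestCountsMomentRecovery:
    def test_high_coverage_zero_dispersion_tracks_truth(self, small_config):
        cfg = dataclasses.replace(
            small_config, coverage_mean=10_000.0, dispersion=0.0,
            n_chroms=1, chrom_length=200_000, n_genes=10, n_cgis=14,
            n_mat_3cgi_gain=2, n_mat_bodycgi_gain=1, n_mat_5cgi_gain=1,
            n_mat_3cgi_loss=0, n_mat_bodycgi_loss=0, n_mat_5cgi_loss=0,
            n_mat_shore5_loss=1, n_mat_shore3_loss=1, n_mat_noncgi_gain=1,
            n_diff_3cgi_gain=0, n_diff_shore_loss=0,
        )
        truth = plan_truth(cfg)
        samples, _ = generate_counts(cfg, truth=truth)
        p0 = profile_from_coverage(samples["ISC_P0"], "ISC_P0")
        p21 = profile_from_coverage(samples["ISC_P21"], "ISC_P21")
        for key in truth.planted_bins("maturation"):
            d = next(
                t for t in truth.dmrs
                if t.chrom == key[0] and t.start <= key[1] < t.end
            )
            base = d.base_override
            if base is None:
                base = (
                    cfg.baseline_cgi if d.kind.endswith("cgi")
                    else cfg.baseline_noncgi
                )
            assert p0.bins[key].level == pytest.approx(base, abs=1.0)
            assert p21.bins[key].level == pytest.approx(base + d.delta, abs=1.0)

    def test_planted_3cgi_gain_called_as_mdmr_gain(self, small_config):
        samples, _ = generate_counts(small_config)
        truth = plan_truth(small_config)
        p0 = profile_from_coverage(samples["ISC_P0"], "ISC_P0")
        p21 = profile_from_coverage(samples["ISC_P21"], "ISC_P21")
        called = {d.key: d for d in call_dmrs(p0, p21, contrast="mDMR")}
        gain3_bins = [
            key
            for key in truth.planted_bins("maturation")
            for t in truth.dmrs
            if t.kind == "3cgi" and t.contrast == "maturation"
            and t.direction == "gain"
            and t.chrom == key[0] and t.start <= key[1] < t.end
        ]
        assert gain3_bins
        hit = [k for k in gain3_bins if k in called]
        assert len(hit) >= 0.9 * len(gain3_bins)
        assert all(called[k].direction == "gain" for k in hit)

    def test_differentiation_plants_absent_from_isc_contrast(self, small_config):
        """Maturation plants shift both cell types, so the cell-type
        contrast at one age sees only differentiation plants."""
        truth = plan_truth(small_config)
        samples, _ = generate_counts(small_config, truth=truth)
        isc = profile_from_coverage(samples["ISC_P21"], "ISC_P21")
        diff = profile_from_coverage(samples["Diff_P21"], "Diff_P21")
        called = {d.key for d in call_dmrs(isc, diff, contrast="dDMR")}
        diff_bins = truth.planted_bins("differentiation")
        assert len(called & diff_bins) >= 0.9 * len(diff_bins)
        # maturation-planted CGI bins cancel in this contrast
        mat_cgi_bins = {
            key
            for key in truth.planted_bins("maturation")
            for t in truth.dmrs
            if t.kind.endswith("cgi") and t.chrom == key[0]
            and t.start <= key[1] < t.end
        }
        assert len(called & mat_cgi_bins) <= 0.05 * len(mat_cgi_bins)


class TestExpression:
    def test_zero_noise_recovers_coupling_exactly(self, small_config):
        cfg = dataclasses.replace(
            small_config, expression_noise_sd=0.0, expression_coupling=0.04
        )
        series = simulate_expression_series(0.04, seed=[cfg.seed, 99], config=cfg)
        r = age_adjusted_regression(series)
        assert r.coefficient == pytest.approx(0.04, abs=1e-9)

    def test_negative_coupling_recovers_negative_sign(self, small_config):
        series = simulate_expression_series(-0.05, seed=[3, 4], config=small_config)
        r = age_adjusted_regression(series)
        assert r.direction == "negative" and r.coefficient < 0

    def test_null_coupling_is_controlled(self, small_config):
        hits = 0
        for s in range(60):
            series = simulate_expression_series(0.0, seed=[s, 1], config=small_config)
            r = age_adjusted_regression(series)
            hits += abs(r.coefficient) > 3 * r.stderr
        assert hits <= 4  # ~0.3% expected rate; allow slack

    def test_table_contains_coupled_and_uncoupled_genes(self, small_config):
        truth = plan_truth(small_config)
        df = generate_expression(small_config, truth)
        assert set(df.loc[df["coupled"], "gene"]) == set(truth.coupled_genes)
        assert set(df.loc[~df["coupled"], "gene"]) == set(truth.uncoupled_genes)
        per_gene = df.groupby("gene").size()
        expected = len(small_config.expression_ages) * small_config.expression_replicates
        assert (per_gene == expected).all()


class TestPanels:
    def test_blocked_rows_stall_only_under_gf(self, small_config):
        cnv, roles = generate_panel(small_config, "CNV")
        gf, roles_gf = generate_panel(small_config, "GF")
        assert roles == roles_gf
        blocked = [r for r, v in roles.items() if v == "gf_blocked"]
        assert blocked
        last_age = small_config.panel_ages[-1]
        cnv_last = [i for i, a in enumerate(cnv.ages) if a == last_age]
        for row in blocked:
            cnv_mean = cnv.values.loc[row].to_numpy()[cnv_last].mean()
            gf_mean = gf.values.loc[row].to_numpy()[cnv_last].mean()
            assert cnv_mean - gf_mean > 15  # the planted deficit

    def test_repeat_rows_identical_means_across_conditions(self, small_config):
        cnv, roles = generate_panel(small_config, "CNV")
        gf, _ = generate_panel(small_config, "GF")
        reps = [r for r, v in roles.items() if v == "repeat"]
        assert set(reps) == {"Line1", "IAP"}
        for row in reps:
            assert abs(
                cnv.values.loc[row].mean() - gf.values.loc[row].mean()
            ) < 3.0  # same mean, noise only

    def test_panel_shape_and_labels(self, small_config):
        panel, roles = generate_panel(small_config, "CNV")
        n_sites = (
            small_config.panel_sites_per_gene
            * (small_config.panel_gain_genes + small_config.panel_loss_genes
               + small_config.panel_stable_genes)
            + 2
        )
        n_samples = len(small_config.panel_ages) * small_config.panel_samples_per_age
        assert panel.values.shape == (n_sites, n_samples)
        assert set(panel.conditions) == {"CNV"}


def test_generate_dataset_writes_consistent_files(tmp_path, small_config):
    paths = generate_dataset(small_config, tmp_path)
    for key in ("cgi_bed", "refflat", "samples", "gmt", "expression",
                "truth", "config", "panel:CNV", "panel:GF"):
        assert paths[key].exists(), key
    truth = TruthSet.from_json(paths["truth"].read_text())
    assert truth.dmrs == plan_truth(small_config).dmrs
    sheet = paths["samples"].read_text().splitlines()
    assert len(sheet) == 1 + len(small_config.ages) * len(small_config.cell_types)
    roles = json.loads(paths["panel_roles"].read_text())
    assert "Line1" in roles and "IAP" in roles
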