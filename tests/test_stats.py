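"""Proportion test, Fisher enrichment, t tests, regression, BH FDR,
and panel clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from binmeth.errors import UndefinedResultError, ValidationError
from binmeth.stats import (
    ExprMethSeries,
    SamplePanel,
    age_adjusted_regression,
    bh_fdr,
    fisher_enrichment,
    global_proportion_test,
    hierarchical_cluster,
    read_gmt,
    two_sample_ttest,
    write_gmt,
)

from conftest import fisher_two_sided_oracle, make_profile


def direction_profiles(n_higher_a: int, n_total: int, n_ties: int = 0):
    """Profiles where exactly n_higher_a of n_total informative bins are
    higher in a."""
    levels_a, levels_b = {}, {}
    for i in range(n_total):
        key = ("chr1", 200 * i)
        if i < n_higher_a:
            levels_a[key], levels_b[key] = 60.0, 40.0
        else:
            levels_a[key], levels_b[key] = 40.0, 60.0
    for j in range(n_ties):
        key = ("chr1", 200 * (n_total + j))
        levels_a[key] = levels_b[key] = 50.0
    return make_profile(levels_a, "a"), make_profile(levels_b, "b")


class TestGlobalProportionTest:
    def test_null_split_gives_p_near_one(self):
        a, b = direction_profiles(50, 100)
        r = global_proportion_test(a, b)
        assert r.pvalue > 0.9 and r.statistic == pytest.approx(0.5)

    def test_80_of_100_matches_exact_binomial_tail(self):
        a, b = direction_profiles(80, 100)
        r = global_proportion_test(a, b)
        tail = sum(math.comb(100, k) for k in range(80, 101)) / 2 ** 100
        assert r.pvalue == pytest.approx(2 * tail, rel=1e-9)
        assert r.pvalue < 1e-8

    def test_all_ties_is_undefined(self):
        a, b = direction_profiles(0, 0, n_ties=30)
        with pytest.raises(UndefinedResultError):
            global_proportion_test(a, b)

    def test_swap_symmetry(self):
        a, b = direction_profiles(70, 100, n_ties=5)
        fwd = global_proportion_test(a, b)
        rev = global_proportion_test(b, a)
        assert fwd.statistic == pytest.approx(1 - rev.statistic)
        assert fwd.pvalue == pytest.approx(rev.pvalue)

    def test_large_n_uses_continuity_corrected_normal(self):
        a, b = direction_profiles(350, 600)
        r = global_proportion_test(a, b)
        z = (abs(350 - 300) - 0.5) / (math.sqrt(600) / 2)
        from scipy.stats import norm

        assert r.pvalue == pytest.approx(2 * norm.sf(z))

    def test_pooled_z_variant_detects_pooled_shift(self):
        a, b = direction_profiles(100, 100)
        r = global_proportion_test(a, b, method="pooled_z")
        assert r.method == "pooled_z" and r.pvalue < 1e-6


class TestFisherEnrichment:
    def run_one(self, k, K, n, N):
        universe = {f"g{i}" for i in range(N)}
        term = {f"g{i}" for i in range(K)}
        dmr = {f"g{i}" for i in range(k)} | {f"g{K + i}" for i in range(n - k)}
        (res,) = fisher_enrichment(dmr, {"T": term}, universe)
        assert (res.k, res.K, res.n, res.N) == (k, K, n, N)
        return res

    def test_complete_overlap_matches_enumeration(self):
        res = self.run_one(10, 10, 20, 100)
        assert res.p == pytest.approx(fisher_two_sided_oracle(10, 10, 20, 100), rel=1e-9)

    def test_overlap_at_expectation_gives_p_one(self):
        res = self.run_one(2, 10, 20, 100)
        assert res.p == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_terms_tested(self):
        universe = {f"g{i}" for i in range(40)}
        sets = {f"T{j}": {f"g{i}" for i in range(j, j + 8)} for j in range(5)}
        results = fisher_enrichment({f"g{i}" for i in range(8)}, sets, universe)
        assert len(results) == 5
        for r in results:
            assert r.p_bonf == pytest.approx(min(1.0, r.p * 5))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            fisher_enrichment({"a"}, {"T": {"a"}}, set())

    def test_genes_outside_universe_ignored(self):
        universe = {"a", "b", "c", "d"}
        (res,) = fisher_enrichment(
            {"a", "zz"}, {"T": {"a", "b", "yy"}}, universe
        )
        assert (res.k, res.K, res.n, res.N) == (1, 2, 1, 4)

    def test_matches_enumeration_on_margin_grid(self):
        for N in (5, 12, 30):
            for K in (1, N // 3, N // 2):
                for n in (1, N // 3, N // 2):
                    if K < 1 or n < 1:
                        continue
                    for k in range(max(0, n - (N - K)), min(K, n) + 1):
                        res = self.run_one(k, K, n, N)
                        want = fisher_two_sided_oracle(k, K, n, N)
                        assert res.p == pytest.approx(want, rel=1e-8), (k, K, n, N)


def test_gmt_round_trip():
    sets = {"A": {"g1", "g2"}, "B": {"g3"}}
    assert read_gmt(write_gmt(sets)) == sets


class TestTTest:
    def test_identical_samples(self):
        assert two_sample_ttest([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_separated_groups_match_closed_form(self):
        t, p = two_sample_ttest([1, 2, 3], [101, 102, 103])
        # pooled sd = 1, se = sqrt(2/3), t = -100/se with 4 df
        assert t == pytest.approx(-100 / math.sqrt(2 / 3))
        assert p < 1e-4

    def test_singleton_group_undefined(self):
        with pytest.raises(UndefinedResultError):
            two_sample_ttest([1.0], [1, 2, 3])

    def test_zero_variance_different_means_undefined(self):
        with pytest.raises(UndefinedResultError):
            two_sample_ttest([5, 5, 5], [7, 7, 7])

    def test_welch_flag_changes_p_under_unequal_variances(self):
        x, y = [1, 2, 3, 4], [10, 30, 50, 70]
        t_pooled, p_pooled = two_sample_ttest(x, y)
        t_welch, p_welch = two_sample_ttest(x, y, equal_var=False)
        assert p_welch != p_pooled  # fewer effective df under Welch
        assert np.sign(t_welch) == np.sign(t_pooled)


def ols_oracle(X, y):
    """Normal-equation OLS, independent of statsmodels."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta


class TestAgeAdjustedRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        meth = rng.uniform(10, 60, 12)
        age = rng.permutation(np.repeat([0.0, 21.0, 100.0, 300.0], 3))
        series = ExprMethSeries("g", tuple(age), tuple(meth), tuple(0.02 * meth))
        r = age_adjusted_regression(series)
        assert r.coefficient == pytest.approx(0.02, abs=1e-10)
        assert r.pvalue < 1e-10 and r.direction == "positive"

    def test_age_only_signal_gives_null_meth_coefficient(self):
        rng = np.random.default_rng(1)
        age = np.repeat([0.0, 21.0, 100.0, 300.0], 3)
        meth = rng.uniform(10, 60, 12)
        expr = 0.01 * age + rng.normal(0, 0.05, 12)
        series = ExprMethSeries("g", tuple(age), tuple(meth), tuple(expr))
        r = age_adjusted_regression(series)
        X = np.column_stack([np.ones(12), meth, age])
        beta = ols_oracle(X, expr)
        assert r.coefficient == pytest.approx(beta[1], rel=1e-8)
        assert abs(r.coefficient) < 3 * r.stderr

    def test_too_few_observations(self):
        s = ExprMethSeries("g", (0, 1, 2), (1, 2, 3), (1, 2, 3))
        with pytest.raises(UndefinedResultError):
            age_adjusted_regression(s)

    def test_collinear_methylation_and_age_rejected(self):
        age = (0.0, 21.0, 100.0, 300.0, 0.0, 21.0, 100.0, 300.0)
        s = ExprMethSeries("g", age, age, tuple(np.arange(8.0)))
        with pytest.raises(UndefinedResultError):
            age_adjusted_regression(s)

    def test_negative_ages_rejected(self):
        with pytest.raises(ValidationError):
            ExprMethSeries("g", (-1.0, 0, 1, 2), (1, 2, 3, 4), (1, 2, 3, 4))


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_input_order_preserved(self):
        p = [0.5, 0.001, 0.04]
        adj = bh_fdr(p)
        assert np.argmin(adj) == 1 and np.argmax(adj) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @staticmethod
    def step_up_oracle(p):
        """Hand-rolled BH: sort, scale by n/rank, enforce monotone minima
        from the largest rank down, cap at 1."""
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p, kind="stable")
        scaled = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj, 1.0)
        return out

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_step_up_oracle_and_is_monotone(self, p):
        adj = bh_fdr(p)
        assert adj == pytest.approx(self.step_up_oracle(p), abs=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)


def block_panel(seed=0, n_rows=20, ages=("P0", "P21"), reps=3, gap=40.0):
    rng = np.random.default_rng(seed)
    cols, data, age_labels = [], [], []
    for ai, age in enumerate(ages):
        for r in range(reps):
            cols.append(f"{age}_r{r + 1}")
            age_labels.append(age)
            data.append(
                np.clip(20.0 + ai * gap + rng.normal(0, 1.0, n_rows), 0, 100)
            )
    df = pd.DataFrame(
        np.column_stack(data), index=[f"s{i}" for i in range(n_rows)], columns=cols
    )
    return SamplePanel(df, tuple(age_labels), tuple(["CNV"] * len(cols)))


class TestHierarchicalClustering:
    def test_identical_pair_merges_first(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [50.0, 60.0], "c": [50.0, 60.0]},
            index=["r1", "r2"],
        )
        result = hierarchical_cluster(df, axis="samples")
        first = set(result.linkage[0, :2].astype(int))
        assert first == {1, 2}  # b and c are identical vectors

    def test_two_block_structure_recovered_at_two_cut(self):
        panel = block_panel()
        result = hierarchical_cluster(panel, axis="samples")
        cut = result.cut(2)
        by_age = {}
        for cid, age in zip(cut, panel.ages):
            by_age.setdefault(age, set()).add(cid)
        assert all(len(v) == 1 for v in by_age.values())
        assert by_age["P0"] != by_age["P21"]

    def test_first_merge_is_globally_closest_pair(self):
        # exhaustive check over all pairings of a 4-item instance
        panel = block_panel(seed=3, reps=2)
        mat = panel.values.to_numpy().T
        result = hierarchical_cluster(panel, axis="samples")
        dists = {
            (i, j): float(np.linalg.norm(mat[i] - mat[j]))
            for i in range(4)
            for j in range(i + 1, 4)
        }
        best = min(dists, key=dists.get)
        assert set(result.linkage[0, :2].astype(int)) == set(best)

    def test_two_samples_single_merge_input_order(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["r1", "r2"])
        result = hierarchical_cluster(df, axis="samples")
        assert result.linkage.shape[0] == 1
        assert result.ordered_labels() == ("a", "b")

    def test_constant_matrix_clusters_without_error(self):
        df = pd.DataFrame(np.full((5, 4), 42.0),
                          index=[f"r{i}" for i in range(5)],
                          columns=list("abcd"))
        result = hierarchical_cluster(df, axis="samples")
        assert len(result.leaf_order) == 4

    def test_partition_invariant_to_column_permutation(self):
        panel = block_panel(seed=9)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = SamplePanel(
            panel.values.iloc[:, perm],
            tuple(panel.ages[i] for i in perm),
            tuple(panel.conditions[i] for i in perm),
        )
        base_cut = hierarchical_cluster(panel, axis="samples").cut(2)
        perm_cut = hierarchical_cluster(permuted, axis="samples").cut(2)
        base_parts = {
            frozenset(np.asarray(panel.values.columns)[base_cut == c])
            for c in set(base_cut)
        }
        perm_parts = {
            frozenset(np.asarray(permuted.values.columns)[perm_cut == c])
            for c in set(perm_cut)
        }
        assert base_parts == perm_parts

    def test_site_axis_clusters_rows(self):
        panel = block_panel()
        result = hierarchical_cluster(panel, axis="sites")
        assert len(result.leaf_order) == panel.values.shape[0]

    def test_zscore_rows_option(self):
        panel = block_panel()
        result = hierarchical_cluster(panel, axis="samples", zscore_rows=True)
        assert len(result.leaf_order) == panel.values.shape[1]


class TestSamplePanel:
    def test_tsv_round_trip(self):
        panel = block_panel()
        back = SamplePanel.from_tsv(panel.to_tsv())
        assert back.ages == panel.ages and back.conditions == panel.conditions
        assert np.allclose(back.values.to_numpy(), panel.values.round(2).to_numpy())

    def test_out_of_range_values_rejected(self):
        df = pd.DataFrame({"a": [150.0]}, index=["r"])
        with pytest.raises(ValidationError):
            SamplePanel(df, ("P0",), ("CNV",))

    def test_label_length_mismatch_rejected(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["r"])
        with pytest.raises(ValidationError):
            SamplePanel(df, ("P0",), ("CNV", "CNV"))
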