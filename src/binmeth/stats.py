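"""Statistical layer: bin-unit proportion test, Fisher gene-set enrichment
with Bonferroni, two-tailed t tests, age-adjusted methylation-expression
regression with Benjamini-Hochberg FDR, and hierarchical clustering of
CpG-site methylation panels.

Conventions worth stating because they differ between toolchains:

* The two-sided Fisher p-value uses the minimum-likelihood rule (sum of
  hypergeometric probabilities not exceeding the observed table's), the
  convention implemented by :func:`scipy.stats.fisher_exact`.
* The "test for proportions with the bin as the unit of observation" is
  implemented as a sign test on per-bin direction indicators (ties
  dropped): each mutually passing bin contributes one Bernoulli
  observation, success meaning profile a is higher.  A pooled two-proportion
  z test over summed calls is available as an alternative (``method=
  "pooled_z"``) since the phrase fixes the unit, not the statistic.
* t tests default to classic pooled-variance Student; Welch by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import UndefinedResultError, ValidationError
from .quantify import MethylationProfile


# ---------------------------------------------------------------------------
# global proportion test


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float          # proportion of informative bins higher in a
    pvalue: float
    n_informative: int
    n_ties: int
    method: str

    @property
    def direction(self) -> str:
        if self.statistic > 0.5:
            return "a higher"
        if self.statistic < 0.5:
            return "b higher"
        return "no direction"


def global_proportion_test(
    profile_a: MethylationProfile,
    profile_b: MethylationProfile,
    method: str = "sign",
    exact_max_n: int = 500,
) -> ProportionTestResult:
    """Test whether one profile is globally more methylated, with the bin
    as the unit of observation.

    ``sign`` (default): two-sided binomial test of p=0.5 on the number of
    mutually passing bins where level_a > level_b (ties dropped); exact for
    n <= ``exact_max_n``, else normal approximation with continuity
    correction.  ``pooled_z``: two-proportion z test on calls pooled over
    the mutually passing bins.
    """
    common = [
        k
        for k in set(profile_a.bins) & set(profile_b.bins)
        if profile_a.bins[k].passes_filter and profile_b.bins[k].passes_filter
    ]
    if method == "pooled_z":
        if len(common) < 2:
            raise UndefinedResultError("fewer than 2 mutually passing bins")
        ma = sum(profile_a.bins[k].meth_calls for k in common)
        ta = sum(profile_a.bins[k].total_calls for k in common)
        mb = sum(profile_b.bins[k].meth_calls for k in common)
        tb = sum(profile_b.bins[k].total_calls for k in common)
        pa, pb = ma / ta, mb / tb
        pool = (ma + mb) / (ta + tb)
        se = math.sqrt(pool * (1 - pool) * (1 / ta + 1 / tb))
        if se == 0:
            raise UndefinedResultError("degenerate pooled proportions")
        z = (pa - pb) / se
        p = 2 * sps.norm.sf(abs(z))
        frac = float(np.mean([
            profile_a.bins[k].level > profile_b.bins[k].level for k in common
        ]))
        return ProportionTestResult(frac, float(p), len(common), 0, "pooled_z")
    if method != "sign":
        raise ValidationError(f"unknown method {method!r}")

    higher = lower = ties = 0
    for k in common:
        da = profile_a.bins[k].level - profile_b.bins[k].level
        if da > 0:
            higher += 1
        elif da < 0:
            lower += 1
        else:
            ties += 1
    n = higher + lower
    if n < 2:
        raise UndefinedResultError("fewer than 2 informative bins")
    if n <= exact_max_n:
        p = sps.binomtest(higher, n, 0.5, alternative="two-sided").pvalue
    else:
        # normal approximation with continuity correction
        mu, sd = n / 2.0, math.sqrt(n) / 2.0
        z = (abs(higher - mu) - 0.5) / sd
        p = min(1.0, 2 * sps.norm.sf(max(z, 0.0)))
    return ProportionTestResult(higher / n, float(p), n, ties, "sign")


# ---------------------------------------------------------------------------
# Fisher gene-set enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int            # DMR genes in the term
    K: int            # term size within the universe
    n: int            # DMR genes in the universe
    N: int            # universe size
    odds_ratio: float
    p: float
    p_bonf: float


def fisher_enrichment(
    dmr_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact enrichment of a DMR gene list against each
    supplied term, Bonferroni-adjusted over the terms actually tested.

    Gene sets and the DMR list are restricted to the universe before
    testing; terms empty after restriction are not tested.  Results are
    sorted by raw p (term id breaking ties).
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty gene universe")
    dmr = set(dmr_genes) & uni
    restricted = {
        term: set(members) & uni for term, members in gene_sets.items()
    }
    tested = {term: members for term, members in restricted.items() if members}
    results = []
    N, n = len(uni), len(dmr)
    for term, members in tested.items():
        K = len(members)
        k = len(members & dmr)
        table = [[k, n - k], [K - k, N - K - (n - k)]]
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentResult(
                term=term,
                k=k,
                K=K,
                n=n,
                N=N,
                odds_ratio=float(odds),
                p=float(p),
                p_bonf=min(1.0, float(p) * len(tested)),
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results


def read_gmt(text: str | Iterable[str]) -> dict[str, set[str]]:
    """Parse GMT lines (term, description, genes...) into term -> gene set."""
    if isinstance(text, str):
        text = text.splitlines()
    sets: dict[str, set[str]] = {}
    for raw in text:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line needs >=3 fields: {line[:60]!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]]) -> str:
    lines = [
        f"{term}\tna\t" + "\t".join(sorted(set(members)))
        for term, members in sorted(gene_sets.items())
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# t test


def two_sample_ttest(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-tailed two-sample t test (pooled-variance Student by default;
    ``equal_var=False`` for Welch).  Returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise UndefinedResultError("each group needs >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise UndefinedResultError("zero variance in both groups")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# age-adjusted regression


@dataclass(frozen=True)
class ExprMethSeries:
    """Paired methylation/expression observations for one gene over age.

    Expression is on whatever relative scale the input table uses (e.g.
    relative to a reference housekeeping gene); ages are in days and must
    be non-negative.
    """

    gene: str
    age: tuple[float, ...]
    methylation: tuple[float, ...]
    expression: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.age)
        if len(self.methylation) != n or len(self.expression) != n:
            raise ValidationError("age/methylation/expression lengths differ")
        if any(a < 0 for a in self.age):
            raise ValidationError("ages must be non-negative")


@dataclass(frozen=True)
class RegressionResult:
    gene: str
    coefficient: float      # expression change per methylation point, age-adjusted
    stderr: float
    pvalue: float
    direction: str          # "positive" | "negative"
    nobs: int


def age_adjusted_regression(
    series: ExprMethSeries,
    log_age: bool = False,
    max_condition: float = 1e8,
) -> RegressionResult:
    """OLS of expression on methylation adjusting for age.

    Returns the methylation partial coefficient, its two-sided p-value and
    sign.  Age enters in days (``log_age`` switches to log1p(days)).
    Requires >= 4 observations and a well-conditioned design (methylation
    not collinear with age).
    """
    import statsmodels.api as sm

    n = len(series.age)
    if n < 4:
        raise UndefinedResultError("need >= 4 observations for regression")
    age = np.log1p(series.age) if log_age else np.asarray(series.age, float)
    X = np.column_stack(
        [np.ones(n), np.asarray(series.methylation, float), age]
    )
    # scale columns before conditioning check so units don't dominate
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    if np.linalg.cond(X / scale) > max_condition:
        raise UndefinedResultError(
            f"degenerate design for {series.gene}: methylation collinear with age"
        )
    fit = sm.OLS(np.asarray(series.expression, float), X).fit()
    coef, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    return RegressionResult(
        gene=series.gene,
        coefficient=float(coef),
        stderr=float(se),
        pvalue=float(p),
        direction="positive" if coef >= 0 else "negative",
        nobs=n,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sample panels and hierarchical clustering


@dataclass
class SamplePanel:
    """CpG-site x sample percent-methylation matrix with sample labels.

    ``values`` is rectangular with no missing entries; rows are CpG-site
    labels (gene + site index), columns are sample names.  ``ages`` and
    ``conditions`` run parallel to the columns.
    """

    values: pd.DataFrame
    ages: tuple[str, ...]
    conditions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("panel contains missing values")
        ncol = self.values.shape[1]
        if len(self.ages) != ncol or len(self.conditions) != ncol:
            raise ValidationError("ages/conditions must match column count")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValidationError("panel values must be percent in [0, 100]")

    def to_tsv(self) -> str:
        header1 = "site\t" + "\t".join(map(str, self.values.columns))
        header2 = "label\t" + "\t".join(
            f"{a}|{c}" for a, c in zip(self.ages, self.conditions)
        )
        body = [
            str(idx) + "\t" + "\t".join(f"{v:.2f}" for v in row)
            for idx, row in zip(self.values.index, self.values.to_numpy())
        ]
        return "\n".join([header1, header2, *body]) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "SamplePanel":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) < 3:
            raise ValidationError("panel TSV needs two header rows and data")
        cols = lines[0].split("\t")[1:]
        labels = lines[1].split("\t")[1:]
        ages, conditions = [], []
        for lab in labels:
            a, _, c = lab.partition("|")
            ages.append(a)
            conditions.append(c)
        idx, rows = [], []
        for ln in lines[2:]:
            fields = ln.split("\t")
            idx.append(fields[0])
            rows.append([float(x) for x in fields[1:]])
        values = pd.DataFrame(rows, index=idx, columns=cols)
        return cls(values, tuple(ages), tuple(conditions))


@dataclass(frozen=True)
class ClusteringResult:
    linkage: np.ndarray
    leaf_order: tuple[int, ...]
    labels: tuple[str, ...]          # labels in original order
    axis: str
    metric: str
    method: str

    def ordered_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.leaf_order)

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster ids (1..k) in original item order."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")


def hierarchical_cluster(
    panel: SamplePanel | pd.DataFrame,
    axis: str = "samples",
    metric: str = "euclidean",
    method: str = "average",
    zscore_rows: bool = False,
) -> ClusteringResult:
    """Agglomerative clustering of a methylation panel.

    Defaults: Euclidean distance, average linkage, raw percent values
    (``zscore_rows`` standardises each CpG row first).  Leaf order is
    deterministic: ties in the distance matrix are broken by original item
    index (scipy's stable pairwise ordering).
    """
    df = panel.values if isinstance(panel, SamplePanel) else panel
    if zscore_rows:
        vals = df.to_numpy(dtype=float)
        sd = vals.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        df = pd.DataFrame(
            (vals - vals.mean(axis=1, keepdims=True)) / sd,
            index=df.index,
            columns=df.columns,
        )
    if axis == "samples":
        mat = df.to_numpy(dtype=float).T
        labels = tuple(map(str, df.columns))
    elif axis == "sites":
        mat = df.to_numpy(dtype=float)
        labels = tuple(map(str, df.index))
    else:
        raise ValidationError("axis must be 'samples' or 'sites'")
    if mat.shape[0] < 2:
        raise ValidationError("need >= 2 items on the clustered axis")
    dist = pdist(mat, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    order = tuple(int(i) for i in hierarchy.leaves_list(Z))
    return ClusteringResult(Z, order, labels, axis, metric, method)
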