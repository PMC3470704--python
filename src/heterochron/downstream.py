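"""Post-heterochrony analyses.

Effect sizes for a case/control contrast (Cohen's d), the "corrected"
disease effect (residual of d after regressing out the expression-age
correlation across genes), rank-sum comparison of corrected effects
between gene groups, residual-variance F-tests, hypergeometric gene-set
overlap with odds ratios, hierarchical gene clustering of trajectories or
shift profiles, and bootstrap co-assignment clustering of samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .dataset import ExpressionDataset
from .preprocess import standardize_genes
from .trajectory import PolyFitResult

__all__ = [
    "cohens_d",
    "age_expression_correlations",
    "corrected_effect_sizes",
    "group_effect_comparison",
    "variance_f_test",
    "VarianceTestResult",
    "hypergeometric_overlap",
    "OverlapResult",
    "cluster_genes",
    "bootstrap_cluster_samples",
    "BootstrapClusterResult",
]


def cohens_d(case_values, control_values) -> float:
    """Cohen's d: (mean_case - mean_control) / pooled SD.

    Pooled SD uses the (n1-1, n2-1)-weighted variances. Zero pooled SD
    leaves d undefined (NaN, with a warning).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per arm")
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0.0:
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(s2))


def age_expression_correlations(ds: ExpressionDataset) -> pd.Series:
    """Pearson r of expression vs age, per gene."""
    arr = ds.values.to_numpy(dtype=float)
    ages = ds.ages.to_numpy(dtype=float)
    ac = ages - ages.mean()
    xc = arr - arr.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1)) * np.sqrt((ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ ac) / denom
    return pd.Series(r, index=ds.gene_ids, name="age_corr")


def corrected_effect_sizes(d, age_corr) -> np.ndarray:
    """Residuals of d on age_corr across genes (OLS with intercept).

    The residual 'corrected effect' isolates the case/control effect from
    the shared aging signal; by construction it has mean ~0 and zero
    sample correlation with age_corr. A constant age_corr degenerates to
    d - mean(d) (with a warning).
    """
    d = np.asarray(d, dtype=float)
    ac = np.asarray(age_corr, dtype=float)
    if len(d) != len(ac):
        raise ValueError("d and age_corr must have equal length")
    if len(d) < 10:
        raise ValueError("need at least 10 genes")
    if not (np.isfinite(d).all() and np.isfinite(ac).all()):
        raise ValueError("non-finite effect sizes or correlations")
    if np.ptp(ac) <= 1e-12:
        warnings.warn("constant age_corr: returning centered d", stacklevel=2)
        return d - d.mean()
    X = np.column_stack([np.ones_like(ac), ac])
    beta, *_ = np.linalg.lstsq(X, d, rcond=None)
    return d - X @ beta


def group_effect_comparison(residuals, gene_groups):
    """Two-sided Wilcoxon rank-sum test of corrected effects between two
    gene groups.

    Parameters
    ----------
    residuals : mapping or Series of corrected effect per gene.
    gene_groups : dict with two keys (e.g. ``up-in-A``/``down-in-A``)
        mapping to gene lists.

    Returns ``(statistic, p)``. When every value ties the test is
    undefined; p = 1 is returned.
    """
    residuals = pd.Series(residuals)
    keys = list(gene_groups)
    if len(keys) != 2:
        raise ValueError("gene_groups must contain exactly two groups")
    x = residuals.loc[list(gene_groups[keys[0]])].to_numpy(dtype=float)
    y = residuals.loc[list(gene_groups[keys[1]])].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both gene groups must be nonempty")
    if np.ptp(np.concatenate([x, y])) <= 0.0:
        return 0.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class VarianceTestResult:
    F: float
    p_a_greater: float
    p_b_greater: float
    df_a: int
    df_b: int


def variance_f_test(values_a, values_b, ages_a=None, ages_b=None,
                    fit_a: PolyFitResult | None = None,
                    fit_b: PolyFitResult | None = None) -> VarianceTestResult:
    """F-test of within-group dispersion, A vs B.

    Variances are computed on residuals around each group's own fitted age
    curve when fits (and ages) are supplied -- raw group variance would
    conflate trajectory divergence with dispersion -- otherwise around the
    group mean. F = s²_A / s²_B with (nA - dA - 1, nB - dB - 1) df; both
    one-sided p-values are reported.
    """
    ya = np.asarray(values_a, dtype=float)
    yb = np.asarray(values_b, dtype=float)
    if len(ya) < 3 or len(yb) < 3:
        raise ValueError("need at least 3 samples per group")

    def _rss_df(y, ages, fit):
        if fit is not None:
            if ages is None:
                raise ValueError("ages required when a fit is supplied")
            resid = y - fit.predict(np.asarray(ages, dtype=float))
            df = len(y) - fit.degree - 1
        else:
            resid = y - y.mean()
            df = len(y) - 1
        if df < 1:
            raise ValueError("non-positive residual degrees of freedom")
        return float((resid ** 2).sum()), df

    rss_a, df_a = _rss_df(ya, ages_a, fit_a)
    rss_b, df_b = _rss_df(yb, ages_b, fit_b)
    if rss_b <= 0.0 or rss_a <= 0.0:
        raise ValueError("zero residual variance: F undefined")
    F = (rss_a / df_a) / (rss_b / df_b)
    return VarianceTestResult(
        F=float(F),
        p_a_greater=float(stats.f.sf(F, df_a, df_b)),
        p_b_greater=float(stats.f.sf(1.0 / F, df_b, df_a)),
        df_a=df_a, df_b=df_b,
    )


@dataclass
class OverlapResult:
    odds_ratio: float
    p: float
    table: np.ndarray  # 2x2: [[both, A only], [B only, neither]]


def hypergeometric_overlap(set_a, set_b, universe) -> OverlapResult:
    """Upper-tail hypergeometric test of gene-set overlap.

    The p-value is P(overlap >= observed) under random draws of |A| genes
    from the universe; the odds ratio uses the Haldane-Anscombe 0.5
    correction when any 2x2 cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A = set(set_a) & universe
    B = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    N = len(universe)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        oa, ob, oc, od = a, b, c, d
    odds = (oa * od) / (ob * oc)
    p = float(stats.hypergeom.sf(a - 1, N, len(A), len(B)))
    return OverlapResult(float(odds), p,
                         np.array([[a, b], [c, d]], dtype=int))


def _correlation_distance(features: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distance; constant rows get distance 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(features)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_genes(features, k: int):
    """Agglomerative clustering of gene feature vectors.

    Average linkage on correlation distance (1 - r), cut at k clusters.
    ``features`` is a genes x features matrix (e.g. concatenated per-group
    fitted curves, or per-grid-point shift profiles).

    Returns a Series of 1-based cluster labels indexed by gene.
    """
    df = features if isinstance(features, pd.DataFrame) else pd.DataFrame(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > df.shape[0]:
        raise ValueError(f"k={k} exceeds the {df.shape[0]} genes provided")
    if k == 1:
        return pd.Series(np.ones(df.shape[0], dtype=int), index=df.index,
                         name="cluster")
    Z = hierarchy.linkage(_correlation_distance(df.to_numpy(dtype=float)),
                          method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=df.index, name="cluster")


@dataclass
class BootstrapClusterResult:
    linkage: np.ndarray
    coassignment: pd.DataFrame     # pairwise same-cluster frequency
    partition: pd.Series           # consensus 2-group labels (1/2)
    stability: float               # mean co-assignment agreement w/ partition


def bootstrap_cluster_samples(data, n_boot: int = 1000,
                              seed: int | None = None,
                              detrend_ages=None,
                              max_degree: int = 3) -> BootstrapClusterResult:
    """Bootstrap-supported 2-group clustering of samples.

    Samples are clustered hierarchically (average linkage, correlation
    distance on per-gene standardized expression); genes are resampled
    with replacement ``n_boot`` times, the 2-cluster cut is recorded each
    time, and the pairwise co-assignment frequency matrix summarizes
    stability. The consensus partition clusters (1 - co-assignment), and
    the stability score is the mean over sample pairs of the co-assignment
    frequency (same consensus group) or its complement (different groups).

    When ``detrend_ages`` is given (ages per sample), each gene is first
    residualized on its pooled fitted age curve, so samples group by their
    *deviation* from the shared age trend rather than by age itself --
    the appropriate feature space for isolating an accelerated
    subpopulation, since age dominates the raw correlation structure.
    """
    values = data.values if isinstance(data, ExpressionDataset) else data
    df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(values)
    n_genes, n_samples = df.shape
    if n_samples < 2 or n_genes < 10:
        raise ValueError("need >= 2 samples and >= 10 genes")
    rng = np.random.default_rng(seed)
    if detrend_ages is not None:
        from .trajectory import fit_best_polynomial

        ages = np.asarray(detrend_ages, dtype=float)
        arr = df.to_numpy(dtype=float)
        resid = np.empty_like(arr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n_genes):
                fit = fit_best_polynomial(ages, arr[i], max_degree=max_degree)
                resid[i] = arr[i] - fit.predict(ages)
        df = pd.DataFrame(resid, index=df.index, columns=df.columns)
    std = standardize_genes(df).to_numpy(dtype=float)

    def _two_cut(mat):
        Z = hierarchy.linkage(_correlation_distance(mat.T), method="average")
        return Z, hierarchy.fcluster(Z, t=2, criterion="maxclust")

    Z_full, _ = _two_cut(std)
    co = np.zeros((n_samples, n_samples))
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, n_genes)
        _, labels = _two_cut(std[idx])
        co += labels[:, None] == labels[None, :]
    co /= n_boot
    np.fill_diagonal(co, 1.0)
    dist = np.clip(1.0 - co, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z_cons = hierarchy.linkage(squareform(dist, checks=False),
                               method="average")
    partition = hierarchy.fcluster(Z_cons, t=2, criterion="maxclust")
    same = partition[:, None] == partition[None, :]
    iu = np.triu_indices(n_samples, k=1)
    stability = float(np.where(same, co, 1.0 - co)[iu].mean())
    return BootstrapClusterResult(
        linkage=Z_full,
        coassignment=pd.DataFrame(co, index=df.columns, columns=df.columns),
        partition=pd.Series(partition, index=df.columns, name="partition"),
        stability=stability,
    )
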