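"""Per-gene trajectory test cascade.

Three stages, each an F- or correlation test at a raw p < alpha threshold
(no multiple-testing correction by default, an intentional reproduction
choice; a BH-FDR switch is available):

1. age effect -- ordinary least squares polynomial (degree 0-3, chosen by
   the adjusted-r² criterion) against the intercept-only model;
2. between-group divergence -- analysis of covariance: one pooled curve
   versus independent per-group curves of the same degree;
3. co-direction -- Pearson correlation of the two groups' fitted curves on
   a shared age grid must be significantly positive, so that a time shift
   (not opposite trends) can explain the divergence.

Ages are centered before fitting for numerical conditioning; coefficients
are reported in the centered basis (intercept first).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PolyFitResult",
    "fit_best_polynomial",
    "age_test",
    "ancova_divergence_test",
    "codirection_test",
    "run_cascade",
]

_TIE_TOL = 1e-10
polyval = np.polynomial.polynomial.polyval
polyvander = np.polynomial.polynomial.polyvander


@dataclass
class PolyFitResult:
    """Selected polynomial fit of expression on (centered) age."""

    degree: int
    coefficients: np.ndarray  # centered basis, intercept first
    center: float             # age offset subtracted before fitting
    adjusted_r2: float
    rss: float
    n: int

    def predict(self, ages) -> np.ndarray:
        return polyval(np.asarray(ages, dtype=float) - self.center,
                       self.coefficients)


def _feasible_max_degree(x: np.ndarray, max_degree: int) -> int:
    n = len(x)
    n_distinct = len(np.unique(x))
    cap = min(max_degree, n - 2, n_distinct - 1)
    return max(cap, 0)


def fit_best_polynomial(ages, values, max_degree: int = 3,
                        center: float | None = None) -> PolyFitResult:
    """OLS fits for each degree 0..max_degree; keep the best adjusted r².

    Ties (within 1e-10) are broken toward the lower degree. If the design
    cannot support ``max_degree`` (too few samples or distinct ages) the
    degree is capped with a warning.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("ages and values must have equal length")
    if n < 2 or len(np.unique(x)) < 2:
        raise ValueError("need at least 2 samples with distinct ages")
    cap = _feasible_max_degree(x, max_degree)
    if cap < max_degree:
        warnings.warn(
            f"degree capped at {cap} (n={n}, "
            f"{len(np.unique(x))} distinct ages)", stacklevel=2
        )
    if center is None:
        center = float(x.mean())
    xc = x - center
    tss = float(((y - y.mean()) ** 2).sum())

    best = None
    for d in range(cap + 1):
        V = polyvander(xc, d)
        beta, *_ = np.linalg.lstsq(V, y, rcond=None)
        rss = float(((y - V @ beta) ** 2).sum())
        if tss <= 0.0:
            adj = 0.0
        else:
            adj = 1.0 - (rss / (n - d - 1)) / (tss / (n - 1))
        fit = PolyFitResult(d, np.atleast_1d(beta), center, adj, rss, n)
        if best is None or adj > best.adjusted_r2 + _TIE_TOL:
            best = fit
    return best


def age_test(ages, values, max_degree: int = 3, fit: PolyFitResult | None = None):
    """F-test of the selected polynomial against the intercept-only model.

    Returns the p-value; degree-0 selection yields p = 1 by definition.
    """
    y = np.asarray(values, dtype=float)
    if fit is None:
        fit = fit_best_polynomial(ages, y, max_degree=max_degree)
    d, n = fit.degree, fit.n
    if d == 0:
        return 1.0
    rss0 = float(((y - y.mean()) ** 2).sum())
    if fit.rss <= 0.0:
        return 0.0
    F = ((rss0 - fit.rss) / d) / (fit.rss / (n - d - 1))
    return float(stats.f.sf(F, d, n - d - 1))


def ancova_divergence_test(ages, values, groups, max_degree: int = 3,
                           full_output: bool = False):
    """ANCOVA-style divergence test: pooled curve vs per-group curves.

    The polynomial degree is chosen once, on the pooled data, by the
    adjusted-r² criterion (capped so each group can support it); the full
    model fits an independent curve of that degree per group. F-test on the
    RSS reduction with (d+1) numerator and (n - 2(d+1)) denominator df.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    grp = np.asarray(groups)
    levels = sorted(pd.unique(grp))
    if len(levels) != 2:
        raise ValueError(f"expected two groups, got {levels}")
    masks = [grp == lv for lv in levels]
    cap = max_degree
    for lv, m in zip(levels, masks):
        gcap = _feasible_max_degree(x[m], max_degree)
        if int(m.sum()) < 2 or gcap < 1:
            raise ValueError(
                f"group {lv!r} has too few samples/distinct ages for the fit"
            )
        cap = min(cap, int(m.sum()) - 2, gcap)
    pooled = fit_best_polynomial(x, y, max_degree=cap)
    d = pooled.degree
    n = len(y)
    df_den = n - 2 * (d + 1)
    if df_den < 1:
        raise ValueError("not enough samples for the per-group model")
    rss_full = 0.0
    for m in masks:
        V = polyvander(x[m] - pooled.center, d)
        beta, *_ = np.linalg.lstsq(V, y[m], rcond=None)
        rss_full += float(((y[m] - V @ beta) ** 2).sum())
    num = (pooled.rss - rss_full) / (d + 1)
    if rss_full <= 1e-300:
        F = 0.0 if num <= 1e-300 else np.inf
    else:
        F = num / (rss_full / df_den)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, d + 1, df_den))
    if full_output:
        return p, {"F": float(F), "degree": d, "rss_pooled": pooled.rss,
                   "rss_full": rss_full, "df_num": d + 1, "df_den": df_den}
    return p


def codirection_test(fit_a: PolyFitResult, fit_b: PolyFitResult, age_grid):
    """Pearson correlation of the two fitted curves on a shared grid.

    One-sided test for positive correlation. A flat (degree-0 or
    zero-variance) curve leaves r undefined; the gene is reported as
    not-passing with reason.

    Returns ``(r, p, reason)``; reason is "" when the test applies.
    """
    grid = np.asarray(age_grid, dtype=float)
    if len(grid) < 20:
        raise ValueError("co-direction grid needs at least 20 points")
    ca = fit_a.predict(grid)
    cb = fit_b.predict(grid)
    if ca.std() <= 1e-12 or cb.std() <= 1e-12:
        return np.nan, 1.0, "flat fitted curve: correlation undefined"
    r, p = stats.pearsonr(ca, cb, alternative="greater")
    return float(r), float(p), ""


def _overlap_grid(ages_a, ages_b, n_points):
    lo = max(np.min(ages_a), np.min(ages_b))
    hi = min(np.max(ages_a), np.max(ages_b))
    if not lo < hi:
        raise ValueError("the two groups' age ranges do not overlap")
    return np.linspace(lo, hi, n_points)


def run_cascade(ds, alpha: float = 0.05, max_degree: int = 3,
                codirection_grid: int = 100,
                correction: str | None = None) -> pd.DataFrame:
    """Apply the three-stage cascade to every gene of a dataset.

    Parameters
    ----------
    ds : ExpressionDataset
    alpha : float
        Per-stage threshold on the (raw) p-values.
    correction : {None, "fdr_bh"}
        Optional Benjamini-Hochberg adjustment of each stage's p-values
        before thresholding.

    Returns a per-gene table with p-values, the co-direction r, selected
    degrees, the pass flags of the three stages and a reason string for
    genes dropped by an error or a degenerate fit. Per-gene failures never
    abort the run.
    """
    ages = ds.ages.to_numpy(dtype=float)
    grp = ds.groups.to_numpy()
    rows = []
    for gene in ds.gene_ids:
        rec = {
            "gene": gene, "age_p": np.nan, "divergence_p": np.nan,
            "codirection_r": np.nan, "codirection_p": np.nan,
            "degree_pooled": -1, "degree_a": -1, "degree_b": -1,
            "passes_stage1": False, "passes_stage2": False,
            "passes_stage3": False, "reason": "",
        }
        y = ds.values.loc[gene].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pooled = fit_best_polynomial(ages, y, max_degree=max_degree)
                rec["degree_pooled"] = pooled.degree
                rec["age_p"] = age_test(ages, y, fit=pooled)
                rec["divergence_p"] = ancova_divergence_test(
                    ages, y, grp, max_degree=max_degree
                )
                aa, ya, ab, yb = ds.group_arrays(gene)
                fit_a = fit_best_polynomial(aa, ya, max_degree=max_degree)
                fit_b = fit_best_polynomial(ab, yb, max_degree=max_degree)
                rec["degree_a"] = fit_a.degree
                rec["degree_b"] = fit_b.degree
                grid = _overlap_grid(aa, ab, codirection_grid)
                r, p, reason = codirection_test(fit_a, fit_b, grid)
                rec["codirection_r"] = r
                rec["codirection_p"] = p
                if reason:
                    rec["reason"] = reason
        except (ValueError, np.linalg.LinAlgError) as exc:
            rec["reason"] = str(exc)
        rows.append(rec)
    table = pd.DataFrame(rows).set_index("gene")

    def _adjusted(col):
        p = table[col].copy()
        if correction == "fdr_bh":
            ok = p.notna()
            p.loc[ok] = stats.false_discovery_control(p[ok], method="bh")
        elif correction is not None:
            raise ValueError(f"unknown correction {correction!r}")
        return p

    p1 = _adjusted("age_p")
    p2 = _adjusted("divergence_p")
    p3 = _adjusted("codirection_p")
    table["passes_stage1"] = p1.notna() & (p1 < alpha)
    table["passes_stage2"] = table["passes_stage1"] & p2.notna() & (p2 < alpha)
    table["passes_stage3"] = (
        table["passes_stage2"] & p3.notna() & (p3 < alpha)
        & (table["reason"] == "")
    )
    return table


# ---------------------------------------------------------------------------
# batched fitting helpers (used by the DTW null simulations)
# ---------------------------------------------------------------------------

def _batch_select_curves(x: np.ndarray, Y: np.ndarray, grid: np.ndarray,
                         max_degree: int, center: float | None = None):
    """Fit many replicate series sharing one age design; evaluate on a grid.

    Parameters
    ----------
    x : (n,) ages; Y : (R, n) replicate values; grid : (g,) evaluation ages.

    Returns
    -------
    curves : (R, g) fitted values of the adjusted-r²-selected degree.
    degrees : (R,) selected degree per replicate.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(x)
    if center is None:
        center = float(x.mean())
    xc = x - center
    gc = np.asarray(grid, dtype=float) - center
    cap = _feasible_max_degree(x, max_degree)
    R = Y.shape[0]
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    tss_safe = np.where(tss > 0, tss, 1.0)

    best_adj = np.full(R, -np.inf)
    degrees = np.zeros(R, dtype=int)
    curves = np.empty((R, len(gc)))
    for d in range(cap + 1):
        V = polyvander(xc, d)          # (n, d+1)
        pinv = np.linalg.pinv(V)       # (d+1, n)
        B = Y @ pinv.T                 # (R, d+1)
        resid = Y - B @ V.T
        rss = (resid ** 2).sum(axis=1)
        adj = 1.0 - (rss / (n - d - 1)) / (tss_safe / (n - 1))
        adj = np.where(tss > 0, adj, 0.0)
        G = polyvander(gc, d)          # (g, d+1)
        cand = B @ G.T                 # (R, g)
        take = adj > best_adj + _TIE_TOL
        if d == 0:
            take = np.ones(R, dtype=bool)
        best_adj = np.where(take, adj, best_adj)
        degrees = np.where(take, d, degrees)
        curves[take] = cand[take]
    return curves, degrees
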