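"""Heterochrony testing by dynamic time warping with simulated significance.

The two groups' fitted expression-age curves are evaluated on a shared
grid spanning the overlap of their observed age ranges, jointly
standardized (one mean/SD across both curves, so a pure vertical offset of
monotone curves is read as a time shift, not discarded), and aligned by
dynamic time warping with relaxed end matching: the warping path may start
and end up to ``slack`` grid points away from the corners, with
squared-difference local cost and steps {(1,0), (0,1), (1,1)}.

From the optimal path a per-grid-point time shift is estimated (matched
reference age minus query age, averaged per query point); its mean over
the query points, in years, is the test statistic. Significance is
assessed by a parametric-bootstrap null: both groups share the pooled
fitted curve, Gaussian noise with the pooled residual SD is added at the
real samples' ages, and the whole fit-grid-align-estimate pipeline is
rerun per replicate. Both alignment directions are tested; a gene is
significantly heterochronic only when both directions reject and their
shifts agree in sign.

Sign convention (fixed): shifts are reported as (group-B age minus
group-A age along the path), so a positive mean shift always means group
A is accelerated -- it reaches group B's older-age expression states at a
younger age.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dataset import ExpressionDataset
from .trajectory import (PolyFitResult, _batch_select_curves, _overlap_grid,
                         fit_best_polynomial)

__all__ = [
    "CurveGrid",
    "AlignmentPath",
    "ShiftEstimate",
    "HeterochronyResult",
    "build_curve_grid",
    "dtw_align",
    "estimate_shift",
    "simulate_null_p",
    "heterochrony_test",
    "heterochrony_screen",
    "nls_shift_estimate",
]

_MIN_GRID = 10
# backtracking pointer codes
_DIAG, _UP, _LEFT, _START = 0, 1, 2, 3


@dataclass
class CurveGrid:
    """Jointly standardized fitted curves of the two groups on a shared grid."""

    ages: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if not (len(self.ages) == len(self.values_a) == len(self.values_b)):
            raise ValueError("grid arrays must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("grid ages must be strictly increasing")

    @property
    def step(self) -> float:
        return float(self.ages[1] - self.ages[0])


@dataclass
class AlignmentPath:
    """Monotone warping path as ordered (i, j) index pairs plus its cost."""

    pairs: np.ndarray  # (K, 2) int
    cost: float


@dataclass
class ShiftEstimate:
    """Per-query-grid-point time shifts (years) and their mean."""

    query: str                 # "A" or "B": which curve indexed the path rows
    query_ages: np.ndarray
    shifts: np.ndarray         # ageB - ageA per query point (positive = A fast)
    mean_shift: float
    direction: str = "none"    # set by the significance test


@dataclass
class HeterochronyResult:
    gene: object
    p_a_to_b: float
    p_b_to_a: float
    significant: bool
    shift: ShiftEstimate            # A-as-query estimate
    shift_b_to_a: ShiftEstimate
    mean_shift: float               # average of the two directions' means
    direction: str
    n_null: int
    seed: int | None
    reason: str = ""


def build_curve_grid(ds: ExpressionDataset, gene, fit_a: PolyFitResult,
                     fit_b: PolyFitResult, n_grid: int = 50) -> CurveGrid:
    """Evaluate both groups' fits on the age-overlap grid and standardize.

    Standardization is joint: one mean and SD computed across the two
    curves together, so relative offset and shape are preserved.
    """
    if n_grid < _MIN_GRID:
        raise ValueError(f"n_grid must be >= {_MIN_GRID}")
    aa, _, ab, _ = ds.group_arrays(gene)
    grid = _overlap_grid(aa, ab, n_grid)
    ca = fit_a.predict(grid)
    cb = fit_b.predict(grid)
    both = np.concatenate([ca, cb])
    mu, sd = both.mean(), both.std()
    if sd <= 1e-12:
        return CurveGrid(grid, np.zeros(n_grid), np.zeros(n_grid),
                         degenerate=True)
    return CurveGrid(grid, (ca - mu) / sd, (cb - mu) / sd)


# ---------------------------------------------------------------------------
# dynamic programming core (vectorized across replicates)
# ---------------------------------------------------------------------------

def _dtw_tables(costs: np.ndarray, slack: int):
    """DP tables for a batch of cost matrices.

    costs : (R, n, m). Paths may start at (i,0) or (0,j) with i,j <= slack.
    Returns cumulative costs D and backtracking pointers P.
    Tie preference: diagonal, then (i-1,j), then (i,j-1), then fresh start.
    """
    R, n, m = costs.shape
    D = np.empty((R, n, m))
    P = np.empty((R, n, m), dtype=np.int8)
    D[:, 0, 0] = costs[:, 0, 0]
    P[:, 0, 0] = _START
    for i in range(1, n):
        cont = D[:, i - 1, 0]
        if i <= slack:
            take = cont <= 0.0  # fresh start costs only the local cell
            D[:, i, 0] = np.where(take, cont, 0.0) + costs[:, i, 0]
            P[:, i, 0] = np.where(take, _UP, _START)
        else:
            D[:, i, 0] = cont + costs[:, i, 0]
            P[:, i, 0] = _UP
    for j in range(1, m):
        cont = D[:, 0, j - 1]
        if j <= slack:
            take = cont <= 0.0
            D[:, 0, j] = np.where(take, cont, 0.0) + costs[:, 0, j]
            P[:, 0, j] = np.where(take, _LEFT, _START)
        else:
            D[:, 0, j] = cont + costs[:, 0, j]
            P[:, 0, j] = _LEFT
    for i in range(1, n):
        Di1 = D[:, i - 1]
        Di = D[:, i]
        Pi = P[:, i]
        ci = costs[:, i]
        for j in range(1, m):
            diag = Di1[:, j - 1]
            up = Di1[:, j]
            left = Di[:, j - 1]
            best = diag
            ptr = np.zeros(R, dtype=np.int8)
            mask = up < best
            if mask.any():
                best = np.where(mask, up, best)
                ptr[mask] = _UP
            mask = left < best
            if mask.any():
                best = np.where(mask, left, best)
                ptr[mask] = _LEFT
            Di[:, j] = best + ci[:, j]
            Pi[:, j] = ptr
    return D, P


def _end_candidates(n: int, m: int, slack: int):
    """Admissible end cells, corner first (preferred on cost ties)."""
    cells = [(n - 1, m - 1)]
    for t in range(1, slack + 1):
        if m - 1 - t >= 0:
            cells.append((n - 1, m - 1 - t))
        if n - 1 - t >= 0:
            cells.append((n - 1 - t, m - 1))
    return cells


def _backtrack(P: np.ndarray, i: int, j: int) -> np.ndarray:
    pairs = [(i, j)]
    while True:
        p = P[i, j]
        if p == _START:
            break
        if p == _DIAG:
            i, j = i - 1, j - 1
        elif p == _UP:
            i -= 1
        else:
            j -= 1
        pairs.append((i, j))
    return np.asarray(pairs[::-1], dtype=int)


def _batch_align(curves_q: np.ndarray, curves_r: np.ndarray, slack: int):
    """Align each query curve to its reference curve (row-wise batch).

    Returns (paths, costs): a list of (K,2) index arrays and a (R,) array.
    """
    costs = (curves_q[:, :, None] - curves_r[:, None, :]) ** 2
    R, n, m = costs.shape
    D, P = _dtw_tables(costs, slack)
    cells = _end_candidates(n, m, slack)
    endD = np.stack([D[:, i, j] for (i, j) in cells], axis=1)  # (R, C)
    pick = np.argmin(endD, axis=1)   # first occurrence wins -> corner preferred
    final = endD[np.arange(R), pick]
    paths = [_backtrack(P[r], *cells[pick[r]]) for r in range(R)]
    return paths, final


def dtw_align(grid: CurveGrid, slack: int = 5, query: str = "A") -> AlignmentPath:
    """Minimum-cost monotone alignment of the two curves with open ends.

    ``query`` selects which curve indexes the path rows: ``"A"`` aligns
    curve A onto B (path pairs are (i_A, j_B)); ``"B"`` the reverse.
    """
    n = len(grid.ages)
    if not 0 <= slack <= max(1, n / 4):
        raise ValueError(f"slack must lie in [0, n_grid/4], got {slack}")
    if query == "A":
        q, r = grid.values_a, grid.values_b
    elif query == "B":
        q, r = grid.values_b, grid.values_a
    else:
        raise ValueError("query must be 'A' or 'B'")
    paths, final = _batch_align(q[None, :], r[None, :], slack)
    return AlignmentPath(paths[0], float(final[0]))


def _mean_shift_from_path(pairs: np.ndarray, ages: np.ndarray,
                          query: str) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-query-point shifts (ageB - ageA) and their mean.

    ``pairs`` rows are (query index, reference index). For query A the
    reference is B, so shift = ages[ref] - ages[query]; for query B the
    roles flip and shift = ages[query] - ages[ref]. Either way positive
    means A accelerated.
    """
    qi = pairs[:, 0]
    ri = pairs[:, 1]
    raw = ages[ri] - ages[qi] if query == "A" else ages[qi] - ages[ri]
    counts = np.bincount(qi)
    sums = np.bincount(qi, weights=raw)
    present = counts > 0
    shifts = sums[present] / counts[present]
    return ages[np.nonzero(present)[0]], shifts, float(shifts.mean())


def estimate_shift(path: AlignmentPath, grid: CurveGrid,
                   query: str = "A") -> ShiftEstimate:
    """Per-grid-point time shifts along an alignment path, in years."""
    if len(path.pairs) == 0:
        raise ValueError("empty alignment path")
    qa, shifts, mean = _mean_shift_from_path(path.pairs, grid.ages, query)
    return ShiftEstimate(query, qa, shifts, mean)


# ---------------------------------------------------------------------------
# observed statistic and the simulation null
# ---------------------------------------------------------------------------

def _observed_shifts(ds, gene, n_grid, slack, max_degree):
    aa, ya, ab, yb = ds.group_arrays(gene)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_a = fit_best_polynomial(aa, ya, max_degree=max_degree)
        fit_b = fit_best_polynomial(ab, yb, max_degree=max_degree)
    grid = build_curve_grid(ds, gene, fit_a, fit_b, n_grid=n_grid)
    if grid.degenerate:
        zero = ShiftEstimate("A", grid.ages, np.zeros(len(grid.ages)), 0.0)
        zero_b = ShiftEstimate("B", grid.ages, np.zeros(len(grid.ages)), 0.0)
        return grid, zero, zero_b, True
    pa = dtw_align(grid, slack=slack, query="A")
    pb = dtw_align(grid, slack=slack, query="B")
    return (grid, estimate_shift(pa, grid, "A"), estimate_shift(pb, grid, "B"),
            False)


def _batch_mean_shifts(curves_a, curves_b, ages, slack):
    """Both-direction mean shifts for a batch of curve pairs -> (R, 2)."""
    R = curves_a.shape[0]
    out = np.empty((R, 2))
    paths, _ = _batch_align(curves_a, curves_b, slack)
    for r in range(R):
        out[r, 0] = _mean_shift_from_path(paths[r], ages, "A")[2]
    paths, _ = _batch_align(curves_b, curves_a, slack)
    for r in range(R):
        out[r, 1] = _mean_shift_from_path(paths[r], ages, "B")[2]
    return out


def _null_mean_shifts(ds, gene, n_null, rng, n_grid, slack, max_degree,
                      null_mode="parametric"):
    """Mean shifts (both directions) under the no-heterochrony null.

    Parametric mode: both groups share the pooled fitted curve; Gaussian
    noise with the pooled residual SD is added at the real samples' ages.
    Permutation mode: group labels are permuted across samples.
    Returns an (n_null, 2) array, or None when the pooled fit is degenerate.
    """
    ages = ds.ages.to_numpy(dtype=float)
    y = ds.values.loc[gene].to_numpy(dtype=float)
    a, b = ds.group_levels
    mask_a = ds.group_mask(a)
    mask_b = ds.group_mask(b)
    grid = _overlap_grid(ages[mask_a], ages[mask_b], n_grid)

    if null_mode == "parametric":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = fit_best_polynomial(ages, y, max_degree=max_degree)
        mu = pooled.predict(ages)
        resid = y - mu
        sigma = float(np.sqrt((resid ** 2).sum()
                              / max(len(y) - pooled.degree - 1, 1)))
        if sigma <= 1e-12 and pooled.degree == 0:
            return None, grid
        Y = mu[None, :] + sigma * rng.standard_normal((n_null, len(y)))
        ca, _ = _batch_select_curves(ages[mask_a], Y[:, mask_a], grid,
                                     max_degree)
        cb, _ = _batch_select_curves(ages[mask_b], Y[:, mask_b], grid,
                                     max_degree)
        curves = np.concatenate([ca, cb], axis=1)
    elif null_mode == "permutation":
        # per-replicate designs differ, so the fits are looped
        n_a = int(mask_a.sum())
        ca = np.empty((n_null, len(grid)))
        cb = np.empty((n_null, len(grid)))
        for r in range(n_null):
            idx = rng.permutation(len(y))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ca[r], _ = _batch_select_curves(
                    ages[idx[:n_a]], y[idx[:n_a]][None, :], grid, max_degree
                )
                cb[r], _ = _batch_select_curves(
                    ages[idx[n_a:]], y[idx[n_a:]][None, :], grid, max_degree
                )
        curves = np.concatenate([ca, cb], axis=1)
    else:
        raise ValueError("null_mode must be 'parametric' or 'permutation'")

    mu_c = curves.mean(axis=1, keepdims=True)
    sd_c = curves.std(axis=1, keepdims=True)
    flat = sd_c[:, 0] <= 1e-12
    sd_c[flat] = 1.0
    curves = (curves - mu_c) / sd_c
    curves[flat] = 0.0
    g = len(grid)
    return _batch_mean_shifts(curves[:, :g], curves[:, g:], grid, slack), grid


def _add_one_p(null_stats: np.ndarray, observed: float) -> float:
    """Add-one permutation-style p-value; always > 0."""
    n = len(null_stats)
    return float((1 + int((np.abs(null_stats) >= abs(observed)).sum()))
                 / (n + 1))


def simulate_null_p(ds: ExpressionDataset, gene, observed_stat: float,
                    n_null: int = 1000, seed: int | None = None,
                    direction: str = "A_to_B", n_grid: int = 50,
                    slack: int = 5, max_degree: int = 3,
                    null_mode: str = "parametric") -> float:
    """Simulation p-value for one alignment direction's |mean shift|.

    p = (1 + #{null |mean_shift| >= |observed|}) / (n_null + 1).
    A degenerate pooled fit (flat curve, no residual scale) yields p = 1.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    nulls, _ = _null_mean_shifts(ds, gene, n_null, rng, n_grid, slack,
                                 max_degree, null_mode)
    if nulls is None:
        return 1.0
    col = 0 if direction in ("A_to_B", "AtoB", "A") else 1
    return _add_one_p(nulls[:, col], observed_stat)


def heterochrony_test(ds: ExpressionDataset, gene, alpha: float = 0.05,
                      n_null: int = 1000, seed: int | None = None,
                      n_grid: int = 50, slack: int = 5, max_degree: int = 3,
                      null_mode: str = "parametric") -> HeterochronyResult:
    """Bidirectional DTW shift test for one gene.

    Aligns A onto B and B onto A, obtains a simulation p-value for each
    direction (from one shared set of null replicates), and declares the
    gene significantly heterochronic only when both p-values fall below
    ``alpha`` and the two directions' mean shifts agree in sign. The
    reported direction follows the shift sign: positive = A-accelerated.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    rng = np.random.default_rng(seed)
    grid, est_a, est_b, degenerate = _observed_shifts(
        ds, gene, n_grid, slack, max_degree
    )
    if degenerate:
        return HeterochronyResult(
            gene, 1.0, 1.0, False, est_a, est_b, 0.0, "none", n_null, seed,
            reason="degenerate fits: both curves flat",
        )
    nulls, _ = _null_mean_shifts(ds, gene, n_null, rng, n_grid, slack,
                                 max_degree, null_mode)
    if nulls is None:
        return HeterochronyResult(
            gene, 1.0, 1.0, False, est_a, est_b,
            0.5 * (est_a.mean_shift + est_b.mean_shift), "none", n_null, seed,
            reason="degenerate pooled fit under the null",
        )
    p_ab = _add_one_p(nulls[:, 0], est_a.mean_shift)
    p_ba = _add_one_p(nulls[:, 1], est_b.mean_shift)
    mean_shift = 0.5 * (est_a.mean_shift + est_b.mean_shift)
    sign_ok = np.sign(est_a.mean_shift) == np.sign(est_b.mean_shift) != 0
    significant = bool(p_ab < alpha and p_ba < alpha and sign_ok)
    reason = ""
    if p_ab < alpha and p_ba < alpha and not sign_ok:
        reason = "alignment directions disagree in shift sign"
    direction = "none"
    if significant:
        direction = "A-accelerated" if mean_shift > 0 else "B-accelerated"
    est_a.direction = direction
    est_b.direction = direction
    return HeterochronyResult(gene, p_ab, p_ba, significant, est_a, est_b,
                              mean_shift, direction, n_null, seed, reason)


def heterochrony_screen(ds: ExpressionDataset, genes=None, alpha: float = 0.05,
                        n_null: int = 1000, seed: int | None = None,
                        n_grid: int = 50, slack: int = 5, max_degree: int = 3,
                        null_mode: str = "parametric",
                        threads: int = 1) -> pd.DataFrame:
    """Run :func:`heterochrony_test` over many genes; per-gene child seeds
    are spawned from ``seed`` so results do not depend on worker count."""
    if genes is None:
        genes = list(ds.gene_ids)
    genes = list(genes)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(len(genes))]

    def one(gene, s):
        return heterochrony_test(ds, gene, alpha=alpha, n_null=n_null, seed=s,
                                 n_grid=n_grid, slack=slack,
                                 max_degree=max_degree, null_mode=null_mode)

    if threads > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=threads, backend="loky")(
            delayed(one)(g, s) for g, s in zip(genes, child_seeds)
        )
    else:
        results = [one(g, s) for g, s in zip(genes, child_seeds)]
    rows = [
        {
            "gene": r.gene, "p_a_to_b": r.p_a_to_b, "p_b_to_a": r.p_b_to_a,
            "mean_shift_years": r.mean_shift, "direction": r.direction,
            "significant": r.significant, "n_null": r.n_null,
            "seed": r.seed, "reason": r.reason,
        }
        for r in results
    ]
    columns = ["gene", "p_a_to_b", "p_b_to_a", "mean_shift_years",
               "direction", "significant", "n_null", "seed", "reason"]
    return pd.DataFrame(rows, columns=columns).set_index("gene")


# ---------------------------------------------------------------------------
# nonlinear-least-squares alternative estimator
# ---------------------------------------------------------------------------

def _nls_directional(ages_q, values_q, ages_r, values_r, max_degree,
                     fit_r: PolyFitResult | None = None) -> float:
    """Least-squares shift of the query observations onto the reference
    group's fitted curve; positive = query matches older reference ages."""
    if fit_r is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_r = fit_best_polynomial(ages_r, values_r,
                                        max_degree=max_degree)
    if fit_r.degree == 0 or np.std(fit_r.predict(ages_r)) <= 1e-12:
        raise ValueError("flat reference curve: shift undefined")
    r_lo, r_hi = float(ages_r.min()), float(ages_r.max())
    span = r_hi - r_lo
    min_in = max(len(ages_q) // 2, 2)

    def msd(delta):
        shifted = ages_q + delta
        inside = (shifted >= r_lo) & (shifted <= r_hi)
        if inside.sum() < min_in:
            return np.inf
        return float(((values_q[inside]
                       - fit_r.predict(shifted[inside])) ** 2).mean())

    # coarse scan guards against local minima of the fitted polynomial
    deltas = np.linspace(-span / 2, span / 2, 201)
    coarse = np.array([msd(d) for d in deltas])
    k = int(np.argmin(coarse))
    blo = deltas[max(k - 1, 0)]
    bhi = deltas[min(k + 1, len(deltas) - 1)]
    res = optimize.minimize_scalar(msd, bounds=(blo, bhi), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def nls_shift_estimate(ds: ExpressionDataset, gene, max_degree: int = 3,
                       fit_b: PolyFitResult | None = None,
                       symmetric: bool = True) -> float:
    """Shift estimate by 1-D nonlinear least squares, in years.

    The directional estimate finds the delta minimizing the mean squared
    difference between the query group's observed values and the
    reference group's fitted curve evaluated at (age + delta), over delta
    in [-span/2, +span/2] (span = reference observed age span). Only
    query samples whose shifted age falls inside the reference range
    enter the objective (at least half of them must), so the polynomial
    is never extrapolated.

    With ``symmetric=True`` (default) the returned shift averages the
    A-onto-fit(B) estimate and the negated B-onto-fit(A) estimate,
    mirroring the bidirectional alignment rule; ``symmetric=False`` gives
    the plain A-onto-fit(B) direction. Positive = A accelerated. A flat
    reference curve leaves the shift undefined (ValueError).
    """
    aa, ya, ab, yb = ds.group_arrays(gene)
    d_ab = _nls_directional(aa, ya, ab, yb, max_degree, fit_r=fit_b)
    if not symmetric:
        return d_ab
    d_ba = _nls_directional(ab, yb, aa, ya, max_degree)
    return 0.5 * (d_ab - d_ba)
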