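import numpy as np
import pytest

from heterochron.dataset import ExpressionDataset
from heterochron.dtws import (CurveGrid, build_curve_grid, dtw_align,
                              estimate_shift, heterochrony_test,
                              nls_shift_estimate, simulate_null_p)
from heterochron.synthdata import SimulationConfig, generate
from heterochron.trajectory import fit_best_polynomial


def brute_force_cost(a, b, slack):
    """Exhaustive enumeration over all admissible open-ended monotone paths."""
    n, m = len(a), len(b)
    ends = {(i, m - 1) for i in range(n) if n - 1 - i <= slack}
    ends |= {(n - 1, j) for j in range(m) if m - 1 - j <= slack}
    best = [np.inf]

    def dfs(i, j, c):
        c += (a[i] - b[j]) ** 2
        if (i, j) in ends:
            best[0] = min(best[0], c)
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                dfs(i + di, j + dj, c)

    starts = {(i, 0) for i in range(min(slack, n - 1) + 1)}
    starts |= {(0, j) for j in range(min(slack, m - 1) + 1)}
    for i, j in starts:
        dfs(i, j, 0.0)
    return best[0]


def _grid_from_curves(a, b, lo=20.0, hi=90.0):
    return CurveGrid(np.linspace(lo, hi, len(a)), a, b)


class TestAlignment:
    def test_matches_exhaustive_enumeration_on_small_grids(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = int(rng.integers(3, 7))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            for slack in (0, 1):
                grid = CurveGrid(np.linspace(20, 90, n), a, b)
                path = dtw_align(grid, slack=slack)
                oracle = brute_force_cost(a, b, slack)
                assert path.cost == pytest.approx(oracle, abs=1e-12)

    def test_identical_curves_align_diagonally_at_zero_cost(self):
        vals = np.sin(np.linspace(0, 3, 30))
        grid = _grid_from_curves(vals, vals.copy())
        path = dtw_align(grid, slack=3)
        assert path.cost == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_array_equal(path.pairs[:, 0], path.pairs[:, 1])
        est = estimate_shift(path, grid)
        assert est.mean_shift == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(est.shifts, 0.0)

    def test_time_reversed_curve_costs_more(self):
        rng = np.random.default_rng(24)
        a = np.cumsum(rng.uniform(0.2, 1.0, 25))  # monotone, asymmetric
        a = (a - a.mean()) / a.std()
        grid_fwd = _grid_from_curves(a, a.copy())
        grid_rev = _grid_from_curves(a, a[::-1].copy())
        assert (dtw_align(grid_rev, slack=5).cost
                > dtw_align(grid_fwd, slack=5).cost)

    def test_slack_validation(self):
        vals = np.linspace(0, 1, 20)
        grid = _grid_from_curves(vals, vals)
        with pytest.raises(ValueError, match="slack"):
            dtw_align(grid, slack=9)  # > n/4


class TestCurveGrid:
    def test_minimum_grid_size_enforced(self, planted_shift_dataset):
        ds, _ = planted_shift_dataset
        gene = ds.gene_ids[0]
        aa, ya, ab, yb = ds.group_arrays(gene)
        fa = fit_best_polynomial(aa, ya)
        fb = fit_best_polynomial(ab, yb)
        with pytest.raises(ValueError, match=">= 10"):
            build_curve_grid(ds, gene, fa, fb, n_grid=2)

    def test_identical_fits_give_identical_curves(self, planted_shift_dataset):
        ds, _ = planted_shift_dataset
        gene = ds.gene_ids[0]
        aa, ya, *_ = ds.group_arrays(gene)
        fit = fit_best_polynomial(aa, ya)
        grid = build_curve_grid(ds, gene, fit, fit)
        np.testing.assert_allclose(grid.values_a, grid.values_b, atol=1e-12)


class TestShiftRecovery:
    @staticmethod
    def _noise_free_shift_dataset(delta=10.0, n=24):
        ages = np.linspace(20.0, 99.0, n)
        b = 0.05 * ages
        a = 0.05 * (ages + delta)
        values = np.vstack([np.concatenate([a, b])])
        import pandas as pd
        sample_ids = [f"s{i}" for i in range(2 * n)]
        return ExpressionDataset(
            pd.DataFrame(values, index=["g1"], columns=sample_ids),
            pd.Series(np.concatenate([ages, ages]), index=sample_ids),
            pd.Series(["A"] * n + ["B"] * n, index=sample_ids),
        )

    def test_noise_free_onset_shift_recovered_within_grid_step(self):
        ds = self._noise_free_shift_dataset(delta=10.0)
        aa, ya, ab, yb = ds.group_arrays("g1")
        fa = fit_best_polynomial(aa, ya)
        fb = fit_best_polynomial(ab, yb)
        grid = build_curve_grid(ds, "g1", fa, fb)
        path = dtw_align(grid, slack=12)
        est = estimate_shift(path, grid)
        assert est.mean_shift == pytest.approx(10.0, abs=grid.step + 0.5)

    def test_rate_scale_shifts_grow_with_age(self):
        """Rate-scaled gene: per-point shifts increase with age and the
        mean matches the planted midpoint shift."""
        ages = tuple(np.linspace(20, 99, 20))
        cfg = SimulationConfig(
            n_genes=10, n_per_group=20, noise_sd=0.0, frac_age_related=1.0,
            frac_divergent_given_age_related=1.0,
            frac_heterochronic_given_divergent=1.0, direction_bias=1.0,
            shift_years=10.0, heterochrony_mode_mix=0.0,
            trajectory_degree_weights=(0, 1, 0, 0),
            age_sampling="from_list", age_list=ages, seed=25,
        )
        ds, truth = generate(cfg)
        gene = truth.index[truth["true_mode"] == "rate-scale"][0]
        aa, ya, ab, yb = ds.group_arrays(gene)
        fa = fit_best_polynomial(aa, ya)
        fb = fit_best_polynomial(ab, yb)
        grid = build_curve_grid(ds, gene, fa, fb)
        est = estimate_shift(dtw_align(grid, slack=12), grid)
        assert est.mean_shift == pytest.approx(10.0, abs=3.0)
        half = len(est.shifts) // 2
        assert est.shifts[half:].mean() > est.shifts[:half].mean()

    def test_swapping_groups_negates_the_shift(self):
        ds = self._noise_free_shift_dataset(delta=8.0)
        swapped = ExpressionDataset(
            ds.values, ds.ages, ds.groups.map({"A": "B", "B": "A"})
        )

        def mean_shift(d):
            aa, ya, ab, yb = d.group_arrays("g1")
            fa = fit_best_polynomial(aa, ya)
            fb = fit_best_polynomial(ab, yb)
            grid = build_curve_grid(d, "g1", fa, fb)
            return estimate_shift(dtw_align(grid, slack=12), grid).mean_shift

        s1 = mean_shift(ds)
        s2 = mean_shift(swapped)
        assert s1 == pytest.approx(-s2, abs=2.0)
        assert s1 > 5.0


class TestSignificance:
    def test_zero_observed_statistic_gives_p_one(self, small_null_dataset):
        ds, _ = small_null_dataset
        p = simulate_null_p(ds, ds.gene_ids[0], observed_stat=0.0,
                            n_null=100, seed=1)
        assert p == 1.0

    def test_fixed_seed_reproduces_p(self, small_null_dataset):
        ds, _ = small_null_dataset
        g = ds.gene_ids[1]
        p1 = simulate_null_p(ds, g, observed_stat=3.0, n_null=100, seed=42)
        p2 = simulate_null_p(ds, g, observed_stat=3.0, n_null=100, seed=42)
        assert p1 == p2

    def test_planted_gene_detected_with_direction(self, planted_shift_dataset):
        ds, truth = planted_shift_dataset
        gene = truth.index[truth["is_heterochronic"]][0]
        res = heterochrony_test(ds, gene, n_null=200, seed=7, slack=12)
        assert res.significant
        assert res.direction == "A-accelerated"
        assert res.p_a_to_b < 0.05 and res.p_b_to_a < 0.05

    def test_flat_gene_reports_degenerate_reason(self):
        import pandas as pd
        n = 12
        sample_ids = [f"s{i}" for i in range(2 * n)]
        values = pd.DataFrame(np.full((1, 2 * n), 3.0), index=["g1"],
                              columns=sample_ids)
        ds = ExpressionDataset(
            values,
            pd.Series(np.tile(np.linspace(20, 90, n), 2), index=sample_ids),
            pd.Series(["A"] * n + ["B"] * n, index=sample_ids),
        )
        res = heterochrony_test(ds, "g1", n_null=100, seed=1)
        assert not res.significant
        assert "degenerate" in res.reason

    def test_permutation_null_mode_runs(self, small_null_dataset):
        ds, _ = small_null_dataset
        res = heterochrony_test(ds, ds.gene_ids[0], n_null=100, seed=3,
                                null_mode="permutation")
        assert 0.0 < res.p_a_to_b <= 1.0


class TestNlsShift:
    def test_noise_free_shift_recovered_exactly(self):
        ds = TestShiftRecovery._noise_free_shift_dataset(delta=10.0)
        assert nls_shift_estimate(ds, "g1") == pytest.approx(10.0, abs=0.1)

    def test_identical_groups_give_zero(self):
        ds = TestShiftRecovery._noise_free_shift_dataset(delta=0.0)
        assert nls_shift_estimate(ds, "g1") == pytest.approx(0.0, abs=0.1)

    def test_flat_reference_curve_rejected(self):
        import pandas as pd
        n = 12
        sample_ids = [f"s{i}" for i in range(2 * n)]
        rng = np.random.default_rng(9)
        row = np.concatenate([np.linspace(0, 1, n),
                              np.full(n, 0.5)])  # B flat
        values = pd.DataFrame(row[None, :], index=["g1"], columns=sample_ids)
        ds = ExpressionDataset(
            values,
            pd.Series(np.tile(np.linspace(20, 90, n), 2), index=sample_ids),
            pd.Series(["A"] * n + ["B"] * n, index=sample_ids),
        )
        with pytest.raises(ValueError, match="flat reference"):
            nls_shift_estimate(ds, "g1", symmetric=False)
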