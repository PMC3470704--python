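import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from heterochron.downstream import (bootstrap_cluster_samples, cluster_genes,
                                    cohens_d, corrected_effect_sizes,
                                    group_effect_comparison,
                                    hypergeometric_overlap, variance_f_test)
from heterochron.synthdata import SimulationConfig, generate
from heterochron.trajectory import fit_best_polynomial


class TestCohensD:
    def test_worked_example(self):
        assert cohens_d([3, 4, 5], [1, 2, 3]) == pytest.approx(2.0)

    def test_identical_groups_and_antisymmetry(self):
        x = [1.0, 2.0, 3.5]
        assert cohens_d(x, x) == 0.0
        y = [0.5, 1.5, 4.0]
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_shift_invariance(self):
        rng = np.random.default_rng(30)
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 12)
        assert cohens_d(x + 7, y + 7) == pytest.approx(cohens_d(x, y))

    def test_zero_pooled_sd_warns_nan(self):
        with pytest.warns(UserWarning, match="zero pooled SD"):
            assert math.isnan(cohens_d([1.0, 1.0], [1.0, 1.0]))


class TestCorrectedEffects:
    def test_linear_relation_leaves_zero_residuals(self):
        ac = np.linspace(-0.9, 0.9, 50)
        res = corrected_effect_sizes(2.0 * ac + 0.3, ac)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_age_corr(self):
        rng = np.random.default_rng(31)
        ac = rng.uniform(-1, 1, 200)
        d = 1.5 * ac + rng.normal(0, 0.5, 200)
        res = corrected_effect_sizes(d, ac)
        assert abs(np.corrcoef(res, ac)[0, 1]) < 1e-10
        assert abs(res.mean()) < 1e-12

    def test_noise_component_recovered(self):
        rng = np.random.default_rng(32)
        ac = rng.uniform(-1, 1, 500)
        eps = rng.normal(0, 0.4, 500)
        res = corrected_effect_sizes(2.0 * ac + eps, ac)
        assert np.corrcoef(res, eps)[0, 1] > 0.99

    def test_constant_age_corr_degenerates_to_centering(self):
        d = np.arange(12.0)
        with pytest.warns(UserWarning, match="constant age_corr"):
            res = corrected_effect_sizes(d, np.full(12, 0.5))
        np.testing.assert_allclose(res, d - d.mean())


class TestGroupEffectComparison:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(33)
        res = pd.Series(rng.normal(0, 1, 200),
                        index=[f"g{i}" for i in range(200)])
        res.iloc[:100] += 1.0
        _, p = group_effect_comparison(
            res, {"up": res.index[:100], "down": res.index[100:]})
        assert p < 0.01

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(34)
        vals = rng.normal(0, 1, 100)
        idx = [f"g{i}" for i in range(100)]
        res = pd.Series(vals, index=idx)
        ps = []
        for _ in range(200):
            perm = rng.permutation(idx)
            ps.append(group_effect_comparison(
                res, {"a": perm[:50], "b": perm[50:]})[1])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_all_tied_values_give_p_one(self):
        res = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        _, p = group_effect_comparison(
            res, {"a": res.index[:10], "b": res.index[10:]})
        assert p == 1.0

    def test_empty_group_rejected(self):
        res = pd.Series([1.0, 2.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="nonempty"):
            group_effect_comparison(res, {"a": ["g1", "g2"], "b": []})


class TestVarianceFTest:
    def test_swapping_groups_inverts_f(self):
        rng = np.random.default_rng(35)
        a, b = rng.normal(0, 2, 20), rng.normal(0, 1, 20)
        r1 = variance_f_test(a, b)
        r2 = variance_f_test(b, a)
        assert r1.F == pytest.approx(1.0 / r2.F)
        assert r1.p_a_greater == pytest.approx(r2.p_b_greater)

    def test_calibration_under_equal_variance(self):
        rng = np.random.default_rng(36)
        rej = 0
        for _ in range(500):
            a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
            if variance_f_test(a, b).p_a_greater < 0.05:
                rej += 1
        assert 0.02 <= rej / 500 <= 0.09

    def test_inflated_group_detected_on_residuals(self):
        """Fourfold variance inflation at n=20/group: the analytic power of
        the one-sided F-test is 0.85-0.89 for residual df 16-18, so the
        detection rate is checked against that attainable level."""
        cfg = SimulationConfig(n_genes=100, n_per_group=20,
                               frac_age_related=1.0,
                               frac_variance_inflated=1.0,
                               variance_inflation_factor=4.0, seed=37)
        ds, _ = generate(cfg)
        hits = 0
        for gene in ds.gene_ids:
            aa, ya, ab, yb = ds.group_arrays(gene)
            fa = fit_best_polynomial(aa, ya)
            fb = fit_best_polynomial(ab, yb)
            res = variance_f_test(ya, yb, aa, ab, fa, fb)
            hits += res.p_a_greater < 0.05
        assert hits / 100 >= 0.80

    def test_shift_invariance(self):
        rng = np.random.default_rng(38)
        a, b = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        assert variance_f_test(a + 5, b + 5).F == pytest.approx(
            variance_f_test(a, b).F)


class TestHypergeometricOverlap:
    def test_worked_complete_overlap_case(self):
        universe = [f"g{i}" for i in range(20)]
        res = hypergeometric_overlap(universe[:10], universe[:10], universe)
        assert res.p == pytest.approx(1.0 / math.comb(20, 10), rel=1e-12)

    def test_matches_enumeration_on_small_universes(self):
        for N in (5, 8, 12):
            universe = list(range(N))
            for na in (0, 2, N // 2, N):
                for nb in (1, N // 2):
                    max_k = min(na, nb)
                    min_k = max(0, na + nb - N)
                    for k in range(min_k, max_k + 1):
                        A = universe[:na]
                        B = universe[na - k:na - k + nb]
                        res = hypergeometric_overlap(A, B, universe)
                        kk = len(set(A) & set(B))
                        exact = sum(
                            math.comb(na, j) * math.comb(N - na, nb - j)
                            for j in range(kk, min(na, nb) + 1)
                        ) / math.comb(N, nb)
                        assert res.p == pytest.approx(exact, rel=1e-10)

    def test_degenerate_full_overlap(self):
        universe = list(range(10))
        res = hypergeometric_overlap(universe, universe, universe)
        assert res.p == 1.0

    def test_expected_overlap_gives_odds_near_one(self):
        universe = list(range(100))
        A = universe[:50]
        B = universe[25:75]  # overlap 25 = |A||B|/N
        res = hypergeometric_overlap(A, B, universe)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.05)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            hypergeometric_overlap([], [], [])


class TestClusterGenes:
    @staticmethod
    def _archetypes(noise, seed=39):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 40)
        rows, labels = [], []
        for i in range(60):
            up = i < 30
            base = t if up else 1.0 - t
            rows.append(base + rng.normal(0, noise, 40))
            labels.append(int(up))
        return pd.DataFrame(rows), np.array(labels)

    def test_planted_archetypes_recovered(self):
        feats, labels = self._archetypes(noise=0.05)
        pred = cluster_genes(feats, 2)
        assert adjusted_rand_score(labels, pred) >= 0.95

    def test_k_one_and_k_too_large(self):
        feats, _ = self._archetypes(noise=0.1)
        assert (cluster_genes(feats, 1) == 1).all()
        with pytest.raises(ValueError, match="exceeds"):
            cluster_genes(feats.iloc[:5], 9)

    def test_duplicated_rows_cluster_together(self):
        feats, _ = self._archetypes(noise=0.3)
        feats.iloc[1] = feats.iloc[0]
        pred = cluster_genes(feats, 4)
        assert pred.iloc[0] == pred.iloc[1]

    def test_invariant_to_gene_order(self):
        feats, labels = self._archetypes(noise=0.05)
        perm = np.random.default_rng(40).permutation(len(feats))
        pred1 = cluster_genes(feats, 2).to_numpy()
        pred2 = cluster_genes(feats.iloc[perm], 2)
        pred2 = pred2.reindex(feats.index).to_numpy()
        assert adjusted_rand_score(pred1, pred2) == pytest.approx(1.0)


class TestBootstrapClustering:
    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(41)
        data = pd.DataFrame(rng.normal(size=(40, 12)))
        r1 = bootstrap_cluster_samples(data, n_boot=50, seed=5)
        r2 = bootstrap_cluster_samples(data, n_boot=50, seed=5)
        pd.testing.assert_frame_equal(r1.coassignment, r2.coassignment)
        assert r1.stability == r2.stability

    def test_homogeneous_data_has_no_stable_split(self):
        rng = np.random.default_rng(42)
        data = pd.DataFrame(rng.normal(size=(200, 24)))
        res = bootstrap_cluster_samples(data, n_boot=100, seed=6)
        assert res.stability < 0.85

    def test_planted_subpopulation_separated_when_detrended(self):
        cfg = SimulationConfig(
            n_genes=300, n_per_group=20, frac_age_related=1.0,
            frac_divergent_given_age_related=1.0,
            frac_heterochronic_given_divergent=1.0, direction_bias=1.0,
            shift_years=15.0, heterochrony_mode_mix=1.0,
            subpopulation_fraction=0.5, seed=43,
        )
        ds, truth = generate(cfg)
        sub = set(truth.attrs["subpopulation_samples"])
        res = bootstrap_cluster_samples(ds, n_boot=100, seed=7,
                                        detrend_ages=ds.ages)
        part = res.partition
        in_sub = part.index.isin(sub)
        match = max((part.eq(1) == in_sub).mean(),
                    (part.eq(2) == in_sub).mean())
        assert match == 1.0
        assert res.stability >= 0.9
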