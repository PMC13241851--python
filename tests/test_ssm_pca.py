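"""SSM residuals, PCA, component filtering, stepwise recombination, CV."""

import numpy as np
import pytest
from scipy import stats

from neuroenergetics import (AgeGroupSplit, CohortConfig, CovariancePattern,
                             PatternComponent, age_relationship,
                             build_energetics_table, crossvalidate_pattern,
                             display_mask, filter_components,
                             generate_regional_cohort, pca_components,
                             posthoc_region_trends, separation_stats,
                             ssm_residual, stepwise_logistic_aic)
from neuroenergetics.ssm_pca import _logistic_fit
from neuroenergetics.synthetic_cohort import _default_pattern


def _split(older_mask, ages=None):
    older = np.asarray(older_mask, dtype=bool)
    if ages is None:
        ages = np.where(older, 70.0, 50.0) + np.linspace(0, 5, older.size)
    return AgeGroupSplit(cutoff=60.0, older=older, ages=np.asarray(ages, float))


class TestSsmResidual:
    def test_additive_structure_gives_zero_residual(self, rng):
        a = rng.standard_normal(6)[:, None]
        b = rng.standard_normal(9)[None, :]
        R = ssm_residual(a + b).matrix
        assert np.abs(R).max() < 1e-12

    def test_row_and_col_means_zero(self, rng):
        R = ssm_residual(rng.standard_normal((7, 11))).matrix
        assert np.abs(R.mean(axis=0)).max() < 1e-10
        assert np.abs(R.mean(axis=1)).max() < 1e-10

    def test_three_by_three_hand_example(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0], [5.0, 5.0, 11.0]])
        # independent arithmetic: R = X - row - col + grand
        row = X.mean(axis=1, keepdims=True)
        col = X.mean(axis=0, keepdims=True)
        expected = X - row - col + X.mean()
        assert np.allclose(ssm_residual(X).matrix, expected, atol=1e-14)

    def test_degenerate_dims_rejected(self):
        with pytest.raises(ValueError):
            ssm_residual(np.ones((1, 5)))

    def test_projection_invariant_to_constant_offsets(self, rng):
        X = rng.standard_normal((8, 13))
        w = rng.standard_normal(13)
        w /= np.linalg.norm(w)
        base = ssm_residual(X).matrix @ w
        shifted = X + rng.standard_normal(8)[:, None] \
            + rng.standard_normal(13)[None, :]
        assert np.allclose(ssm_residual(shifted).matrix @ w, base, atol=1e-9)


class TestPca:
    def test_rank_one_residual(self, rng):
        s = rng.standard_normal(6)
        s -= s.mean()
        w = rng.standard_normal(10)
        w -= w.mean()
        w /= np.linalg.norm(w)
        comps = pca_components(ssm_residual(np.outer(s, w)))
        assert len(comps) == 1
        assert comps[0].vaf == pytest.approx(100.0, abs=1e-9)
        assert abs(comps[0].weights @ w) == pytest.approx(1.0, abs=1e-9)

    def test_scores_mutually_orthogonal(self, rng):
        comps = pca_components(ssm_residual(rng.standard_normal((6, 9))))
        S = np.column_stack([c.scores for c in comps])
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        R = ssm_residual(rng.standard_normal((5, 7)))
        comps = pca_components(R)
        M = R.matrix
        evals, evecs = np.linalg.eigh(M.T @ M)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        total = evals.sum()
        for k, c in enumerate(comps):
            assert c.vaf == pytest.approx(100 * evals[k] / total, abs=1e-8)
            assert abs(abs(c.weights @ evecs[:, k]) - 1.0) < 1e-8
            assert np.allclose(c.scores, M @ c.weights, atol=1e-10)

    def test_vaf_sums_to_hundred(self, rng):
        comps = pca_components(ssm_residual(rng.standard_normal((8, 12))))
        assert sum(c.vaf for c in comps) == pytest.approx(100.0, abs=1e-6)

    def test_non_centered_input_rejected(self):
        from neuroenergetics.ssm_pca import ResidualProfile
        with pytest.raises(ValueError, match="centered"):
            pca_components(ResidualProfile(matrix=np.arange(12.0).reshape(3, 4)))


class TestFilter:
    def _comp(self, scores, vaf, index=0):
        w = np.zeros(5)
        w[index] = 1.0
        return PatternComponent(weights=w, scores=np.asarray(scores, float),
                                vaf=vaf, index=index)

    def test_low_vaf_excluded_regardless_of_separation(self):
        split = _split([True] * 4 + [False] * 4)
        comp = self._comp([5, 5, 5, 5, -5, -5, -5, -5], vaf=4.9)
        assert filter_components([comp], split) == []

    def test_identical_group_distributions_excluded(self):
        split = _split([True, False, True, False])
        comp = self._comp([1.0, 1.0, 2.0, 2.0], vaf=50.0)
        assert filter_components([comp], split) == []

    def test_planted_group_effect_retained_in_most_replicates(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            older = np.arange(12) < 6
            scores = 3.0 * older.astype(float) + rng.standard_normal(12)
            comp = self._comp(scores, vaf=40.0)
            hits += len(filter_components([comp], _split(older))) == 1
        assert hits >= 95


class TestStepwise:
    def test_uncorrelated_component_gives_empty_model(self):
        rng = np.random.default_rng(3)
        older = np.arange(20) % 2 == 0
        comp = PatternComponent(weights=np.ones(4) / 2.0,
                                scores=rng.standard_normal(20), vaf=50.0)
        w, coefs = stepwise_logistic_aic([comp], _split(older))
        assert w is None and coefs == {}

    def test_separating_component_beats_pure_noise(self):
        # the signal component must essentially always enter the model; the
        # pure-noise one should enter only at the chance rate of AIC
        # inclusion for a null predictor, P(chi2_1 > 2) ~ 0.16
        signal_in = noise_in = 0
        for seed in range(100):
            rng = np.random.default_rng(100 + seed)
            older = np.arange(16) < 8
            signal = PatternComponent(
                weights=np.array([1.0, 0.0, 0.0]),
                scores=2.5 * older + rng.standard_normal(16), vaf=40.0, index=0)
            noise = PatternComponent(
                weights=np.array([0.0, 1.0, 0.0]),
                scores=rng.standard_normal(16), vaf=30.0, index=1)
            w, coefs = stepwise_logistic_aic([signal, noise], _split(older))
            signal_in += w is not None and 0 in coefs
            noise_in += w is not None and 1 in coefs
        assert signal_in >= 95
        assert noise_in <= 30

    def test_combined_weights_unit_norm(self, rng):
        older = np.arange(14) < 7
        comps = [PatternComponent(weights=rng.standard_normal(6),
                                  scores=(3.0 * older
                                          + rng.standard_normal(14)),
                                  vaf=50.0 - 10 * i, index=i)
                 for i in range(2)]
        w, _ = stepwise_logistic_aic(comps, _split(older))
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-12)

    def test_logistic_fit_matches_statsmodels_on_separable_free_data(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(200), rng.standard_normal(200)])
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.5 + 0.8 * X[:, 1])))
             ).astype(float)
        beta, ll = _logistic_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert ll == pytest.approx(ref.llf, abs=1e-8)

    def test_survives_perfect_separation(self):
        older = np.arange(10) < 5
        comp = PatternComponent(weights=np.array([1.0, 0.0]),
                                scores=np.where(older, 5.0, -5.0), vaf=60.0)
        w, coefs = stepwise_logistic_aic([comp], _split(older))
        assert w is not None and np.all(np.isfinite(w))


class TestSeparationAndAge:
    def test_equal_means_zero_d(self):
        split = _split([True, True, False, False])
        _, _, d = separation_stats(np.array([1.0, 2.0, 1.0, 2.0]), split)
        assert d == 0.0

    def test_toy_groups_d_three(self):
        split = _split([False, False, False, True, True, True])
        t, p, d = separation_stats(np.array([1.0, 2, 3, 4, 5, 6]), split)
        assert d == pytest.approx(3.0)
        # cross-check t/p with scipy directly
        t_ref, p_ref = stats.ttest_ind([4.0, 5, 6], [1.0, 2, 3])
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_scores_equal_ages_r2_one(self):
        ages = np.array([40.0, 50.0, 62.0, 71.0])
        r2, p = age_relationship(ages, ages)
        assert r2 == pytest.approx(1.0)

    def test_constant_scores_flagged(self):
        r2, p = age_relationship(np.ones(5), np.arange(5.0))
        assert np.isnan(r2) and np.isnan(p)

    def test_permutation_null_p_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(35, 80, 24)
        ps = []
        for _ in range(200):
            _, p = age_relationship(rng.standard_normal(24), ages)
            ps.append(p)
        frac = np.mean(np.asarray(ps) < 0.05)
        assert 0.0 <= frac <= 0.11      # binomial fluctuation around 0.05


class TestCrossValidation:
    def test_noiseless_planted_pattern_stable_and_recovered(self):
        cfg = CohortConfig(n_subjects=16, n_regions=25, noise_sd=0.0,
                           global_scale_sd=0.0, seed=21)
        ds = generate_regional_cohort(cfg)
        table = build_energetics_table(ds)
        split = AgeGroupSplit.from_ages(ds.ages)
        pat = crossvalidate_pattern(table.rep, split, n_iter=10, seed=0)
        planted = _default_pattern(cfg.n_regions, cfg.seed)
        planted = planted - planted.mean()
        planted /= np.linalg.norm(planted)
        assert pat.weight_sd.max() < 0.02
        assert abs(pat.weights @ planted) > 0.95

    def test_same_seed_identical_pattern(self, small_energetics):
        _, table, split = small_energetics
        a = crossvalidate_pattern(table.rep, split, n_iter=5, seed=3)
        b = crossvalidate_pattern(table.rep, split, n_iter=5, seed=3)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.scores, b.scores)
        assert a.components_used == b.components_used

    def test_recovery_at_default_noise(self):
        cfg = CohortConfig(seed=2)
        ds = generate_regional_cohort(cfg)
        table = build_energetics_table(ds)
        split = AgeGroupSplit.from_ages(ds.ages)
        pat = crossvalidate_pattern(table.rep, split, n_iter=20, seed=2)
        planted = _default_pattern(cfg.n_regions, cfg.seed)
        planted = planted - planted.mean()
        planted /= np.linalg.norm(planted)
        assert abs(pat.weights @ planted) >= 0.9
        assert pat.age_r2 > 0.8
        # scores are oriented to increase with age
        assert np.corrcoef(pat.scores, ds.ages)[0, 1] > 0

    def test_region_exclusion_barely_moves_age_fit(self):
        cfg = CohortConfig(seed=6)
        ds = generate_regional_cohort(cfg)
        table = build_energetics_table(ds)
        split = AgeGroupSplit.from_ages(ds.ages)
        full = crossvalidate_pattern(table.rep, split, n_iter=20, seed=1)
        planted = np.abs(_default_pattern(cfg.n_regions, cfg.seed))
        drop = np.argsort(planted)[:2]          # two low-weight regions
        keep = np.setdiff1d(np.arange(cfg.n_regions), drop)
        reduced = crossvalidate_pattern(table.rep[:, keep], split,
                                        n_iter=20, seed=1)
        assert abs(full.age_r2 - reduced.age_r2) < 0.05


class TestDisplayAndTrends:
    def _pattern(self, w, sd):
        w = np.asarray(w, float)
        n = w.size
        return CovariancePattern(
            metric="rep", region_names=[f"r{i}" for i in range(n)],
            weights=w, weight_sd=np.asarray(sd, float), scores=np.zeros(4),
            subject_ids=list("abcd"), separation_t=0.0, separation_p=1.0,
            cohens_d=0.0, age_r2=0.0, age_p=1.0)

    def test_display_mask_threshold_logic(self):
        # weights standardized to SD 1 across regions before masking
        w = [1.5, -1.5, 0.1, -0.1]
        scale = np.std(w, ddof=1)
        pat = self._pattern(w, [0.0, 0.6 * scale, 0.0, 0.0])
        shown = display_mask(pat, threshold=1.0)
        assert "r0" in shown            # 1.5/scale - 0 > 1
        assert "r1" not in shown        # 1.5/scale - 0.6/scale < 1... depends
        assert "r2" not in shown

    def test_display_mask_symmetric_pattern(self):
        pat = self._pattern([2.0, -2.0, 0.1, -0.1], [0.0] * 4)
        shown = display_mask(pat)
        assert set(shown) == {"r0", "r1"}

    def test_bilateral_partner_included(self):
        pat = self._pattern([2.0, 0.0, 0.1, -0.1], [0.0] * 4)
        shown = display_mask(pat, laterality={"r0": "r1", "r1": "r0"})
        assert "r1" in shown

    def test_posthoc_trends_recover_planted_direction(self):
        cfg = CohortConfig(n_subjects=20, n_regions=20, noise_sd=0.05,
                           pattern_mode="concordant", seed=12)
        ds = generate_regional_cohort(cfg)
        table = build_energetics_table(ds)
        planted = _default_pattern(cfg.n_regions, cfg.seed)
        region = table.region_names[int(np.argmax(np.abs(planted)))]
        trends = posthoc_region_trends(ds, table, region)
        # concordant plant: both modalities move together with age
        assert np.sign(trends["z_cmrglu"]) == np.sign(trends["z_cbf"])
        assert abs(trends["rep"]) > 0.5

    def test_trend_covariances_combine_linearly(self, small_energetics):
        ds, table, _ = small_energetics
        j = 3
        cov = lambda v: np.cov(v, ds.ages, ddof=1)[0, 1]
        lhs = cov(table.rep[:, j])
        rhs = (cov(table.z_cbf[:, j]) + cov(table.z_cmrglu[:, j])) / np.sqrt(2)
        assert lhs == pytest.approx(rhs, abs=1e-10)
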