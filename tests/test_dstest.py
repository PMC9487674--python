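import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

import dsbench as d
from dsbench import dstest, normagg
from dsbench.dstest import (
    estimate_prior_df,
    fit_random_intercept,
    _rots_stat,
    _topk_overlap,
)
from dsbench.simgen import ValidationError


def _groups(na, nb):
    return np.array(["A"] * na + ["B"] * nb, dtype=object)


def _pb(values, conditions):
    values = np.asarray(values, dtype=float)
    samples = [f"s{j + 1}" for j in range(values.shape[1])]
    return normagg.PseudobulkMatrix(
        values=values,
        gene_ids=[f"g{i + 1}" for i in range(values.shape[0])],
        sample_ids=samples,
        sample_to_condition=dict(zip(samples, conditions)),
        aggregation="sum",
    )


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (3, 1))
        res = d.wilcoxon_test(vals, _groups(3, 3))
        assert np.allclose(res.p_value, 1.0)

    def test_complete_separation_exact(self):
        # 3 vs 3 complete separation: 2 of C(6,3)=20 assignments are as
        # extreme -> two-sided p = 0.1
        vals = np.array([[1.0, 2.0, 3.0, 10.0, 11.0, 12.0]])
        res = d.wilcoxon_test(vals, _groups(3, 3))
        assert res.p_value[0] == pytest.approx(0.1)

    def test_matches_permutation_oracle_20_cells(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 10)
        y = rng.normal(0.9, 1, 10)
        vals = np.concatenate([x, y])[None, :]
        res = d.wilcoxon_test(vals, _groups(10, 10))
        # Monte-Carlo permutation of the rank-sum statistic
        ranks = stats.rankdata(vals[0])
        obs = abs(ranks[:10].sum() - ranks.sum() / 2)
        count = 0
        n_draws = 100_000
        for _ in range(n_draws):
            perm = rng.permutation(ranks)
            if abs(perm[:10].sum() - ranks.sum() / 2) >= obs - 1e-9:
                count += 1
        assert res.p_value[0] == pytest.approx(count / n_draws, abs=0.01)

    def test_asymptotic_path_with_ties(self):
        rng = np.random.default_rng(3)
        vals = rng.poisson(2, size=(50, 60)).astype(float)
        res = d.wilcoxon_test(vals, _groups(30, 30))
        assert ((res.p_value >= 0) & (res.p_value <= 1)).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            d.wilcoxon_test(np.zeros((1, 3)), np.array(["A", "A", "A"]))


class TestLogisticRegression:
    def test_constant_gene_p_one(self):
        vals = np.full((1, 20), 2.0)
        res = d.lr_test(vals, _groups(10, 10))
        assert res.p_value[0] == pytest.approx(1.0, abs=1e-6)

    def test_latent_encoding_groups_gives_p_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(5, 20))
        latent = np.array([[1.0]] * 10 + [[0.0]] * 10)
        res = d.lr_test(vals, _groups(10, 10), latent=latent)
        assert np.allclose(res.p_value, 1.0)

    def test_deviance_matches_independent_maximization(self):
        # 12-cell toy: compare the LRT statistic against direct numerical
        # maximization of both binomial likelihoods
        rng = np.random.default_rng(5)
        x = np.r_[rng.normal(0, 1, 6), rng.normal(1.0, 1, 6)]
        y = np.r_[np.zeros(6), np.ones(6)]
        res = d.lr_test(x[None, :], _groups(6, 6))

        def nll(beta, X):
            eta = X @ beta
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        X_full = np.column_stack([np.ones(12), x])
        X_null = np.ones((12, 1))
        ll_full = -minimize(nll, np.zeros(2), args=(X_full,), method="BFGS").fun
        ll_null = -minimize(nll, np.zeros(1), args=(X_null,), method="BFGS").fun
        stat_oracle = 2 * (ll_full - ll_null)
        stat_ours = stats.chi2.isf(res.p_value[0], 1)
        assert stat_ours == pytest.approx(stat_oracle, abs=1e-6)


class TestPoissonGLM:
    def test_equal_means_equal_depths(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(5, size=(30, 80))
        res = d.poisson_glm_test(counts, _groups(40, 40))
        # p-values are approximately uniform: no systematic rejection
        assert np.nanmedian(res.p_value) > 0.2

    def test_closed_form_deviance_two_cells_per_group(self):
        # single gene, equal library sizes: Poisson MLEs are group means;
        # deviance difference has a closed form
        counts = np.array([[4, 6, 10, 12], [10, 10, 10, 10]])
        res = d.poisson_glm_test(counts, _groups(2, 2))
        y = counts[0].astype(float)
        lib = counts.sum(axis=0).astype(float)
        # with unequal library sizes the MLE rates are sum(y)/sum(lib)
        rate_all = y.sum() / lib.sum()
        rate_a = y[:2].sum() / lib[:2].sum()
        rate_b = y[2:].sum() / lib[2:].sum()

        def ll(rates):
            mu = rates * lib
            return np.sum(y * np.log(mu) - mu)

        stat = 2 * (ll(np.r_[rate_a, rate_a, rate_b, rate_b]) -
                    ll(np.full(4, rate_all)))
        assert stats.chi2.isf(res.p_value[0], 1) == pytest.approx(stat, abs=1e-9)

    def test_offset_invariance(self):
        # doubling the other genes doubles library sizes; the tested gene's
        # p-value is unchanged because the offset absorbs depth
        rng = np.random.default_rng(7)
        gene = rng.poisson(4, 40)
        rest = rng.poisson(3, size=(20, 40))
        c1 = np.vstack([gene, rest])
        c2 = np.vstack([gene, rest * 2])
        # make library sizes exactly double
        assert np.allclose(c2.sum(0), 2 * c1.sum(0) - gene)
        g = _groups(20, 20)
        p1 = d.poisson_glm_test(c1, g).p_value[0]
        lib1 = c1.sum(axis=0)
        # direct check: fit with offset log(lib) vs log(2*lib)
        import statsmodels.api as sm
        X = np.column_stack([np.ones(40), (np.arange(40) >= 20).astype(float)])
        f1 = sm.GLM(gene, X, family=sm.families.Poisson(),
                    offset=np.log(lib1)).fit()
        f2 = sm.GLM(gene, X, family=sm.families.Poisson(),
                    offset=np.log(2.0 * lib1)).fit()
        assert f1.params[1] == pytest.approx(f2.params[1], abs=1e-9)
        assert 0 <= p1 <= 1


class TestNegbinomGLM:
    def test_equidispersed_agrees_with_poisson(self):
        rng = np.random.default_rng(8)
        counts = np.vstack([
            rng.poisson(6, 100),
            rng.poisson(4, 100),
            rng.poisson(8, 100),
        ])
        g = _groups(50, 50)
        p_nb = d.negbinom_glm_test(counts, g).p_value
        p_po = d.poisson_glm_test(counts, g).p_value
        assert np.nanmax(np.abs(p_nb - p_po)) < 0.01

    def test_equal_groups_large_p(self):
        rng = np.random.default_rng(9)
        lam = rng.gamma(2.0, 2.5, size=200)  # NB via gamma-Poisson
        counts = np.vstack([rng.poisson(lam), rng.poisson(5, 200)])
        res = d.negbinom_glm_test(counts, _groups(100, 100))
        assert res.p_value[0] > 0.05

    def test_dispersion_recovery(self):
        rng = np.random.default_rng(10)
        phi = 0.5
        n = 2000
        mu = 5.0
        lam = rng.gamma(1 / phi, phi * mu, size=n)
        gene = rng.poisson(lam)
        # near-constant depth so the offset does not distort the NB law
        counts = np.vstack([gene, np.full(n, 1000)])
        res = d.negbinom_glm_test(counts, _groups(n // 2, n // 2))
        alpha = res.metadata["dispersions"][0]
        assert 0.5 * phi <= alpha <= 1.5 * phi


class TestHurdle:
    def test_identical_groups_p_near_one(self):
        block = np.array([0.0, 0.0, 1.2, 2.0, 0.7, 0.0, 1.5, 0.3])
        vals = np.tile(np.r_[block, block], (3, 1))
        res = d.hurdle_test(vals, _groups(8, 8))
        assert (res.p_value > 0.9).all()

    def test_detection_only_difference_loads_discrete_part(self):
        # same positive values in both groups, very different detection
        rng = np.random.default_rng(11)
        pos = np.abs(rng.normal(2, 0.1, 200))
        a = pos.copy()
        b = pos.copy()
        b[rng.random(200) < 0.8] = 0.0  # group B mostly undetected
        vals = np.r_[a, b][None, :]
        res = d.hurdle_test(vals, _groups(200, 200))
        chi2_d, chi2_c = res.metadata["chi2_parts"][0]
        assert chi2_d > 50
        assert chi2_c < chi2_d / 10

    def test_combined_statistic_is_sum_of_parts(self):
        rng = np.random.default_rng(12)
        vals = np.maximum(rng.normal(0.5, 1, size=(20, 60)), 0)
        res = d.hurdle_test(vals, _groups(30, 30))
        parts = res.metadata["chi2_parts"]
        dfs = res.metadata["df_parts"]
        ok = ~np.isnan(res.p_value)
        expect = stats.chi2.sf(parts[ok].sum(axis=1), dfs[ok].sum(axis=1))
        assert np.allclose(res.p_value[ok], expect)

    def test_all_zero_gene_missing(self):
        vals = np.zeros((1, 10))
        res = d.hurdle_test(vals, _groups(5, 5))
        assert np.isnan(res.p_value[0])


class TestLMM:
    def _sim(self, rng, n_subj=10, cells=20, subj_sd=1.0, resid_sd=1.0, shift=0.0):
        subjects = np.repeat([f"p{i}" for i in range(n_subj)], cells)
        cond = np.repeat(["A"] * (n_subj // 2) + ["B"] * (n_subj // 2), cells)
        b = rng.normal(0, subj_sd, n_subj)
        y = (np.repeat(b, cells) + rng.normal(0, resid_sd, n_subj * cells)
             + shift * (cond == "B"))
        return y, cond, subjects

    def test_degenerate_limit_matches_ols_t_test(self):
        rng = np.random.default_rng(13)
        y, cond, subjects = self._sim(rng, n_subj=10, cells=20,
                                      subj_sd=0.0, shift=0.3)
        res = d.lmm_random_intercept_test(y[None, :], cond, subjects)
        t = stats.ttest_ind(y[cond == "A"], y[cond == "B"], equal_var=True)
        assert res.p_value[0] == pytest.approx(t.pvalue, abs=0.02)

    def test_identical_groups_large_p(self):
        y = np.tile(np.arange(20.0), 10)
        subjects = np.repeat([f"p{i}" for i in range(10)], 20)
        cond = np.repeat(["A"] * 5 + ["B"] * 5, 20)
        res = d.lmm_random_intercept_test(y[None, :], cond, subjects)
        assert res.p_value[0] > 0.9

    def test_variance_ratio_recovery(self):
        # subject variance 1, residual 1: REML ratio within factor 2 in
        # >= 90% of 100 replicates at 10 subjects per group x 50 cells
        rng = np.random.default_rng(14)
        ok = 0
        for _ in range(100):
            y, cond, subjects = self._sim(rng, n_subj=20, cells=50,
                                          subj_sd=1.0, resid_sd=1.0)
            fit = fit_random_intercept(y, cond, subjects, reml=True)
            ratio = fit["sigma2_subject"] / fit["sigma2_resid"]
            if 0.5 <= ratio <= 2.0:
                ok += 1
        assert ok >= 90

    def test_agrees_with_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(15)
        y, cond, subjects = self._sim(rng, n_subj=8, cells=15,
                                      subj_sd=0.8, shift=0.5)
        fit = fit_random_intercept(y, cond, subjects, reml=True)
        X = np.column_stack([np.ones(len(y)), (cond == "B").astype(float)])
        m = sm.MixedLM(y, X, groups=subjects).fit(reml=True)
        params = np.asarray(m.params)
        assert fit["condition_effect"] == pytest.approx(params[1], abs=1e-4)
        assert fit["sigma2_subject"] == pytest.approx(
            float(np.asarray(m.cov_re)[0, 0]), rel=1e-3, abs=1e-4)
        assert fit["sigma2_resid"] == pytest.approx(m.scale, rel=1e-3)

    def test_subject_spanning_conditions_rejected(self):
        y = np.arange(8.0)
        cond = np.array(["A", "A", "B", "B"] * 2)
        subjects = np.array(["p1", "p1", "p1", "p1", "p2", "p2", "p2", "p2"])
        with pytest.raises(ValidationError):
            d.lmm_random_intercept_test(y[None, :], cond, subjects)


class TestModeratedT:
    def test_no_shrinkage_limit_is_ordinary_t(self):
        rng = np.random.default_rng(16)
        pb = _pb(rng.normal(5, 1, size=(40, 8)), ["A"] * 4 + ["B"] * 4)
        pb.aggregation = "mean"  # values used as-is
        res = d.pb_moderated_t(pb, d0_override=0.0)
        v = pb.values
        t = stats.ttest_ind(v[:, 4:], v[:, :4], axis=1, equal_var=True)
        assert np.allclose(res.p_value, t.pvalue, atol=1e-12)

    def test_full_shrinkage_limit_uses_common_variance(self):
        rng = np.random.default_rng(17)
        pb = _pb(rng.normal(5, 1, size=(40, 8)), ["A"] * 4 + ["B"] * 4)
        pb.aggregation = "mean"
        s0sq = 2.0
        res = d.pb_moderated_t(pb, d0_override=np.inf, s0sq_override=s0sq)
        v = pb.values
        diff = v[:, 4:].mean(1) - v[:, :4].mean(1)
        z = diff / np.sqrt(s0sq * (1 / 4 + 1 / 4))
        assert np.allclose(res.p_value, 2 * stats.norm.sf(np.abs(z)), atol=1e-12)

    def test_matches_direct_shrinkage_formula(self):
        # 50-gene toy with heterogeneous gene variances (so the prior df is
        # finite): recompute the moderated t from the fitted prior
        rng = np.random.default_rng(18)
        sds = rng.lognormal(0.0, 0.8, size=50)
        pb = _pb(rng.normal(3, 1.0, size=(50, 10)) * sds[:, None],
                 ["A"] * 5 + ["B"] * 5)
        pb.aggregation = "mean"
        res = d.pb_moderated_t(pb)
        d0, s0sq = res.metadata["d0"], res.metadata["s0sq"]
        v = pb.values
        ma, mb = v[:, :5].mean(1), v[:, 5:].mean(1)
        dg = 8
        s2 = (((v[:, :5] - ma[:, None]) ** 2).sum(1)
              + ((v[:, 5:] - mb[:, None]) ** 2).sum(1)) / dg
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
        t = (mb - ma) / np.sqrt(s2_post * (1 / 5 + 1 / 5))
        p = 2 * stats.t.sf(np.abs(t), dg + d0)
        assert np.allclose(res.p_value, p, atol=1e-9)

    def test_prior_df_estimation_sane(self):
        rng = np.random.default_rng(19)
        df = 6
        true_s2 = 1.3
        s2 = true_s2 * rng.chisquare(df, 3000) / df
        d0, s0sq = estimate_prior_df(s2, df)
        # variances drawn from one common value: strong shrinkage
        assert d0 > 20
        assert s0sq == pytest.approx(true_s2, rel=0.1)

    def test_too_few_samples_rejected(self):
        pb = _pb(np.ones((3, 2)), ["A", "B"])
        with pytest.raises(ValidationError):
            d.pb_moderated_t(pb)


class TestPseudobulkNB:
    def test_equal_groups_large_p(self):
        rng = np.random.default_rng(20)
        pb = _pb(rng.poisson(50, size=(60, 12)), ["A"] * 6 + ["B"] * 6)
        res = d.pb_nbglm(pb, norm="tmm")
        assert np.nanmedian(res.p_value) > 0.2

    def test_zero_dispersion_matches_poisson_wald(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(21)
        values = rng.poisson(40, size=(20, 8)).astype(float)
        pb = _pb(values, ["A"] * 4 + ["B"] * 4)
        res = d.pb_nbglm(pb, norm="tmm", fixed_dispersion=0.0)
        offset = np.log(pb.library_sizes() * normagg.tmm_factors(pb))
        X = np.column_stack([np.ones(8), np.r_[np.zeros(4), np.ones(4)]])
        for g in range(20):
            fit = sm.GLM(values[g], X, family=sm.families.Poisson(),
                         offset=offset).fit()
            p = 2 * stats.norm.sf(abs(fit.params[1] / fit.bse[1]))
            assert res.p_value[g] == pytest.approx(p, abs=1e-6)

    def test_wald_matches_independent_likelihood_maximization(self):
        rng = np.random.default_rng(22)
        values = rng.poisson(30, size=(5, 12)).astype(float)
        values[0, 6:] = values[0, 6:] * 2
        pb = _pb(values, ["A"] * 6 + ["B"] * 6)
        alpha = 0.1
        res = d.pb_nbglm(pb, norm="tmm", fixed_dispersion=alpha)
        offset = np.log(pb.library_sizes() * normagg.tmm_factors(pb))
        X = np.column_stack([np.ones(12), np.r_[np.zeros(6), np.ones(6)]])
        y = values[0]

        def nll(beta):
            mu = np.exp(X @ beta + offset)
            r = 1 / alpha
            return -np.sum(stats.nbinom.logpmf(y, r, r / (r + mu)))

        opt = minimize(nll, np.zeros(2), method="BFGS")
        assert res.effect[0] * np.log(2) == pytest.approx(opt.x[1], abs=1e-4)

    def test_all_zero_gene_missing(self):
        rng = np.random.default_rng(23)
        values = rng.poisson(30, size=(10, 8)).astype(float)
        values[3] = 0
        pb = _pb(values, ["A"] * 4 + ["B"] * 4)
        res = d.pb_nbglm(pb, norm="tmm")
        assert np.isnan(res.p_value[3])
        assert np.isnan(res.p_value).sum() == 1


class TestROTS:
    def test_a2_only_matches_t_statistic_ranking(self):
        rng = np.random.default_rng(24)
        v = rng.normal(0, 1, size=(50, 10))
        mask_a = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        dstat = _rots_stat(v, mask_a, ~mask_a, 0.0, 1.0)
        t = np.abs(stats.ttest_ind(v[:, ~mask_a], v[:, mask_a],
                                   axis=1, equal_var=True).statistic)
        assert np.array_equal(np.argsort(-dstat), np.argsort(-t))

    def test_a1_only_matches_mean_difference_ranking(self):
        rng = np.random.default_rng(25)
        v = rng.normal(0, 1, size=(50, 10))
        mask_a = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        dstat = _rots_stat(v, mask_a, ~mask_a, 1.0, 0.0)
        diff = np.abs(v[:, ~mask_a].mean(1) - v[:, mask_a].mean(1))
        assert np.array_equal(np.argsort(-dstat), np.argsort(-diff))

    def test_topk_overlap_brute_force(self):
        rng = np.random.default_rng(26)
        for _ in range(20):
            d1, d2 = rng.normal(size=(2, 20))
            k = int(rng.integers(1, 10))
            got = _topk_overlap(d1, d2, k)
            top1 = set(np.argsort(-d1)[:k])
            top2 = set(np.argsort(-d2)[:k])
            assert got == len(top1 & top2) / k

    def test_deterministic_and_detects_signal(self):
        rng = np.random.default_rng(27)
        v = rng.normal(0, 1, size=(60, 12))
        v[:6, 6:] += 3.0  # strong signal in 6 genes
        pb1 = _pb(v, ["A"] * 6 + ["B"] * 6)
        pb1.aggregation = "mean"
        r1 = d.pb_rots(pb1, n_bootstrap=50, seed=5)
        r2 = d.pb_rots(pb1, n_bootstrap=50, seed=5)
        assert np.array_equal(r1.p_value, r2.p_value)
        assert (np.argsort(r1.p_value)[:6] < 6).mean() >= 0.8

    def test_small_groups_rejected(self):
        pb = _pb(np.ones((5, 4)), ["A", "A", "B", "B"])
        with pytest.raises(ValidationError):
            d.pb_rots(pb)


class TestCrossCuttingProperties:
    FAST_METHODS = ["wilcoxon", "hurdle", "pb_modt_sum", "pb_modt_mean",
                    "pb_nbglm_tmm", "lmm"]

    @pytest.mark.parametrize("method", FAST_METHODS)
    def test_p_values_valid_and_label_symmetric(self, small_dataset, method):
        data, _ = small_dataset
        res = d.run_method(data, method, seed=1)
        ok = ~np.isnan(res.p_value)
        assert ok.any()
        assert (res.p_value[ok] >= 0).all() and (res.p_value[ok] <= 1).all()
        # swap condition labels: two-sided tests are invariant
        swapped = d.CellCountMatrix(
            counts=data.counts, gene_ids=data.gene_ids, cell_ids=data.cell_ids,
            cell_to_sample=data.cell_to_sample,
            sample_to_condition={
                s: ("B" if c == "A" else "A")
                for s, c in data.sample_to_condition.items()
            },
        )
        res2 = d.run_method(swapped, method, seed=1)
        assert np.allclose(res.p_value[ok], res2.p_value[ok],
                           atol=1e-8, equal_nan=True)

    @pytest.mark.parametrize("method", ["wilcoxon", "hurdle"])
    def test_type_one_error_on_iid_null(self, null_iid_dataset, method):
        res = d.run_method(null_iid_dataset, method, seed=2)
        ok = ~np.isnan(res.p_value)
        rate = float(np.mean(res.p_value[ok] < 0.05))
        assert 0.03 <= rate <= 0.07

    def test_glm_type_one_error_on_iid_null_small(self):
        # smaller gene panel for the per-gene GLM tests
        cfg = d.SimConfig(n_samples_total=10, avg_cells_per_sample=25,
                          n_genes=2000, n_de_genes=0,
                          cell_overdispersion=0.2, sample_overdispersion=1e6,
                          baseline_log_mean_range=(-1.0, 1.5), seed=31)
        data, _ = d.simulate_dataset(cfg)
        res = d.run_method(data, "lr", seed=3)
        ok = ~np.isnan(res.p_value)
        rate = float(np.mean(res.p_value[ok] < 0.05))
        assert 0.03 <= rate <= 0.07

    def test_pseudoreplication_inflates_naive_but_not_pseudobulk(
        self, null_hier_dataset
    ):
        wil = d.run_method(null_hier_dataset, "wilcoxon", seed=4)
        modt = d.run_method(null_hier_dataset, "pb_modt_sum", seed=4)
        r_wil = float(np.nanmean(wil.p_value < 0.05))
        r_modt = float(np.nanmean(modt.p_value < 0.05))
        assert r_wil > 0.10
        assert 0.02 <= r_modt <= 0.08

    def test_latent_variants_return_valid_probabilities(self, small_dataset):
        data, _ = small_dataset
        for m in ("lr_latent", "hurdle_latent", "poisson_latent"):
            res = d.run_method(data, m, seed=5)
            ok = ~np.isnan(res.p_value)
            assert (res.p_value[ok] >= 0).all() and (res.p_value[ok] <= 1).all()

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            d.run_method(small_dataset[0], "no_such_method")
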