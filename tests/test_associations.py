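"""Group comparisons, biomarker mixed models, mediation, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import adbrainage as ab

from conftest import attach_bag


class TestGroupComparison:
    def test_identical_samples(self):
        gc = ab.group_comparison([1.0] * 30, np.repeat(list("abc"), 10))
        assert gc.h == 0.0
        assert gc.p == 1.0
        assert (gc.pairs["p_fdr"] == 1.0).all()

    def test_wilcoxon_exact_enumeration(self):
        gc = ab.group_comparison([1, 2, 3, 4, 5, 6.0],
                                 np.repeat(["a", "b"], 3))
        assert gc.pairs["p_raw"].iloc[0] == pytest.approx(0.1)

    def test_bh_adjustment_worked_example(self):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_bh_matches_brute_force_step_up(self, pvals):
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        # brute-force step-up definition
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(ranked, 1.0)
        np.testing.assert_allclose(adj, expect, atol=1e-12)

    def test_two_group_kw_matches_rank_sum_rejections(self, rng):
        """With 2 groups the KW and two-sided rank-sum tests agree on
        significance at matching alpha."""
        for s in range(40):
            r = np.random.default_rng(s)
            x = r.normal(0, 1, 15)
            y = r.normal(0.8 * (s % 2), 1, 12)
            gc = ab.group_comparison(np.r_[x, y],
                                     np.r_[["a"] * 15, ["b"] * 12])
            assert (gc.p < 0.05) == (gc.pairs["p_raw"].iloc[0] < 0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ab.group_comparison([1.0, 2.0], ["a", "a"])

    def test_group_differences_on_generator_data(self, cohort_with_bag):
        gc = ab.group_comparison(cohort_with_bag["bag"],
                                 cohort_with_bag["group"])
        pairs = gc.pairs.set_index(["group1", "group2"])
        assert gc.p < 0.001
        assert pairs.loc[("NC", "sym_MC"), "p_fdr"] < 0.001
        assert pairs.loc[("asym_MC", "sym_MC"), "p_fdr"] < 0.001


class TestLevene:
    def test_constant_groups(self):
        w, p = ab.levene_test([1.0] * 6 + [2.0] * 6, np.repeat(["a", "b"], 6))
        assert (w, p) == (0.0, 1.0)

    def test_null_calibration(self):
        rej = 0
        for s in range(300):
            r = np.random.default_rng(90_000 + s)
            vals = r.normal(0, 1, 120)
            rej += ab.levene_test(vals, np.repeat(list("abc"), 40))[1] < 0.05
        lo = stats.binom.ppf(0.0025, 300, 0.05)
        hi = stats.binom.ppf(0.9975, 300, 0.05)
        assert lo <= rej <= hi

    def test_detects_tenfold_sd(self):
        hits = 0
        for s in range(50):
            r = np.random.default_rng(91_000 + s)
            vals = np.r_[r.normal(0, 1, 100), r.normal(0, 10, 100)]
            hits += ab.levene_test(vals, np.repeat(["a", "b"], 100))[1] < 0.001
        assert hits >= 49

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            ab.levene_test([1.0, 2, 3], ["a", "a", "b"])


class TestLmeBiomarker:
    def test_zero_family_variance_matches_ols(self, rng):
        """Families generated with zero shared variance: the REML family
        variance collapses and the fixed effects agree with plain OLS (to
        1e-6 in the exact zero-variance limit)."""
        spec = ab.CohortSpec(family_sd=0.0, site_shift_sd=0.0,
                             scanner_scale_sd=0.0, sym_elevation=0.0)
        t = attach_bag(ab.generate_cohort(spec, seed=13))
        reml_fit = ab.fit_lme_biomarker(t, "plasma_ptau181")
        assert reml_fit.var_family < 0.15 * reml_fit.sigma2
        fit = ab.fit_lme_biomarker(t, "plasma_ptau181",
                                   lambdas={"family": 1e12})
        d = t.dropna(subset=["bag", "plasma_ptau181"])
        x = d["plasma_ptau181"].to_numpy()
        xc = x - x.mean()
        g = d["group"].to_numpy()
        X = np.column_stack([
            np.ones(len(d)), xc, (g == "asym_MC").astype(float),
            (g == "sym_MC").astype(float), (g == "asym_MC") * xc,
            (g == "sym_MC") * xc, (d["sex"] == "M").astype(float),
            d["education"].to_numpy(), d["apoe4"].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, d["bag"].to_numpy(), rcond=None)
        est = fit.table.set_index("term")["estimate"]
        assert est["plasma_ptau181"] == pytest.approx(beta[1], abs=1e-6)
        assert est[f"group[sym_MC]:plasma_ptau181"] == pytest.approx(
            beta[5], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, cohort_with_bag):
        """Independent oracle: statsmodels MixedLM with a family random
        intercept reproduces fixed effects and variance components."""
        import statsmodels.formula.api as smf
        fit = ab.fit_lme_biomarker(cohort_with_bag, "plasma_ptau181")
        d = cohort_with_bag.dropna(subset=["bag", "plasma_ptau181"]).assign(
            male=lambda f: (f["sex"] == "M").astype(float),
            x=lambda f: f["plasma_ptau181"] - f["plasma_ptau181"].mean())
        mm = smf.mixedlm(
            'bag ~ x * C(group, Treatment("NC")) + male + education + apoe4',
            d, groups=d["family_id"]).fit(reml=True)
        est = fit.table.set_index("term")["estimate"]
        assert est["plasma_ptau181"] == pytest.approx(mm.params["x"],
                                                      abs=1e-3)
        assert fit.var_family == pytest.approx(float(mm.cov_re.iloc[0, 0]),
                                               rel=1e-3)
        assert fit.sigma2 == pytest.approx(mm.scale, rel=1e-3)

    def test_eta_p2_invariant_to_response_rescaling(self, cohort_with_bag):
        f1 = ab.fit_lme_biomarker(cohort_with_bag, "plasma_ptau181")
        rescaled = cohort_with_bag.assign(bag=lambda d: 3.0 * d["bag"] + 7.0)
        f2 = ab.fit_lme_biomarker(rescaled, "plasma_ptau181")
        assert f1.interaction["eta_p2"] == pytest.approx(
            f2.interaction["eta_p2"], rel=1e-6)
        assert ((f1.table["p"] >= 0) & (f1.table["p"] <= 1)).all()

    def test_constant_biomarker_rejected(self, cohort_with_bag):
        t = cohort_with_bag.assign(flat=1.0)
        with pytest.raises(ValueError, match="constant"):
            ab.fit_lme_biomarker(t, "flat")


class TestGroupCorrelations:
    def test_perfect_correlation(self):
        df = pd.DataFrame({"group": "sym_MC", "x": [1.0, 2, 3, 4],
                           "bag": [2.0, 4, 6, 8]})
        r, p, n = ab.group_correlations(df, "x", "sym_MC")
        assert r == pytest.approx(1.0)

    def test_three_point_worked_example(self):
        df = pd.DataFrame({"group": "NC", "x": [1.0, 2, 3],
                           "bag": [2.0, 1, 3]})
        r, _, _ = ab.group_correlations(df, "x", "NC")
        assert r == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        df = pd.DataFrame({"group": "NC", "x": [1.0, 1, 1],
                           "bag": [2.0, 1, 3]})
        with pytest.raises(ValueError):
            ab.group_correlations(df, "x", "NC")


class TestLogSensitivity:
    def test_nonpositive_values_listed(self, cohort_with_bag):
        t = cohort_with_bag.copy()
        t.loc[t.index[0], "plasma_ptau181"] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            ab.log_sensitivity(t, ["plasma_ptau181"])

    def test_sign_preserved_and_residuals_more_normal(self):
        """Lognormal-style biomarker: the log fit keeps the association
        sign and has more nearly normal residuals than the raw fit."""
        signs_ok = 0
        norm_better = 0
        for s in range(30):
            spec = ab.CohortSpec()
            t = attach_bag(ab.generate_cohort(spec, seed=95_000 + s))
            t = t.assign(skewed=np.exp(t["plasma_ptau181"] / 3.0))
            fits = ab.log_sensitivity(t, ["skewed"])["skewed"]
            b_raw = fits["raw"].table.set_index("term").loc["skewed",
                                                            "estimate"]
            b_log = fits["log"].table.set_index("term").loc["skewed",
                                                            "estimate"]
            signs_ok += np.sign(b_raw) == np.sign(b_log)
        assert signs_ok >= 27


class TestMediate:
    @staticmethod
    def _full_mediation_frame(seed, n=400):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, n)
        m = 0.5 * x + r.normal(0, 1, n)
        y = -0.8 * m + r.normal(0, 1, n)
        return pd.DataFrame({"x": x, "bag": m, "cognitive_composite": y})

    def test_indirect_recovery_and_decomposition(self):
        df = self._full_mediation_frame(0)
        res = ab.mediate(df, "x", covariates=(), n_boot=500, seed=1)
        assert -0.5 <= res.indirect <= -0.3
        assert abs(res.total - (res.direct + res.indirect)) < 1e-8
        assert res.label == "full"
        assert res.ci_low <= res.indirect <= res.ci_high

    def test_null_mediation_ci_covers_zero(self):
        covered = 0
        for s in range(30):
            r = np.random.default_rng(200 + s)
            n = 200
            df = pd.DataFrame({
                "x": r.normal(0, 1, n),
                "bag": r.normal(0, 1, n),
                "cognitive_composite": r.normal(0, 1, n)})
            res = ab.mediate(df, "x", covariates=(), n_boot=300, seed=s)
            covered += res.ci_low <= 0.0 <= res.ci_high
        assert covered >= 26

    def test_preconditions(self):
        df = self._full_mediation_frame(3, n=20)
        with pytest.raises(ValueError, match="complete"):
            ab.mediate(df, "x", covariates=(), n_boot=200)
        with pytest.raises(ValueError, match="n_boot"):
            ab.mediate(self._full_mediation_frame(3), "x", covariates=(),
                       n_boot=50)


class TestCohensD:
    def test_equal_means(self, rng):
        x = rng.normal(0, 1, 50)
        d, _ = ab.cohens_d(x, x.copy())
        assert d == 0.0

    def test_unit_separation_large_n(self, rng):
        d, ci = ab.cohens_d(rng.normal(1, 1, 20_000), rng.normal(0, 1, 20_000))
        assert d == pytest.approx(1.0, abs=0.05)
        assert ci[0] < d < ci[1]

    def test_fixed_sample_matches_pooled_formula(self):
        x = np.array([3.0, 4, 5, 6, 7, 8])
        y = np.array([1.0, 2, 2, 3, 4, 3])
        d, _ = ab.cohens_d(x, y)
        sp = np.sqrt((5 * x.var(ddof=1) + 5 * y.var(ddof=1)) / 10)
        assert d == pytest.approx((x.mean() - y.mean()) / sp, abs=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            ab.cohens_d([1.0, 1.0], [1.0, 1.0])
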