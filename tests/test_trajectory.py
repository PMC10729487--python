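"""Spline basis, GAMM, simultaneous bands and divergence machinery."""

import subprocess
import sys

import numpy as np
import pytest
from scipy import stats

import adbrainage as ab
from adbrainage import trajectory as traj
from adbrainage._pls import fit_pls

from conftest import attach_bag


class TestCrBasis:
    def test_linear_functions_have_zero_penalty(self):
        basis, _ = ab.build_cr_basis(np.linspace(-30, 10, 50), k=4)
        beta_lin = 2.0 + 0.7 * basis.knots     # coefficients = knot values
        assert beta_lin @ basis.S @ beta_lin == pytest.approx(0.0, abs=1e-9)
        beta_curved = basis.knots ** 2
        assert beta_curved @ basis.S @ beta_curved > 1e-6

    def test_design_dimensions_and_rank(self):
        x = np.linspace(-30, 10, 100)
        _, B = ab.build_cr_basis(x, k=4)
        assert B.shape == (100, 4)
        assert np.linalg.matrix_rank(B) == 4

    def test_interpolation_property_at_knots(self):
        basis, _ = ab.build_cr_basis(np.linspace(0, 10, 40), k=5)
        at_knots = basis.design(basis.knots)
        np.testing.assert_allclose(at_knots, np.eye(5), atol=1e-10)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            ab.build_cr_basis(np.array([1.0, 1, 1, 2, 2]), k=4)

    def test_lambda_zero_equals_ols_oracle(self, rng):
        x = rng.uniform(-20, 10, 120)
        y = 3 + 0.2 * x ** 2 + rng.normal(0, 2, 120)
        fit = traj.fit_smooth(x, y, k=4, lambdas={"s(x)": 0.0})
        basis = fit.basis
        Z = fit.terms["s(x)"]["Z"]
        X = np.hstack([np.ones((120, 1)), basis.design(x) @ Z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.pls.fitted, X @ beta, atol=1e-8)


def test_reml_smooth_matches_mgcv(tmp_path, rng):
    """Independent oracle: an mgcv cubic-regression-spline GAM with the
    same knots and REML smoothing must produce the same predictions."""
    x = rng.uniform(-20, 10, 120)
    y = 5 + 0.3 * x + 4 * np.sin(x / 6) + rng.normal(0, 2, 120)
    kn = np.quantile(x, np.linspace(0, 1, 4))
    fit = traj.fit_smooth(x, y, k=4, knots=kn)
    grid = np.linspace(x.min(), x.max(), 25)
    info = fit.terms["s(x)"]
    L = np.zeros((25, len(fit.pls.beta)))
    L[:, 0] = 1.0
    L[:, info["slice"]] = fit.basis.design(grid) @ info["Z"]
    pred = L @ fit.pls.beta

    np.savetxt(tmp_path / "xy.csv", np.column_stack([x, y]),
               delimiter=",", header="x,y", comments="")
    np.savetxt(tmp_path / "grid.csv", grid, delimiter=",")
    np.savetxt(tmp_path / "knots.csv", kn, delimiter=",")
    rcode = f"""
    suppressMessages(library(mgcv))
    d <- read.csv('{tmp_path}/xy.csv')
    kn <- scan('{tmp_path}/knots.csv', quiet=TRUE)
    g <- scan('{tmp_path}/grid.csv', quiet=TRUE)
    fit <- gam(y ~ s(x, bs='cr', k=4), data=d, knots=list(x=kn), method='REML')
    write.csv(data.frame(p=predict(fit, newdata=data.frame(x=g))),
              '{tmp_path}/r_pred.csv', row.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
    r_pred = np.loadtxt(tmp_path / "r_pred.csv", skiprows=1)
    np.testing.assert_allclose(pred, r_pred, atol=1e-5)


class TestGamm:
    def test_linear_truth_gives_edf_near_one(self, rng):
        x = rng.uniform(-20, 10, 300)
        y = 1.0 + 0.8 * x + rng.normal(0, 2, 300)
        fit = traj.fit_smooth(x, y, k=4)
        assert fit.pls.edf["s(x)"] == pytest.approx(1.0, abs=0.2)

    def test_forced_lambda_inf_equals_linear_mixed_oracle(self,
                                                          cohort_with_bag):
        t = cohort_with_bag
        lam_f = 2.0
        fit = ab.fit_gamm(t, response="bag",
                          lambdas={"s(eyo):NC": 1e13, "s(eyo):MC": 1e13,
                                   "family": lam_f})
        carrier = (t["group"] != "NC").to_numpy(float)
        eyo = t["eyo"].to_numpy()
        cols = [np.ones(len(t)), carrier]
        for c in ("sex", "education", "apoe4"):
            v = (t[c] == "M").to_numpy(float) if c == "sex" \
                else t[c].to_numpy(float)
            cols.append(v - v.mean())
        cols.append(np.where(carrier == 0, eyo - eyo[carrier == 0].mean(), 0))
        cols.append(np.where(carrier == 1, eyo - eyo[carrier == 1].mean(), 0))
        Xd = np.column_stack(cols)
        fams, fam_idx = np.unique(t["family_id"], return_inverse=True)
        oracle = fit_pls(Xd, t["bag"].to_numpy(), [], fam_idx=fam_idx,
                         n_fam=len(fams), lambdas={"family": lam_f})
        np.testing.assert_allclose(fit.pls.fitted, oracle.fitted, atol=1e-6)

    def test_edf_bounds_for_k4(self, cohort_with_bag):
        fit = ab.fit_gamm(cohort_with_bag, response="bag", k=4)
        for term in ("s(eyo):NC", "s(eyo):MC"):
            assert 1.0 - 1e-6 <= fit.edf[term] <= 4.0

    def test_family_intercept_recovery(self):
        """family_sd=2 with batch effects off: mean estimated SD over 20
        seeds inside [1.6, 2.4]."""
        est = []
        for s in range(20):
            spec = ab.CohortSpec(n_nc=246, n_asym_mc=252, n_sym_mc=102,
                                 site_shift_sd=0.0, scanner_scale_sd=0.0)
            t = attach_bag(ab.generate_cohort(spec, seed=700 + s))
            est.append(np.sqrt(ab.fit_gamm(t, response="bag").var_family))
        assert 1.6 <= np.mean(est) <= 2.4

    def test_requires_columns_and_families(self, cohort_with_bag):
        with pytest.raises(ValueError, match="missing"):
            ab.fit_gamm(cohort_with_bag.drop(columns=["eyo"]), response="bag")
        one_fam = cohort_with_bag.assign(family_id="F000")
        with pytest.raises(ValueError, match="famil"):
            ab.fit_gamm(one_fam, response="bag")


class TestSmoothTermTest:
    def test_null_calibration(self):
        """Flat truth: rejection rate at alpha=0.05 within the binomial
        99.5% envelope over 200 seeds."""
        rej = 0
        for s in range(200):
            rng = np.random.default_rng(30_000 + s)
            x = rng.uniform(-20, 10, 150)
            y = 3.0 + rng.normal(0, 2, 150)
            fit = traj.fit_smooth(x, y, k=4)
            rej += traj.smooth_term_test(fit, "s(x)")[1] < 0.05
        lo = stats.binom.ppf(0.0025, 200, 0.05)
        hi = stats.binom.ppf(0.9975, 200, 0.05)
        assert lo <= rej <= hi

    def test_power_on_default_mc_ramp(self):
        """Default carrier ramp at n=400: MC smooth p < 0.001 in >= 95% of
        seeds."""
        hits = 0
        n_seeds = 40
        for s in range(n_seeds):
            spec = ab.CohortSpec(n_nc=164, n_asym_mc=168, n_sym_mc=68)
            t = attach_bag(ab.generate_cohort(spec, seed=7100 + s))
            fit = ab.fit_gamm(t, response="bag")
            hits += traj.smooth_term_test(fit, "s(eyo):MC")[1] < 0.001
        assert hits >= 0.95 * n_seeds

    def test_unknown_term_rejected(self, cohort_with_bag):
        fit = ab.fit_gamm(cohort_with_bag, response="bag")
        with pytest.raises(KeyError):
            traj.smooth_term_test(fit, "nope")


class TestSimultaneousBand:
    def test_multiplier_dominates_pointwise_quantile(self, cohort_with_bag):
        fit = ab.fit_gamm(cohort_with_bag, response="bag")
        grid = traj._common_grid(cohort_with_bag, 0.5)
        for term in ("s(eyo):NC", "s(eyo):MC"):
            band = ab.simultaneous_band(fit, term, grid, n_draws=2000, seed=3)
            assert band.m >= stats.norm.ppf(1 - (1 - 0.834) / 2) - 1e-9
            assert np.all(band.lower <= band.fit)
            assert np.all(band.fit <= band.upper)

    def test_single_point_grid_recovers_pointwise_quantile(self,
                                                           cohort_with_bag):
        fit = ab.fit_gamm(cohort_with_bag, response="bag")
        band = ab.simultaneous_band(fit, "s(eyo):MC", [0.0], n_draws=40_000,
                                    seed=4)
        assert band.m == pytest.approx(stats.norm.ppf(1 - 0.166 / 2),
                                       abs=0.03)

    def test_band_nesting_95_contains_83(self, cohort_with_bag):
        fit = ab.fit_gamm(cohort_with_bag, response="bag")
        grid = traj._common_grid(cohort_with_bag, 0.5)
        b83 = ab.simultaneous_band(fit, "s(eyo):MC", grid, level=0.834,
                                   n_draws=4000, seed=5)
        b95 = ab.simultaneous_band(fit, "s(eyo):MC", grid, level=0.95,
                                   n_draws=4000, seed=5)
        assert np.all(b95.lower <= b83.lower)
        assert np.all(b95.upper >= b83.upper)

    def test_grid_outside_support_rejected(self, cohort_with_bag):
        fit = ab.fit_gamm(cohort_with_bag, response="bag")
        with pytest.raises(ValueError, match="range"):
            ab.simultaneous_band(fit, "s(eyo):MC", [500.0])


def _const_band(grid, lo, hi):
    g = np.asarray(grid, dtype=float)
    mid = np.full_like(g, (lo + hi) / 2)
    return traj.SimultaneousBand(grid=g, fit=mid,
                                 lower=np.full_like(g, lo),
                                 upper=np.full_like(g, hi),
                                 se=np.ones_like(g), level=0.834, m=2.0,
                                 n_draws=100, term="s")


class TestFindDivergence:
    grid = np.linspace(-10, 5, 31)

    def test_identical_bands_give_none(self):
        b = _const_band(self.grid, -1, 1)
        assert ab.find_divergence(b, _const_band(self.grid, -1, 1)) is None

    def test_disjoint_bands_give_grid_minimum(self):
        assert ab.find_divergence(_const_band(self.grid, 5, 7),
                                  _const_band(self.grid, -1, 1)) == -10.0

    def test_partial_separation_gives_first_sustained_point(self):
        nc = _const_band(self.grid, -1.0, 1.0)
        mc = _const_band(self.grid, -1.0, 1.0)
        mask = self.grid >= -3.0
        mc.lower[mask] = 2.0
        mc.upper[mask] = 4.0
        assert ab.find_divergence(mc, nc) == pytest.approx(-3.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ab.find_divergence(_const_band(self.grid, 0, 1),
                               _const_band(self.grid[:-1], 0, 1))


class TestBootstrapDivergence:
    @staticmethod
    def _table(seed, d1=-7.0, d2=-7.0, noise=3.0):
        spec = ab.CohortSpec(n_nc=120, n_asym_mc=120, n_sym_mc=60)
        t = ab.generate_cohort(spec, seed=seed)
        t = ab.add_measure(t, spec, "m1", divergence_eyo=d1, noise_sd=noise,
                           seed=seed * 7 + 1)
        t = ab.add_measure(t, spec, "m2", divergence_eyo=d2, noise_sd=noise,
                           seed=seed * 7 + 2)
        return t

    def test_determinism_same_seed(self):
        t = self._table(31)
        kw = dict(n_boot=100, seed=9, grid_step=0.5, n_draws=150)
        r1 = ab.bootstrap_divergence(t, ["m1"], **kw)
        r2 = ab.bootstrap_divergence(t, ["m1"], **kw)
        np.testing.assert_array_equal(r1.measures["m1"]["boot"],
                                      r2.measures["m1"]["boot"])
        assert r1.measures["m1"]["ci"] == r2.measures["m1"]["ci"]

    def test_summary_invariants(self):
        t = self._table(32, d2=-3.0)
        r = ab.bootstrap_divergence(t, ["m1", "m2"], n_boot=100, seed=2,
                                    grid_step=0.5, n_draws=150)
        for m in ("m1", "m2"):
            s = r.measures[m]
            assert s["ci"][0] <= s["median"] <= s["ci"][1]
        for p in r.pairwise_p.values():
            assert 0.0 <= p <= 1.0

    def test_n_boot_minimum_enforced(self):
        with pytest.raises(ValueError):
            ab.bootstrap_divergence(self._table(33), ["m1"], n_boot=50)

    def test_noise_ladder_divergence_monotonicity(self):
        """More measurement noise never moves the median bootstrap
        divergence earlier (common random numbers across the ladder)."""
        medians = []
        for noise in (2.0, 6.0, 12.0):
            spec = ab.CohortSpec(n_nc=185, n_asym_mc=189, n_sym_mc=76)
            t = ab.generate_cohort(spec, seed=77)
            t = ab.add_measure(t, spec, "m", divergence_eyo=-7.0,
                               noise_sd=noise, seed=55)
            r = ab.bootstrap_divergence(t, ["m"], n_boot=100, seed=5,
                                        grid_step=0.5, n_draws=150)
            medians.append(r.measures["m"]["median"])
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9
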