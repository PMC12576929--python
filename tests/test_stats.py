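import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from movekba.stats import fit_beta_glmm, fit_lmm

SUBSETS = ["resting", "foraging", "transiting", "sample"]
MU = dict(zip(SUBSETS, [0.9, 0.9, 0.4, 0.86]))


def simulate_beta(seed, n_colonies=14, n_per=10, phi=20.0, sd=0.3):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_colonies):
        u = rng.normal(0, sd)
        for _ in range(n_per):
            for s in SUBSETS:
                m = expit(logit(MU[s]) + u)
                y = rng.beta(m * phi, (1 - m) * phi)
                rows.append(
                    {"colony_id": f"c{c}", "subset": s,
                     "capture_transformed": float(np.clip(y, 1e-9, 1 - 1e-9))}
                )
    return pd.DataFrame(rows)


def simulate_lmm(seed, offsets, n_colonies=14, rand_sd=0.4, resid_sd=0.2):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_colonies):
        u = rng.normal(0, rand_sd)
        for s, off in offsets.items():
            rows.append(
                {"colony_id": f"c{c}", "subset": s,
                 "log10_area": 2.5 + off + u + rng.normal(0, resid_sd)}
            )
    return pd.DataFrame(rows)


class TestBetaGLMM:
    def test_degenerate_random_effect_matches_fixed_effects_oracle(self):
        # no group effect in the data: estimates must agree with an
        # independent fixed-effects-only beta regression
        df = simulate_beta(0, n_colonies=5, n_per=30, sd=0.0)
        fit = fit_beta_glmm(df)
        from statsmodels.othermod.betareg import BetaModel

        X = pd.get_dummies(df["subset"])[sorted(SUBSETS)].to_numpy(dtype=float)
        oracle = BetaModel(df["capture_transformed"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.beta, oracle.params[:4], atol=1e-4)
        assert fit.random_sd < 0.05

    def test_logit_link_identity(self):
        df = simulate_beta(1, n_colonies=4, n_per=20, sd=0.1)
        fit = fit_beta_glmm(df)
        for i, s in enumerate(fit.subsets):
            assert fit.mean_for(s) == pytest.approx(float(expit(fit.beta[i])), abs=1e-12)

    def test_response_must_be_interior(self):
        df = simulate_beta(2, n_colonies=3, n_per=5)
        df.loc[0, "capture_transformed"] = 1.0
        with pytest.raises(ValueError, match="transform_proportion"):
            fit_beta_glmm(df)

    def test_quadrature_convergence(self):
        df = simulate_beta(3, n_colonies=8, n_per=6)
        f9 = fit_beta_glmm(df, n_quad=9)
        f31 = fit_beta_glmm(df, n_quad=31)
        np.testing.assert_allclose(f9.beta, f31.beta, atol=1e-3)

    def test_cis_contain_point_estimates(self):
        df = simulate_beta(4, n_colonies=6, n_per=8)
        fit = fit_beta_glmm(df)
        assert (fit.means["lo95"] <= fit.means["estimate"]).all()
        assert (fit.means["estimate"] <= fit.means["hi95"]).all()


class TestLMM:
    OFFSETS = {"all": 0.0, "foraging": -0.16, "resting": -0.48,
               "transiting": 0.28, "sample": -0.02}

    def test_zero_variance_matches_ols(self):
        df = simulate_lmm(0, self.OFFSETS, rand_sd=0.0)
        fit = fit_lmm(df)
        levels = fit.terms
        X = np.zeros((len(df), len(levels)))
        X[:, 0] = 1.0
        for j, lev in enumerate(levels[1:], start=1):
            X[:, j] = (df["subset"] == lev).to_numpy()
        ols = np.linalg.lstsq(X, df["log10_area"].to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-6)

    def test_matches_independent_mixed_model_fit(self):
        df = simulate_lmm(1, self.OFFSETS)
        fit = fit_lmm(df)
        import statsmodels.formula.api as smf

        oracle = smf.mixedlm(
            "log10_area ~ C(subset, Treatment('all'))", df, groups="colony_id"
        ).fit(reml=False)
        # statsmodels orders contrasts alphabetically, as we do
        np.testing.assert_allclose(fit.beta, oracle.fe_params.to_numpy(), atol=1e-4)

    def test_offset_recovery_across_seeds(self):
        errs = []
        for seed in range(10):
            df = simulate_lmm(seed, self.OFFSETS)
            fit = fit_lmm(df)
            got = dict(zip(fit.terms, fit.beta))
            errs.append(
                max(abs(got[s] - self.OFFSETS[s]) for s in self.OFFSETS if s != "all")
            )
        assert max(errs) < 0.25  # per-seed sampling noise
        assert float(np.mean(errs)) < 0.15

    def test_r2_ordering_and_variances(self):
        df = simulate_lmm(2, self.OFFSETS)
        fit = fit_lmm(df)
        assert 0 <= fit.r2_marginal <= fit.r2_conditional <= 1
        assert fit.random_var >= 0 and fit.resid_var > 0

    def test_shift_invariance_except_intercept(self):
        df = simulate_lmm(3, self.OFFSETS)
        fit = fit_lmm(df)
        df2 = df.copy()
        df2["log10_area"] += 5.0
        fit2 = fit_lmm(df2)
        np.testing.assert_allclose(fit2.beta[1:], fit.beta[1:], atol=1e-8)
        assert fit2.beta[0] == pytest.approx(fit.beta[0] + 5.0, abs=1e-8)

    def test_single_group_rejected(self):
        df = simulate_lmm(4, self.OFFSETS, n_colonies=1)
        with pytest.raises(ValueError):
            fit_lmm(df)
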