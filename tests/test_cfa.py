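"""Bifactor CFA: recovery, fit indices, factor scores, robust SEs."""

import numpy as np
import pandas as pd
import pytest

from pfactor.cfa import (
    BifactorModel,
    BifactorSpec,
    fit_indices_from_chi2,
)
from pfactor.defaults import DEFAULT_TRUE_LOADINGS, SCALE_NAMES


def default_truth():
    lam = DEFAULT_TRUE_LOADINGS
    theta = 1 - (lam**2).sum(axis=1)
    return lam, theta


def random_admissible(rng, spec):
    mask = spec.free_mask
    lam = np.zeros(mask.shape)
    lam[:, 0] = rng.uniform(0.15, 0.7, mask.shape[0])
    for i in range(mask.shape[0]):
        for f in range(1, mask.shape[1]):
            if mask[i, f]:
                cap = np.sqrt(0.9 - lam[i, 0] ** 2)
                lam[i, f] = rng.uniform(0.1, min(0.7, cap))
    theta = 1 - (lam**2).sum(axis=1)
    return lam, theta


def mvn_scores(lam, theta, n, rng, noise="normal"):
    f = rng.standard_normal((n, lam.shape[1]))
    if noise == "normal":
        e = rng.standard_normal((n, lam.shape[0]))
    else:  # scaled t with 3 df, unit variance
        e = rng.standard_t(3, size=(n, lam.shape[0])) / np.sqrt(3.0)
    X = f @ lam.T + e * np.sqrt(theta)
    frame = pd.DataFrame(X, columns=list(SCALE_NAMES))
    frame.insert(0, "person_id", [f"P{i}" for i in range(n)])
    return frame


class TestSpec:
    def test_default_pattern_and_df(self):
        spec = BifactorSpec.default()
        mask = spec.free_mask
        assert mask[:, 0].all()  # every scale on the general factor
        assert mask.sum() == 12 + 11  # conduct has no specific loading
        assert spec.df() == 43

    def test_conduct_alternative_placement(self):
        spec = BifactorSpec.default(conduct_on_specific=True)
        assert spec.free_mask.sum() == 24
        assert spec.df() == 42

    def test_df_formula_for_arbitrary_specs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            keep = {
                item: (None if rng.random() < 0.3 else fac)
                for item, fac in BifactorSpec.default(True).specific_of.items()
            }
            spec = BifactorSpec(items=tuple(SCALE_NAMES), specific_of=keep)
            p = 12
            assert spec.df() == p * (p + 1) // 2 - (int(spec.free_mask.sum()) + p)


class TestFit:
    def test_zero_discrepancy_fixed_point(self):
        lam0, theta0 = default_truth()
        S = lam0 @ lam0.T + np.diag(theta0)
        fit = BifactorModel(S, n=5000).fit()
        assert fit.converged
        assert fit.fml <= 1e-8
        assert np.abs(fit.lam - lam0).max() < 1e-4
        assert np.abs(fit.theta - theta0).max() < 1e-4

    def test_identity_covariance_single_general_factor(self):
        spec = BifactorSpec(
            items=tuple(SCALE_NAMES), specific_of={s: None for s in SCALE_NAMES}
        )
        fit = BifactorModel(np.eye(12), n=1000, spec=spec).fit()
        assert np.abs(fit.lam).max() < 1e-3
        assert np.abs(fit.theta - 1.0).max() < 1e-3

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_admissible_recovery(self, seed):
        spec = BifactorSpec.default()
        lam0, theta0 = random_admissible(np.random.default_rng(seed), spec)
        S = lam0 @ lam0.T + np.diag(theta0)
        fit = BifactorModel(S, n=5000, spec=spec).fit()
        assert fit.fml <= 1e-8
        assert np.abs(fit.lam - lam0).max() < 1e-4

    def test_large_sample_recovery_through_items(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 50_000, np.random.default_rng(4))
        fit = BifactorModel.from_scores(scores).fit()
        assert np.abs(fit.lam - lam0).max() < 0.05

    def test_variable_order_invariance(self):
        lam0, theta0 = default_truth()
        S = lam0 @ lam0.T + np.diag(theta0)
        base = BifactorModel(S, n=2000).fit()

        perm = np.random.default_rng(5).permutation(12)
        spec = BifactorSpec.default()
        spec_p = BifactorSpec(
            items=tuple(np.array(spec.items)[perm]),
            specific_of=spec.specific_of,
        )
        S_p = S[np.ix_(perm, perm)]
        fit_p = BifactorModel(S_p, n=2000, spec=spec_p).fit()
        inv = np.argsort(perm)
        np.testing.assert_allclose(fit_p.lam[inv], base.lam, atol=1e-6)

    def test_heywood_flagged(self):
        lam0, theta0 = default_truth()
        lam = lam0.copy()
        lam[11, 0] = 0.999
        lam[11, 3] = 0.04
        theta = 1 - (lam**2).sum(axis=1)
        S = lam @ lam.T + np.diag(theta)
        fit = BifactorModel(S, n=2000).fit()
        assert fit.heywood

    def test_single_case_rejected(self):
        frame = mvn_scores(*default_truth(), 1, np.random.default_rng(0))
        with pytest.raises(ValueError, match="complete cases"):
            BifactorModel.from_scores(frame)


class TestFitIndices:
    def test_closed_form_worked_triple(self):
        cfi, tli, rmsea = fit_indices_from_chi2(100.0, 48, 2000.0, 66, 1001)
        assert cfi == pytest.approx(1 - 52 / 1934, abs=1e-10)
        assert tli == pytest.approx(
            ((2000 / 66) - (100 / 48)) / ((2000 / 66) - 1), abs=1e-10
        )
        assert rmsea == pytest.approx(np.sqrt(52 / (48 * 1000)), abs=1e-10)

    def test_better_than_expected_fit(self):
        cfi, tli, rmsea = fit_indices_from_chi2(30.0, 48, 2000.0, 66, 500)
        assert cfi == 1.0
        assert rmsea == 0.0

    def test_tli_zero_when_model_matches_baseline_ratio(self):
        ratio = 2000.0 / 66
        _, tli, _ = fit_indices_from_chi2(ratio * 48, 48, 2000.0, 66, 500)
        assert tli == pytest.approx(0.0, abs=1e-12)

    def test_from_fit_matches_hand_computation(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 3000, np.random.default_rng(6))
        fit = BifactorModel.from_scores(scores).fit()
        fi = fit.fit_indices()
        chi2_b, df_b = fit.baseline_chi2()
        cfi, tli, rmsea = fit_indices_from_chi2(fit.chi2, fit.df, chi2_b, df_b, fit.n)
        assert (fi.cfi, fi.tli, fi.rmsea) == (cfi, tli, rmsea)


class TestFactorScores:
    def test_mean_vector_scores_zero(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 500, np.random.default_rng(7))
        fit = BifactorModel.from_scores(scores, standardize=False).fit()
        fs = fit.factor_scores()
        np.testing.assert_allclose(fs[["P", "E", "B", "N"]].mean(), 0.0, atol=1e-10)

    def test_three_item_weights_match_explicit_inversion(self):
        lam = np.array([[0.8], [0.6], [0.4]])
        theta = 1 - lam[:, 0] ** 2
        spec = BifactorSpec(items=("a", "b", "c"), specific_of={}, factors=("G",))
        model = BifactorModel(lam @ lam.T + np.diag(theta), n=100, spec=spec)
        fit = model.fit()
        sigma = fit.implied_cov()
        expected = fit.lam.T @ np.linalg.inv(sigma)
        np.testing.assert_allclose(fit.score_weights("regression"), expected, atol=1e-10)
        # hand inversion from the generating parameters
        hand = lam.T @ np.linalg.inv(lam @ lam.T + np.diag(theta))
        np.testing.assert_allclose(fit.score_weights("regression"), hand, atol=1e-4)

    def test_item_order_equivariance(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 400, np.random.default_rng(8))
        fit = BifactorModel.from_scores(scores).fit()
        base = fit.factor_scores(scores)

        perm = np.random.default_rng(9).permutation(12)
        spec = BifactorSpec.default()
        spec_p = BifactorSpec(
            items=tuple(np.array(spec.items)[perm]), specific_of=spec.specific_of
        )
        fit_p = BifactorModel.from_scores(scores, spec=spec_p).fit()
        other = fit_p.factor_scores(scores)
        np.testing.assert_allclose(
            base[["P", "E", "B", "N"]], other[["P", "E", "B", "N"]], atol=1e-6
        )

    def test_missing_scale_gives_missing_scores(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 300, np.random.default_rng(10))
        scores.loc[5, "conduct"] = np.nan
        fit = BifactorModel.from_scores(scores).fit()
        fs = fit.factor_scores(scores)
        assert fs.loc[5, ["P", "E", "B", "N"]].isna().all()

    def test_bartlett_scores_unbiased_weights(self):
        # W Lambda = I is the defining property of Bartlett scores
        lam0, theta0 = default_truth()
        S = lam0 @ lam0.T + np.diag(theta0)
        fit = BifactorModel(S, n=1000).fit()
        W = fit.score_weights("bartlett")
        np.testing.assert_allclose(W @ fit.lam, np.eye(4), atol=1e-8)


class TestSandwich:
    def test_normal_data_robust_close_to_naive(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 20_000, np.random.default_rng(11))
        fit = BifactorModel.from_scores(scores).fit()
        se = fit.sandwich_se()
        lam_rows = se.index.str.startswith("lambda")
        ratio = se.loc[lam_rows, "se_robust"] / se.loc[lam_rows, "se_naive"]
        assert ratio.between(0.9, 1.1).all()

    def test_duplicated_data_halves_variance(self):
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 2000, np.random.default_rng(12))
        doubled = pd.concat([scores, scores], ignore_index=True)
        doubled["person_id"] = [f"P{i}" for i in range(len(doubled))]
        se1 = BifactorModel.from_scores(scores).fit().sandwich_se()
        se2 = BifactorModel.from_scores(doubled).fit().sandwich_se()
        ratio = (se1["se_robust"] / se2["se_robust"]).to_numpy()
        np.testing.assert_allclose(ratio, np.sqrt(2.0), rtol=0.01)

    def test_heavy_tailed_unique_noise_inflates_uniqueness_se(self):
        # excess kurtosis in the unique errors hits the fourth-moment terms
        # of the uniqueness scores; loading scores are cross-products with
        # the (normal) factors and stay near the information-based SEs
        lam0, theta0 = default_truth()
        scores = mvn_scores(lam0, theta0, 5000, np.random.default_rng(13), noise="t3")
        fit = BifactorModel.from_scores(scores, standardize=False).fit()
        se = fit.sandwich_se()
        theta_rows = se.index.str.startswith("theta")
        ratio = se.loc[theta_rows, "se_robust"] / se.loc[theta_rows, "se_naive"]
        assert (ratio > 1.1).all()

    def test_heavy_tailed_factors_inflate_loading_se(self):
        lam0, theta0 = default_truth()
        rng = np.random.default_rng(14)
        n = 5000
        f = rng.standard_t(3, size=(n, 4)) / np.sqrt(3.0)
        e = rng.standard_normal((n, 12))
        X = f @ lam0.T + e * np.sqrt(theta0)
        frame = pd.DataFrame(X, columns=list(SCALE_NAMES))
        frame.insert(0, "person_id", range(n))
        fit = BifactorModel.from_scores(frame, standardize=False).fit()
        se = fit.sandwich_se()
        lam_rows = se.index.str.startswith("lambda")
        assert (
            se.loc[lam_rows, "se_robust"].mean()
            > 1.1 * se.loc[lam_rows, "se_naive"].mean()
        )

    def test_robust_se_matches_bootstrap_under_heavy_tails(self):
        lam0, theta0 = default_truth()
        rng = np.random.default_rng(13)
        scores = mvn_scores(lam0, theta0, 5000, rng, noise="t3")
        fit = BifactorModel.from_scores(scores, standardize=False).fit()
        se = fit.sandwich_se()

        # bootstrap oracle for the general-factor loadings
        boot = []
        idx_all = np.arange(len(scores))
        for b in range(100):
            take = rng.choice(idx_all, size=len(idx_all), replace=True)
            bf = BifactorModel.from_scores(
                scores.iloc[take].reset_index(drop=True), standardize=False
            ).fit(n_starts=1)
            boot.append(bf.lam[:, 0])
        boot_se = np.std(np.array(boot), axis=0, ddof=1)
        general_rows = [f"lambda[{item},P]" for item in SCALE_NAMES]
        impl_se = se.loc[general_rows, "se_robust"].to_numpy()
        assert np.all(np.abs(impl_se - boot_se) / boot_se < 0.15)
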