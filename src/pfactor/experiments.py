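"""Replicated simulation studies: calibration and bias properties of the
association stage.

These are the package's own statistical-quality experiments: type-I-error
calibration of the multivariable association under the global null,
univariable-vs-multivariable attenuation with correlated scores, and the
bias reduction delivered by inverse-probability weighting under
symptom-dependent genotype availability.  Each study fixes the measurement
model once on a large step-1 cohort and re-uses it across replicates,
mirroring the two-step analysis design.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .association import FactorAssociationModel
from .cfa import BifactorModel, BifactorResults
from .defaults import PRS_TRAITS, SCALE_NAMES
from .ipw import estimate_weights
from .scales import score_scales, standardize_scores
from .simulate import AvailabilityModel, SimulationConfig, simulate_cohort


def _null_config(seed: int, n: int) -> SimulationConfig:
    betas = np.zeros((4, 5))
    return SimulationConfig(
        n_individuals=n,
        factor_betas=betas,
        family_frac=0.0,
        item_missing_rate=0.0,
        target_avail=1.0,
        seed=seed,
    )


def _fit_measurement(config: SimulationConfig) -> BifactorResults:
    _, _, cohort = simulate_cohort(config, genotypes=False)
    std = standardize_scores(score_scales(cohort))
    return BifactorModel.from_scores(std).fit(seed=config.seed)


def _prs_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    pred = cohort[["person_id", "sex"]].copy()
    for t in PRS_TRAITS:
        pred[f"prs_{t}"] = cohort[f"prs_true_{t}"]
    return pred


def null_type_i_error(
    n_replicates: int = 2000,
    n_per_replicate: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
    step1_n: int = 20_000,
) -> dict:
    """Empirical type-I error of the multivariable association under the
    global null (all structural effects zero).

    The measurement model is fixed once on a large null cohort; each
    replicate draws a fresh small cohort and null PRS, and all factor x PRS
    Wald p-values are pooled.
    """
    measurement = _fit_measurement(_null_config(seed, step1_n))
    rejections = 0
    total = 0
    prs_cols = [f"prs_{t}" for t in PRS_TRAITS]
    for rep in range(n_replicates):
        cfg = _null_config(seed + 1 + rep, n_per_replicate)
        _, _, cohort = simulate_cohort(cfg, genotypes=False)
        std = standardize_scores(score_scales(cohort))
        res = FactorAssociationModel(
            measurement, std, _prs_frame(cohort), prs_cols=prs_cols
        ).fit()
        pvals = res.table[res.table["predictor"].isin(prs_cols)]["p"].to_numpy()
        rejections += int((pvals < alpha).sum())
        total += len(pvals)
    return {
        "type_i_error": rejections / total,
        "n_tests": total,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def attenuation_study(n: int = 50_000, seed: int = 0) -> dict:
    """Univariable-vs-multivariable contrast with correlated polygenic scores.

    Two scores correlate 0.5; only the first has a true effect (0.2) on the
    general factor.  The closed-form population values are multivariable
    beta2 = 0 and univariable beta2 = 0.5 * 0.2 = 0.1.
    """
    R = np.eye(4)
    R[0, 1] = R[1, 0] = 0.5
    betas = np.zeros((4, 5))
    betas[0, 0] = 0.2
    cfg = SimulationConfig(
        n_individuals=n,
        effect_corr_matrix=R,
        factor_betas=betas,
        family_frac=0.0,
        item_missing_rate=0.0,
        target_avail=1.0,
        seed=seed,
    )
    _, _, cohort = simulate_cohort(cfg, genotypes=False)
    std = standardize_scores(score_scales(cohort))
    measurement = BifactorModel.from_scores(std).fit(seed=seed)
    model = FactorAssociationModel(
        measurement,
        std,
        _prs_frame(cohort),
        prs_cols=["prs_scz", "prs_adhd"],
        covariate_cols=(),
    )
    multi = model.fit()
    uni = model.fit_univariable()
    return {
        "multivariable_beta1": float(multi.get("P", "prs_scz")["beta"]),
        "multivariable_beta2": float(multi.get("P", "prs_adhd")["beta"]),
        "univariable_beta2": float(uni.get("P", "prs_adhd")["beta"]),
        "n": n,
    }


def ipw_bias_reduction(
    n_replicates: int = 200,
    n_per_replicate: int = 8000,
    avail_slope: float = -1.5,
    true_beta: float = 0.1,
    target_avail: float = 0.68,
    seed: int = 0,
    step1_n: int = 20_000,
) -> dict:
    """How often IPW moves the estimate toward the full-data value under
    symptom-dependent genotype availability.

    Each replicate: a cohort with one true PRS effect on the general factor;
    availability follows a logistic model on the observed standardized mean
    symptom score.  The full-data estimate (before deletion) is the oracle;
    the weighted complete-case estimate wins a replicate when it is closer
    to that oracle than the unweighted one.
    """
    betas = np.zeros((4, 5))
    betas[0, 0] = true_beta
    base = SimulationConfig(
        n_individuals=n_per_replicate,
        factor_betas=betas,
        family_frac=0.0,
        item_missing_rate=0.0,
        target_avail=target_avail,
        genotype_avail_model=AvailabilityModel(slope_p=avail_slope, on="observed_symptoms"),
        seed=seed,
    )
    measurement = _fit_measurement(
        replace(base, n_individuals=step1_n, target_avail=1.0, seed=seed)
    )
    wins = 0
    rows = []
    for rep in range(n_replicates):
        cfg = replace(base, seed=seed + 1 + rep)
        _, _, cohort = simulate_cohort(cfg, genotypes=False)
        scored = score_scales(cohort)
        std = standardize_scores(scored)
        pred = _prs_frame(cohort)

        full = FactorAssociationModel(
            measurement, std, pred, prs_cols=["prs_scz"], covariate_cols=()
        ).fit()
        beta_full = float(full.get("P", "prs_scz")["beta"])

        avail_ids = set(cohort.loc[cohort["genotype_available"], "person_id"])
        std_a = std[std["person_id"].isin(avail_ids)]
        unw = FactorAssociationModel(
            measurement, std_a, pred, prs_cols=["prs_scz"], covariate_cols=()
        ).fit()
        beta_unw = float(unw.get("P", "prs_scz")["beta"])

        cohort_scored = cohort[["person_id", "sex", "genotype_available"]].merge(
            scored, on="person_id"
        )
        weights = estimate_weights(cohort_scored, predictors=["sex", *SCALE_NAMES])
        wtd = FactorAssociationModel(
            measurement, std_a, pred, prs_cols=["prs_scz"], covariate_cols=(), weights=weights
        ).fit()
        beta_w = float(wtd.get("P", "prs_scz")["beta"])

        win = abs(beta_w - beta_full) < abs(beta_unw - beta_full)
        wins += int(win)
        rows.append(
            {"replicate": rep, "beta_full": beta_full, "beta_unweighted": beta_unw, "beta_weighted": beta_w, "win": win}
        )
    detail = pd.DataFrame(rows)
    return {
        "win_fraction": wins / n_replicates,
        "n_replicates": n_replicates,
        "mean_abs_err_unweighted": float((detail["beta_unweighted"] - detail["beta_full"]).abs().mean()),
        "mean_abs_err_weighted": float((detail["beta_weighted"] - detail["beta_full"]).abs().mean()),
        "detail": detail,
    }
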