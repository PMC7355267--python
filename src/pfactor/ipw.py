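"""Inverse-probability weighting for missing genetic data.

A logistic model of genotype availability on fully observed predictors
(default: sex plus the 12 observed scale scores) gives each genotyped person
a weight equal to the inverse of their fitted availability probability
(stabilized by the marginal availability rate by default, trimmed at a high
quantile).  The association stage is then re-run with those case weights and
compared side by side with the unweighted run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .association import AssociationResults, FactorAssociationModel
from .cfa import BifactorResults
from .defaults import SCALE_NAMES

log = logging.getLogger(__name__)

PROB_FLOOR = 1e-6
ESS_WARN = 50.0


@dataclass
class IpwConfig:
    predictors: tuple[str, ...] = ("sex", *SCALE_NAMES)
    stabilize: bool = True
    trim_quantile: float = 0.99


def estimate_weights(
    cohort: pd.DataFrame,
    predictors: list[str] | None = None,
    stabilize: bool = True,
    trim_quantile: float = 0.99,
) -> pd.DataFrame:
    """Fit the availability model and return per-person weights.

    Returns a frame with person_id, prob (fitted availability), weight
    (NaN for unavailable persons), and trimmed flag.  The fitted logistic
    coefficients are attached as ``.attrs['coef']``.
    """
    predictors = list(predictors) if predictors is not None else ["sex", *SCALE_NAMES]
    cols = ["person_id", "genotype_available", *predictors]
    frame = cohort[cols].dropna(subset=predictors).reset_index(drop=True)
    y = frame["genotype_available"].astype(float).to_numpy()
    X = sm.add_constant(frame[predictors].astype(float).to_numpy())
    if y.min() == y.max():  # no missingness (or none observed): weights are 1/rate
        prob = np.full(len(frame), y.mean())
        coef = np.zeros(X.shape[1])
    else:
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = glm.fit()  # IRLS
        prob = np.asarray(fit.predict(X))
        coef = np.asarray(fit.params)

    n_floor = int((prob < PROB_FLOOR).sum())
    if n_floor:
        log.warning("%d fitted availability probabilities < %g floored", n_floor, PROB_FLOOR)
    prob = np.clip(prob, PROB_FLOOR, 1.0)

    marginal = y.mean()
    weight = np.where(y > 0, (marginal if stabilize else 1.0) / prob, np.nan)
    cap = np.nanquantile(weight, trim_quantile)
    trimmed = weight > cap
    weight = np.minimum(weight, cap)

    out = pd.DataFrame(
        {
            "person_id": frame["person_id"].to_numpy(),
            "prob": prob,
            "weight": weight,
            "trimmed": np.where(np.isnan(weight), False, trimmed),
        }
    )
    out.attrs["coef"] = {"const": coef[0], **{p: c for p, c in zip(predictors, coef[1:])}}
    out.attrs["marginal_rate"] = float(marginal)
    out.attrs["n_floored"] = n_floor
    return out


def effective_sample_size(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    w = w[np.isfinite(w)]
    return float(w.sum() ** 2 / (w**2).sum())


def weighted_refit(
    measurement: BifactorResults,
    scores: pd.DataFrame,
    predictors: pd.DataFrame,
    weights: pd.DataFrame,
    prs_cols: list[str] | None = None,
    covariate_cols: tuple[str, ...] = ("sex",),
    mode: str = "fixed_measurement",
) -> tuple[AssociationResults, AssociationResults, pd.DataFrame]:
    """Re-run the multivariable association with IPW case weights.

    Returns (unweighted results, weighted results, comparison table with the
    absolute shift per factor x predictor).
    """
    avail = weights.dropna(subset=["weight"])["person_id"]
    scores_a = scores[scores["person_id"].isin(set(avail))]
    ess = effective_sample_size(weights["weight"].to_numpy())
    if ess < ESS_WARN:
        warnings.warn(f"effective sample size {ess:.1f} < {ESS_WARN}", stacklevel=2)

    common = dict(prs_cols=prs_cols, covariate_cols=covariate_cols, mode=mode)
    unweighted = FactorAssociationModel(measurement, scores_a, predictors, **common).fit()
    weighted = FactorAssociationModel(
        measurement, scores_a, predictors, weights=weights, **common
    ).fit()

    comp = unweighted.table.merge(
        weighted.table, on=["factor", "predictor"], suffixes=("_unweighted", "_weighted")
    )
    comp["abs_shift"] = (comp["beta_weighted"] - comp["beta_unweighted"]).abs()
    return unweighted, weighted, comp


def comparison_summary(comp: pd.DataFrame) -> str:
    tab = comp[
        ["factor", "predictor", "beta_unweighted", "beta_weighted", "abs_shift"]
    ].copy()
    tab[["beta_unweighted", "beta_weighted", "abs_shift"]] = tab[
        ["beta_unweighted", "beta_weighted", "abs_shift"]
    ].round(3)
    return "IPW sensitivity (unweighted vs weighted betas)\n" + tab.to_string(index=False)
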