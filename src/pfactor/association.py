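"""Two-step structural association of polygenic scores (and sex) with the
latent factors.

Step 1 fixes the measurement model (a fitted :class:`~pfactor.cfa.BifactorResults`).
Step 2 estimates standardized effects of the predictors on each latent
factor with the measurement parameters frozen.  With Lambda and Theta fixed
and factor variances fixed at 1, the structural ML estimator reduces exactly
to (weighted) least squares of Bartlett factor scores on the predictors:
the GLS weighting (Lambda' Sigma^-1 Lambda)^-1 Lambda' Sigma^-1 equals the
Bartlett weights (Lambda' Theta^-1 Lambda)^-1 Lambda' Theta^-1 by the
Woodbury identity, and Bartlett scores are conditionally unbiased for the
factors.  Standard errors are casewise sandwich (robust) Wald SEs; optional
case weights enter the normal equations, the standardization, and the
sandwich meat.

A simpler regression-factor-score OLS mode is provided for cross-checks; it
is attenuation-prone (regression scores shrink toward zero) and is not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cfa import BifactorResults

CONDITION_LIMIT = 1e8


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mu = np.average(x, weights=w)
    var = np.average((x - mu) ** 2, weights=w)
    return mu, np.sqrt(var)


class FactorAssociationModel:
    """Regression of latent factors on standardized predictors with the
    measurement model fixed.

    Parameters
    ----------
    measurement : BifactorResults
        Converged step-1 measurement fit.
    scores : DataFrame
        person_id + the 12 scale scores (same scale as the measurement fit,
        i.e. standardized if the fit standardized).
    predictors : DataFrame
        person_id + predictor columns (PRS z-scores, sex, ...).
    prs_cols, covariate_cols :
        Predictors of interest vs. adjustment covariates.  Continuous
        predictors (more than two distinct values) are Z-standardized
        internally using the case weights; binary ones are left as coded.
    weights : Series or DataFrame, optional
        person_id-aligned positive case weights (IPW); default 1.
    mode : "fixed_measurement" (Bartlett-score ML) or "factor_score_ols".
    """

    def __init__(
        self,
        measurement: BifactorResults,
        scores: pd.DataFrame,
        predictors: pd.DataFrame,
        prs_cols: list[str] | None = None,
        covariate_cols: tuple[str, ...] = ("sex",),
        weights: pd.DataFrame | pd.Series | None = None,
        mode: str = "fixed_measurement",
    ):
        if not measurement.converged:
            raise ValueError("step-1 measurement model did not converge")
        if mode not in ("fixed_measurement", "factor_score_ols"):
            raise ValueError(f"unknown mode {mode!r}")
        self.measurement = measurement
        self.mode = mode
        self.prs_cols = list(prs_cols) if prs_cols is not None else [
            c for c in predictors.columns if c not in ("person_id", *covariate_cols)
        ]
        self.covariate_cols = [c for c in covariate_cols if c in predictors.columns]

        merged = scores.merge(predictors, on="person_id", how="inner")
        if weights is not None:
            if isinstance(weights, pd.Series):
                weights = weights.rename("weight").reset_index().rename(columns={"index": "person_id"})
            merged = merged.merge(weights[["person_id", "weight"]], on="person_id", how="inner")
        else:
            merged["weight"] = 1.0
        need = list(measurement.spec.items) + self.prs_cols + self.covariate_cols + ["weight"]
        self.frame = merged.dropna(subset=need).reset_index(drop=True)
        if len(self.frame) < len(self.prs_cols) + len(self.covariate_cols) + 2:
            raise ValueError("too few complete cases for the association model")
        self.weighted = weights is not None

    # ------------------------------------------------------------------
    def _design(self, cols: list[str]) -> np.ndarray:
        w = self.frame["weight"].to_numpy(dtype=float)
        Z = np.empty((len(self.frame), len(cols)))
        for j, c in enumerate(cols):
            x = self.frame[c].to_numpy(dtype=float)
            if len(np.unique(x)) > 2:
                mu, sd = _weighted_moments(x, w)
                x = (x - mu) / sd
            Z[:, j] = x
        # collinearity guard on the weighted predictor correlation matrix
        if Z.shape[1] >= 2:
            C = np.corrcoef(Z, rowvar=False)
            if np.linalg.cond(C) > CONDITION_LIMIT:
                off = np.abs(C - np.eye(len(cols)))
                i, j = np.unravel_index(off.argmax(), off.shape)
                raise ValueError(
                    f"collinear predictors: {cols[i]} and {cols[j]} (|r| = {off[i, j]:.4f})"
                )
        return Z

    def _outcomes(self) -> np.ndarray:
        method = "bartlett" if self.mode == "fixed_measurement" else "regression"
        fs = self.measurement.factor_scores(self.frame, method=method)
        return fs[list(self.measurement.spec.factors)].to_numpy(dtype=float)

    def _wls(self, Z: np.ndarray, y: np.ndarray, w: np.ndarray):
        X = np.column_stack([np.ones(len(Z)), Z])
        XtW = X.T * w
        A = XtW @ X
        beta = np.linalg.solve(A, XtW @ y)
        resid = y - X @ beta
        meat = X * ((w * resid) ** 2)[:, None]
        acov = np.linalg.solve(A, np.linalg.solve(A, X.T @ meat).T)
        se = np.sqrt(np.diag(acov))
        return beta, se, resid

    # ------------------------------------------------------------------
    def fit(self, predictors: list[str] | None = None, label: str = "multivariable"):
        """All predictors of interest entered simultaneously (plus covariates)."""
        cols = (predictors if predictors is not None else self.prs_cols) + self.covariate_cols
        Z = self._design(cols)
        w = self.frame["weight"].to_numpy(dtype=float)
        Y = self._outcomes()
        factors = list(self.measurement.spec.factors)
        rows, r2 = [], {}
        for f, fac in enumerate(factors):
            beta, se, _ = self._wls(Z, Y[:, f], w)
            b, s = beta[1:], se[1:]  # drop intercept
            p = 2.0 * norm.sf(np.abs(b / s))
            for j, c in enumerate(cols):
                rows.append(
                    {"factor": fac, "predictor": c, "beta": b[j], "se": s[j], "p": p[j]}
                )
            # explained latent-factor variance (factor variance fixed at 1)
            mu = np.average(Z, axis=0, weights=w)
            Zc = Z - mu
            cov_z = (Zc.T * w) @ Zc / w.sum()
            r2[fac] = float(b @ cov_z @ b)
        return AssociationResults(
            table=pd.DataFrame(rows),
            r2=pd.Series(r2, name="r2"),
            mode=label,
            estimator=self.mode,
            weighted=self.weighted,
            n=len(self.frame),
        )

    def fit_univariable(self):
        """Each predictor of interest separately (plus covariates)."""
        parts, r2_parts = [], []
        for c in self.prs_cols:
            res = self.fit(predictors=[c], label="univariable")
            tab = res.table[res.table["predictor"] == c]
            parts.append(tab)
            r2_parts.append(res.r2.rename(c))
        table = pd.concat(parts, ignore_index=True)
        r2 = pd.concat(r2_parts, axis=1)
        return AssociationResults(
            table=table,
            r2=r2,
            mode="univariable",
            estimator=self.mode,
            weighted=self.weighted,
            n=len(self.frame),
        )


@dataclass
class AssociationResults:
    """Per-factor standardized betas, robust SEs, p-values and R^2."""

    table: pd.DataFrame
    r2: pd.Series | pd.DataFrame
    mode: str
    estimator: str
    weighted: bool
    n: int

    def wide(self) -> pd.DataFrame:
        """Report layout: one row per factor, beta/se/p per predictor."""
        wide = self.table.pivot(index="factor", columns="predictor", values=["beta", "se", "p"])
        wide = wide.swaplevel(axis=1).sort_index(axis=1)
        if isinstance(self.r2, pd.Series):
            wide[("total", "r2")] = self.r2
        return wide

    def get(self, factor: str, predictor: str) -> pd.Series:
        row = self.table[(self.table["factor"] == factor) & (self.table["predictor"] == predictor)]
        if row.empty:
            raise KeyError((factor, predictor))
        return row.iloc[0]

    def summary(self) -> str:
        head = (
            f"{self.mode} association ({self.estimator}, "
            f"{'weighted' if self.weighted else 'unweighted'}, n = {self.n})"
        )
        tab = self.table.copy()
        tab[["beta", "se"]] = tab[["beta", "se"]].round(3)
        tab["p"] = tab["p"].map(lambda v: f"{v:.3g}")
        lines = [head, tab.to_string(index=False)]
        if isinstance(self.r2, pd.Series):
            lines += ["", "Total R^2 per factor:", self.r2.round(4).to_string()]
        return "\n".join(lines)
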