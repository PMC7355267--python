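"""Omega-family model-based reliability for a bifactor solution.

With standardized loadings (general column lambda_g, specific columns
lambda_s) and unique variances theta, for the unit-weight total composite:

    omega        = [ (sum lambda_g)^2 + sum_s (sum lambda_s)^2 ] / denom
    omega_H      =   (sum lambda_g)^2                            / denom
    denom        =   (sum lambda_g)^2 + sum_s (sum lambda_s)^2 + sum theta

and, per specific factor s restricted to its items,

    omega_S(s)   = [ (sum_s lambda_g)^2 + (sum lambda_s)^2 ] / subscale denom
    omega_HS(s)  =   (sum lambda_s)^2                        / subscale denom.

omega_H isolates the general factor's share of reliable composite variance;
omega_HS is the subscale analogue after removing the general factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OmegaSet:
    omega_total: float
    omega_hierarchical: float
    omega_subscale: dict[str, float]
    omega_hierarchical_subscale: dict[str, float]
    detail: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "omega": self.omega_total,
            "omega_h": self.omega_hierarchical,
            "omega_s": dict(self.omega_subscale),
            "omega_hs": dict(self.omega_hierarchical_subscale),
        }

    def __str__(self) -> str:
        lines = [
            f"omega (total)        = {self.omega_total:.3f}",
            f"omega_H (general)    = {self.omega_hierarchical:.3f}",
        ]
        for s, v in self.omega_subscale.items():
            lines.append(
                f"omega_S[{s}] = {v:.3f}   omega_HS[{s}] = {self.omega_hierarchical_subscale[s]:.3f}"
            )
        return "\n".join(lines)


def omega_from_matrices(
    lam: np.ndarray, theta: np.ndarray, factors, item_factor: np.ndarray
) -> OmegaSet:
    """Omega set from a loading matrix (general factor in column 0), unique
    variances, factor names, and each item's specific-factor column index
    (-1 for none)."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("inadmissible solution: non-positive unique variance")
    lam = np.asarray(lam, dtype=float)
    gen = lam[:, 0]
    gen_var = gen.sum() ** 2
    spec_vars = {}
    for f in range(1, lam.shape[1]):
        spec_vars[factors[f]] = lam[:, f].sum() ** 2
    denom = gen_var + sum(spec_vars.values()) + theta.sum()
    omega_total = (gen_var + sum(spec_vars.values())) / denom
    omega_h = gen_var / denom

    omega_s, omega_hs = {}, {}
    detail = {
        "general_variance": gen_var,
        "specific_variance": dict(spec_vars),
        "unique_variance": float(theta.sum()),
        "denominator": denom,
    }
    for f in range(1, lam.shape[1]):
        name = factors[f]
        on = item_factor == f
        if not on.any():
            continue
        g_sub = gen[on].sum() ** 2
        s_sub = lam[on, f].sum() ** 2
        d_sub = g_sub + s_sub + theta[on].sum()
        omega_s[name] = (g_sub + s_sub) / d_sub
        omega_hs[name] = s_sub / d_sub
        detail[f"subscale_{name}"] = {
            "general": g_sub,
            "specific": s_sub,
            "unique": float(theta[on].sum()),
            "denominator": d_sub,
        }
    return OmegaSet(float(omega_total), float(omega_h), omega_s, omega_hs, detail)


def omega(fit) -> OmegaSet:
    """Omega set for a fitted bifactor solution (standardized scale)."""
    if not fit.converged:
        raise ValueError("omega requires a converged fit")
    spec = fit.spec
    item_factor = np.full(len(spec.items), -1)
    for i, item in enumerate(spec.items):
        fac = spec.specific_of.get(item)
        if fac is not None:
            item_factor[i] = spec.factors.index(fac)
    return omega_from_matrices(fit.lam, fit.theta, list(spec.factors), item_factor)
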