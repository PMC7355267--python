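"""Synthetic cohort generator.

Emulates the statistical structure of a birth-cohort polygenic-score study of
childhood psychopathology: block-LD genotypes under Hardy–Weinberg, discovery
GWAS summary statistics with noise controlled by an effective discovery
sample size, latent bifactor phenotypes (a general factor plus orthogonal
emotional / behavioural / neurodevelopmental factors) measured through
ordinal parent-rated items, covariates (sex, family structure), item-level
missingness, and genotype availability that may depend on psychopathology.

Every stage stores its generating truth (true per-SNP effects, true latent
factors, true standardized polygenic values, continuous scale liabilities) so
downstream estimators can be tested against known parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .defaults import (
    DEFAULT_FACTOR_BETAS,
    DEFAULT_TRUE_LOADINGS,
    FACTORS,
    PRS_TRAITS,
    SCALE_NAMES,
)
from .scales import SCALES, item_columns, score_scales

_BASES = np.array(list("ACGT"))

SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]


@dataclass
class AvailabilityModel:
    """Logistic model for genotype availability.

    ``on="latent_p"`` uses the true general factor; ``on="observed_symptoms"``
    uses the Z-scored mean of the 12 prorated scale scores (what a cohort
    actually observes before genotyping).  The intercept is calibrated so the
    expected availability equals the configured target.
    """

    slope_p: float = -0.5
    slope_sex: float = 0.0
    on: str = "latent_p"  # or "observed_symptoms"


@dataclass
class SimulationConfig:
    """All knobs of the generator.  Defaults are the package's reference
    study conditions (cohort of ~10k children, 12 scales, four PRS)."""

    n_individuals: int = 10_000
    n_snps: int = 2_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_per_trait: int = 40
    effect_corr_matrix: np.ndarray = field(default_factory=lambda: np.eye(4))
    gwas_n: float = 50_000.0
    heritability: float = 0.2  # variance of the true polygenic value per trait
    true_loadings: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_LOADINGS.copy())
    factor_betas: np.ndarray = field(default_factory=lambda: DEFAULT_FACTOR_BETAS.copy())
    item_reliability: float = 0.7  # share of item-liability variance from the scale liability
    item_cutpoints: tuple[float, float] = (0.70, 0.90)  # liability quantiles for ordinal 1 and 2
    item_missing_rate: float = 0.02
    genotype_avail_model: AvailabilityModel = field(default_factory=AvailabilityModel)
    target_avail: float = 0.68
    ld_block_size: int = 50
    ld_r2_range: tuple[float, float] = (0.0, 0.95)
    family_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.effect_corr_matrix = np.asarray(self.effect_corr_matrix, dtype=float)
        self.true_loadings = np.asarray(self.true_loadings, dtype=float)
        self.factor_betas = np.asarray(self.factor_betas, dtype=float)
        R = self.effect_corr_matrix
        if R.shape != (4, 4) or not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("effect_corr_matrix must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("effect_corr_matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("effect_corr_matrix is not positive semi-definite")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 < self.target_avail <= 1):
            raise ValueError("target_avail must lie in (0, 1]")
        if self.true_loadings.shape != (len(SCALE_NAMES), len(FACTORS)):
            raise ValueError("true_loadings must be 12 scales x 4 factors")
        if np.any(self.true_loadings[:, 0] == 0):
            raise ValueError("every scale must have a nonzero general-factor loading")
        if self.factor_betas.shape != (len(FACTORS), len(PRS_TRAITS) + 1):
            raise ValueError("factor_betas must be 4 factors x 5 predictors (4 PRS + sex)")


@dataclass
class GenotypePanel:
    """Person x SNP dosage panel with variant metadata and LD-block truth."""

    person_ids: np.ndarray  # (n,)
    variants: pd.DataFrame  # SNP, CHR, BP, REF, ALT, AAF, block, block_r
    dosages: np.ndarray  # (n, m) values in [0, 2]; NaN = missing

    @property
    def n_individuals(self) -> int:
        return len(self.person_ids)

    @property
    def n_snps(self) -> int:
        return len(self.variants)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypePanel, list[pd.DataFrame]]:
    """Draw a genotype panel and four discovery-GWAS summary-statistic tables.

    Dosages are hard genotypes drawn as two haplotypes per person; within an
    LD block each haplotype allele copies the block's anchor SNP with
    probability r (drawn so r^2 is uniform over ``ld_r2_range``), giving known
    pairwise LD.  True per-SNP effects for the four traits are drawn jointly
    with correlation ``effect_corr_matrix`` at a shared causal set; observed
    effects add noise with variance set by ``gwas_n`` and two-sided normal
    p-values.  The true effect is retained in a ``TRUE_BETA`` column.
    """
    rng = _rng(config, 1)
    n, m = config.n_individuals, config.n_snps
    block_size = config.ld_block_size
    n_blocks = int(np.ceil(m / block_size))
    block_of = np.repeat(np.arange(n_blocks), block_size)[:m]

    lo, hi = config.maf_range
    maf_block = rng.uniform(lo, hi, size=n_blocks)
    r2lo, r2hi = config.ld_r2_range
    r_block = np.sqrt(rng.uniform(r2lo, r2hi, size=n_blocks))

    maf = maf_block[block_of]
    dosages = np.empty((n, m))
    for b in range(n_blocks):
        cols = np.nonzero(block_of == b)[0]
        p, r = maf_block[b], r_block[b]
        hap = np.empty((2, n, len(cols)))
        for h in range(2):
            anchor = rng.random(n) < p
            fresh = rng.random((n, len(cols))) < p
            copy = rng.random((n, len(cols))) < r
            hap[h] = np.where(copy, anchor[:, None], fresh)
        dosages[:, cols] = hap.sum(axis=0)

    # variant metadata: blocks laid out contiguously over autosomes
    chrom = (block_of * 22) // n_blocks + 1
    bp = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        bp[idx] = 10_000 + np.arange(len(idx)) * 1_500
    # alleles: a small fraction of strand-ambiguous (A/T, C/G) pairs survive,
    # as in a post-QC imputation panel, to exercise the harmonization drop
    ref_idx = rng.integers(0, 4, size=m)
    complement = np.array([3, 2, 1, 0])  # A<->T, C<->G
    ambiguous = rng.random(m) < 0.05
    shift = rng.integers(1, 4, size=m)
    alt_idx = (ref_idx + shift) % 4
    clash = alt_idx == complement[ref_idx]  # would be ambiguous by accident
    alt_idx[clash] = (alt_idx[clash] + 1) % 4
    alt_idx[alt_idx == ref_idx] = (alt_idx[alt_idx == ref_idx] + 2) % 4
    alt_idx[ambiguous] = complement[ref_idx[ambiguous]]
    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "CHR": chrom,
            "BP": bp,
            "REF": _BASES[ref_idx],
            "ALT": _BASES[alt_idx],
            "AAF": dosages.mean(axis=0) / 2.0,
            "block": block_of,
            "block_r": r_block[block_of],
        }
    )
    panel = GenotypePanel(
        person_ids=np.array([f"P{i:06d}" for i in range(n)]),
        variants=variants,
        dosages=dosages,
    )

    # true effects: shared causal set, jointly correlated across traits,
    # scaled so each trait's true polygenic value has variance `heritability`
    n_causal = min(config.n_causal_per_trait, m)
    beta_true = np.zeros((m, 4))
    if n_causal > 0:
        # causal variants are spread across LD blocks (at most one per block
        # until blocks are exhausted) so clumping retains distinct signals
        order = rng.permutation(m)
        by_block: dict[int, list[int]] = {}
        for j in order:
            by_block.setdefault(block_of[j], []).append(j)
        causal_list: list[int] = []
        depth = 0
        while len(causal_list) < n_causal:
            for b in sorted(by_block):
                if depth < len(by_block[b]):
                    causal_list.append(by_block[b][depth])
                    if len(causal_list) == n_causal:
                        break
            depth += 1
        causal = np.array(causal_list)
        L = np.linalg.cholesky(config.effect_corr_matrix + 1e-12 * np.eye(4))
        b_std = rng.standard_normal((n_causal, 4)) @ L.T
        b_std *= np.sqrt(config.heritability / n_causal)
        var_allele = 2.0 * maf[causal] * (1.0 - maf[causal])
        beta_true[causal] = b_std / np.sqrt(var_allele)[:, None]

    se = np.where(
        np.isfinite(config.gwas_n),
        1.0 / np.sqrt(np.maximum(config.gwas_n, 1.0) * 2.0 * maf * (1.0 - maf)),
        0.0,
    )
    sumstats = []
    for t, trait in enumerate(PRS_TRAITS):
        beta_hat = beta_true[:, t] + rng.standard_normal(m) * se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta_hat / se, np.where(beta_hat != 0, np.inf, 0.0))
        p = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
        tab = variants[["SNP", "CHR", "BP"]].copy()
        tab["A1"] = variants["ALT"]  # effect allele = panel alternate allele
        tab["A2"] = variants["REF"]
        tab["BETA"] = beta_hat
        tab["SE"] = se
        tab["P"] = p
        tab["TRUE_BETA"] = beta_true[:, t]
        tab.attrs["trait"] = trait
        sumstats.append(tab)
    return panel, sumstats


def true_polygenic_values(panel: GenotypePanel, sumstats: list[pd.DataFrame]) -> np.ndarray:
    """Standardized true polygenic value per person per trait (n x 4)."""
    out = np.empty((panel.n_individuals, len(sumstats)))
    for t, tab in enumerate(sumstats):
        g = panel.dosages @ tab["TRUE_BETA"].to_numpy()
        sd = g.std(ddof=0)
        out[:, t] = (g - g.mean()) / sd if sd > 0 else 0.0
    return out


def _phenotypes_from_predictors(
    prs_true: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    person_ids: np.ndarray,
) -> pd.DataFrame:
    n = len(person_ids)
    lam = config.true_loadings
    uniq = 1.0 - (lam**2).sum(axis=1)
    if np.any(uniq <= 0):
        bad = SCALE_NAMES[int(np.argmin(uniq))]
        raise ValueError(f"loadings imply non-positive unique variance for {bad}")

    sex = (rng.random(n) < 0.5).astype(float)  # female = 1
    Z = np.column_stack([prs_true, sex])

    # population predictor covariance: PRS unit variance with the configured
    # mutual correlations, sex Bernoulli(1/2) independent of PRS
    cov_z = np.zeros((5, 5))
    cov_z[:4, :4] = config.effect_corr_matrix
    cov_z[4, 4] = 0.25
    B = config.factor_betas
    var_sys = np.einsum("fi,ij,fj->f", B, cov_z, B)
    if np.any(var_sys >= 1.0):
        raise ValueError("factor_betas imply systematic variance >= 1 for some factor")
    resid_sd = np.sqrt(1.0 - var_sys)

    factors = Z @ B.T + rng.standard_normal((n, 4)) * resid_sd

    cohort = pd.DataFrame(
        {
            "person_id": person_ids,
            "family_id": [f"F{i:06d}" for i in range(n)],
            "birth_order": np.ones(n, dtype=int),
            "sex": sex.astype(int),
        }
    )
    for f, name in enumerate(FACTORS):
        cohort[f"f_{name}"] = factors[:, f]
    for t, trait in enumerate(PRS_TRAITS):
        cohort[f"prs_true_{trait}"] = prs_true[:, t]

    # continuous scale liabilities (unit variance), then ordinal items
    liab = factors @ lam.T + rng.standard_normal((n, len(SCALE_NAMES))) * np.sqrt(uniq)
    t1, t2 = norm.ppf(config.item_cutpoints[0]), norm.ppf(config.item_cutpoints[1])
    a = np.sqrt(config.item_reliability)
    b = np.sqrt(1.0 - config.item_reliability)
    item_cols: dict[str, np.ndarray] = {}
    for s, name in enumerate(SCALE_NAMES):
        cohort[f"liab_{name}"] = liab[:, s]
        k = SCALES[name].n_items
        item_liab = a * liab[:, [s] * k] + b * rng.standard_normal((n, k))
        ordinal = (item_liab > t1).astype(float) + (item_liab > t2)
        for j, col in enumerate(item_columns(name)):
            item_cols[col] = ordinal[:, j]
    cohort = pd.concat([cohort, pd.DataFrame(item_cols, index=cohort.index)], axis=1)

    # sibling structure: a small fraction of persons become the second-born
    # of another person's family, solely to exercise the oldest-sibling rule
    k = int(round(config.family_frac * n))
    if k > 0 and n >= 2 * k:
        chosen = rng.choice(n, size=2 * k, replace=False)
        older, younger = chosen[:k], chosen[k:]
        fam = cohort["family_id"].to_numpy().copy()
        fam[younger] = fam[older]
        cohort["family_id"] = fam
        bo = cohort["birth_order"].to_numpy().copy()
        bo[younger] = 2
        cohort["birth_order"] = bo

    cohort["genotype_available"] = True
    return cohort


def simulate_phenotypes(
    panel: GenotypePanel, sumstats: list[pd.DataFrame], config: SimulationConfig
) -> pd.DataFrame:
    """Latent factors, scale liabilities and ordinal items for the panel's
    individuals, driven by their true polygenic values and sex."""
    if panel.n_individuals != config.n_individuals:
        raise ValueError("panel size does not match config.n_individuals")
    prs_true = true_polygenic_values(panel, sumstats)
    return _phenotypes_from_predictors(prs_true, config, _rng(config, 2), panel.person_ids)


def simulate_cohort(config: SimulationConfig, genotypes: bool = True):
    """End-to-end convenience: returns ``(panel, sumstats, cohort)``.

    With ``genotypes=False`` the true standardized polygenic values are drawn
    directly as correlated normals (no panel, no summary stats) — the exact
    distribution the genotype route standardizes towards, at a fraction of
    the cost; used for phenotype-side studies at large n.
    """
    if genotypes:
        panel, sumstats = simulate_genotypes(config)
        cohort = simulate_phenotypes(panel, sumstats, config)
    else:
        rng0 = _rng(config, 3)
        L = np.linalg.cholesky(config.effect_corr_matrix + 1e-12 * np.eye(4))
        prs_true = rng0.standard_normal((config.n_individuals, 4)) @ L.T
        prs_true = (prs_true - prs_true.mean(axis=0)) / prs_true.std(axis=0)
        person_ids = np.array([f"P{i:06d}" for i in range(config.n_individuals)])
        panel, sumstats = None, None
        cohort = _phenotypes_from_predictors(prs_true, config, _rng(config, 2), person_ids)
    cohort = impose_missingness(cohort, config)
    return panel, sumstats, cohort


def impose_missingness(cohort: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Blank items at ``item_missing_rate`` and draw genotype availability
    from the configured logistic model, intercept-calibrated to
    ``target_avail``."""
    rng = _rng(config, 4)
    out = cohort.copy()
    rate = config.item_missing_rate
    if not (0.0 <= rate <= 1.0):
        warnings.warn(f"item_missing_rate {rate} clipped to [0, 1]", stacklevel=2)
        rate = float(np.clip(rate, 0.0, 1.0))

    cols = [c for c in out.columns if c.startswith("item_")]
    if rate > 0 and cols:
        block = out[cols].to_numpy(dtype=float)
        block[rng.random(block.shape) < rate] = np.nan
        out[cols] = block

    model = config.genotype_avail_model
    if model.on == "latent_p":
        driver = out["f_P"].to_numpy(dtype=float)
    elif model.on == "observed_symptoms":
        scored = score_scales(out)[list(SCALE_NAMES)].to_numpy(dtype=float)
        z = (scored - np.nanmean(scored, axis=0)) / np.nanstd(scored, axis=0)
        comp = np.nanmean(z, axis=1)
        comp = np.nan_to_num(comp, nan=0.0)
        driver = (comp - comp.mean()) / (comp.std() if comp.std() > 0 else 1.0)
    else:
        raise ValueError(f"unknown availability driver {model.on!r}")
    lin = model.slope_p * driver + model.slope_sex * out["sex"].to_numpy(dtype=float)

    if config.target_avail >= 1.0:
        avail = np.ones(len(out), dtype=bool)
    else:
        c0 = brentq(lambda c: expit(c + lin).mean() - config.target_avail, -30, 30)
        avail = rng.random(len(out)) < expit(c0 + lin)
    out["genotype_available"] = avail
    return out


__all__ = [
    "AvailabilityModel",
    "SimulationConfig",
    "GenotypePanel",
    "SUMSTAT_COLUMNS",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "impose_missingness",
    "true_polygenic_values",
    "replace",
]
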