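"""Polygenic risk scoring: allele harmonization, LD clumping to approximate
linkage equilibrium, p-value thresholding, weighted-mean scoring and
Z-standardization.

A score is the weighted mean number of risk alleles: after reorienting every
weight to its risk allele (so weights are positive), the raw score is
sum(weight * risk-allele dosage) / (2 * number of included SNPs with a
non-missing dosage for that person), then Z-standardized over scored persons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypePanel

log = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

DEFAULT_SWEEP = (0.001, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class PrsConfig:
    p_threshold: float = 0.05
    threshold_sweep: tuple[float, ...] = DEFAULT_SWEEP
    clump_window_kb: float = 250.0
    clump_r2: float = 0.1
    drop_ambiguous: bool = True

    def __post_init__(self) -> None:
        for t in (self.p_threshold, *self.threshold_sweep):
            if not (0 < t <= 1):
                raise ValueError(f"p-value threshold {t} outside (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must lie in [0, 1]")


class HarmonizationError(RuntimeError):
    pass


def harmonize_alleles(
    sumstats: pd.DataFrame, panel: GenotypePanel, drop_ambiguous: bool = True
) -> pd.DataFrame:
    """Orient summary-statistic effects to the panel's alternate allele.

    Effects whose effect allele (A1) equals the panel ALT keep their sign;
    those whose A1 equals the panel REF are negated; strand-ambiguous pairs
    (A/T, C/G) are dropped when requested; mismatching allele pairs and SNPs
    absent from the panel are dropped.  Per-category counts are logged and
    attached as ``.attrs['harmonization_counts']``.
    """
    pv = panel.variants.set_index("SNP")
    counts = {"kept": 0, "flipped": 0, "ambiguous": 0, "mismatch": 0, "not_in_panel": 0}
    rows = []
    for rec in sumstats.itertuples(index=False):
        if rec.SNP not in pv.index:
            counts["not_in_panel"] += 1
            continue
        var = pv.loc[rec.SNP]
        a1, a2 = str(rec.A1), str(rec.A2)
        if drop_ambiguous and frozenset((a1, a2)) in AMBIGUOUS_PAIRS:
            counts["ambiguous"] += 1
            continue
        if a1 == var["ALT"] and a2 == var["REF"]:
            beta = float(rec.BETA)
            counts["kept"] += 1
        elif a1 == var["REF"] and a2 == var["ALT"]:
            beta = -float(rec.BETA)
            counts["flipped"] += 1
        else:
            counts["mismatch"] += 1
            continue
        rows.append(
            {
                "SNP": rec.SNP,
                "CHR": int(var["CHR"]),
                "BP": int(var["BP"]),
                "BETA": beta,
                "SE": float(rec.SE),
                "P": float(rec.P),
                "col": int(pv.index.get_loc(rec.SNP)),
            }
        )
    log.info("allele harmonization: %s", counts)
    if not rows:
        raise HarmonizationError(f"no SNPs survived harmonization: {counts}")
    out = pd.DataFrame(rows)
    out.attrs["harmonization_counts"] = counts
    return out


def _dosage_r2(dosages: np.ndarray, i: int, cand: np.ndarray) -> np.ndarray:
    """Squared correlation between dosage column i and candidate columns."""
    x = dosages[:, i]
    Y = dosages[:, cand]
    ok = np.isfinite(x) & np.all(np.isfinite(Y), axis=1)
    x, Y = x[ok], Y[ok]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc @ xc) * (Yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (xc @ Yc) / denom, 0.0)
    return r**2


def ld_clump(effects: pd.DataFrame, panel: GenotypePanel, config: PrsConfig) -> list[str]:
    """Greedy p-value-ordered clumping.

    Repeatedly take the smallest-p unclaimed SNP as an index SNP and claim
    every unclaimed SNP on the same chromosome within the window whose
    dosage r^2 with the index is >= ``clump_r2``.  Ties on p break by
    (chromosome, position) ascending.  Returns the index-SNP ids in
    (chromosome, position) order.
    """
    if effects.empty:
        return []
    tab = effects.sort_values(["P", "CHR", "BP"], kind="mergesort").reset_index(drop=True)
    claimed = np.zeros(len(tab), dtype=bool)
    window = config.clump_window_kb * 1_000.0
    chrom = tab["CHR"].to_numpy()
    bp = tab["BP"].to_numpy()
    cols = tab["col"].to_numpy()
    kept_rows = []
    for i in range(len(tab)):
        if claimed[i]:
            continue
        claimed[i] = True
        kept_rows.append(i)
        cand = np.nonzero(
            (~claimed) & (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= window)
        )[0]
        if len(cand) == 0:
            continue
        r2 = _dosage_r2(panel.dosages, cols[i], cols[cand])
        claimed[cand[r2 >= config.clump_r2]] = True
    kept = tab.iloc[kept_rows].sort_values(["CHR", "BP"], kind="mergesort")
    return kept["SNP"].tolist()


class EmptyScoreError(RuntimeError):
    pass


def compute_prs(
    panel: GenotypePanel,
    effects: pd.DataFrame,
    retained: list[str],
    config: PrsConfig,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Score every person at one p-value threshold.

    Returns a frame with person_id, raw, z, n_snps, threshold.  Inclusion is
    strict (p < threshold); a threshold of 1.0 includes every retained SNP.
    """
    t = config.p_threshold if p_threshold is None else p_threshold
    sub = effects[effects["SNP"].isin(set(retained))]
    if t < 1.0:
        sub = sub[sub["P"] < t]
    if sub.empty:
        raise EmptyScoreError(f"no SNPs included at p-value threshold {t}")
    beta = sub["BETA"].to_numpy()
    cols = sub["col"].to_numpy()
    dos = panel.dosages[:, cols]
    # risk-allele orientation: negative weights flip to the other allele
    weights = np.abs(beta)
    risk_dos = np.where(beta < 0, 2.0 - dos, dos)
    present = np.isfinite(risk_dos)
    num = np.where(present, risk_dos * weights, 0.0).sum(axis=1)
    n_present = present.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_present > 0, num / (2.0 * n_present), np.nan)
    mu = np.nanmean(raw)
    sd = np.nanstd(raw)
    z = (raw - mu) / sd if sd > 0 else np.zeros_like(raw)
    return pd.DataFrame(
        {
            "person_id": panel.person_ids,
            "raw": raw,
            "z": z,
            "n_snps": len(sub),
            "threshold": t,
        }
    )


def threshold_sweep(
    panel: GenotypePanel,
    effects: pd.DataFrame,
    retained: list[str],
    config: PrsConfig,
) -> dict[float, pd.DataFrame]:
    """One PrsVector per threshold in the configured sweep."""
    if not config.threshold_sweep:
        raise ValueError("threshold sweep is empty")
    return {
        t: compute_prs(panel, effects, retained, config, p_threshold=t)
        for t in config.threshold_sweep
    }


def score_trait(
    panel: GenotypePanel,
    sumstats: pd.DataFrame,
    config: PrsConfig | None = None,
    p_threshold: float | None = None,
) -> pd.DataFrame:
    """Convenience: harmonize -> clump -> score at one threshold."""
    config = config or PrsConfig()
    effects = harmonize_alleles(sumstats, panel, drop_ambiguous=config.drop_ambiguous)
    retained = ld_clump(effects, panel, config)
    return compute_prs(panel, effects, retained, config, p_threshold=p_threshold)
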