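"""Scale scoring: proration of item-level responses and sample-cleaning rules.

Each symptom scale is scored as the mean of the answered items multiplied by
the scale's item count ("prorated score"), valid only when strictly less than
30% of the scale's items are missing.  Families contribute their oldest
sibling only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .defaults import ITEM_MAX, SCALE_ITEMS, SCALE_NAMES

MISSINGNESS_CAP = 0.30  # strict: a scale with >= 30% missing items is scored missing


@dataclass(frozen=True)
class ScaleDefinition:
    """One symptom scale: name, item count, per-item maximum, factor membership."""

    name: str
    n_items: int
    item_max: int
    factor: str  # "E" | "B" | "N"


SCALES: dict[str, ScaleDefinition] = {
    name: ScaleDefinition(name, n, ITEM_MAX, fac) for name, (n, fac) in SCALE_ITEMS.items()
}


def item_columns(scale: str) -> list[str]:
    """Column names holding the item responses of one scale."""
    return [f"item_{scale}_{j}" for j in range(SCALES[scale].n_items)]


def prorate(items, definition: ScaleDefinition) -> float:
    """Prorated scale score for one person.

    ``items`` holds the scale's responses, each 0..item_max or NaN.  Returns
    ``mean(answered) * n_items`` when the missing fraction is < 30%, else NaN.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (definition.n_items,):
        raise ValueError(
            f"{definition.name}: expected {definition.n_items} items, got {arr.shape}"
        )
    answered = ~np.isnan(arr)
    bad = answered & ((arr < 0) | (arr > definition.item_max) | (arr != np.round(arr)))
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"{definition.name}: response {arr[idx]} at item {idx} outside 0..{definition.item_max}"
        )
    missing_frac = 1.0 - answered.mean()
    if missing_frac >= MISSINGNESS_CAP:
        return float("nan")
    return float(arr[answered].mean() * definition.n_items)


def score_scales(cohort: pd.DataFrame) -> pd.DataFrame:
    """Prorate all 12 scales for every person.

    Expects the generator's item columns (``item_<scale>_<j>``); returns a
    frame indexed like ``cohort`` with ``person_id`` plus one prorated score
    column per scale.
    """
    out = pd.DataFrame({"person_id": cohort["person_id"].to_numpy()}, index=cohort.index)
    for name, definition in SCALES.items():
        cols = item_columns(name)
        block = cohort[cols].to_numpy(dtype=float)
        answered = ~np.isnan(block)
        if ((block < 0) | (block > definition.item_max))[answered].any():
            raise ValueError(f"{name}: item response outside 0..{definition.item_max}")
        n_ans = answered.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_ans = np.nansum(block, axis=1) / n_ans
        score = mean_ans * definition.n_items
        missing_frac = 1.0 - n_ans / definition.n_items
        score[missing_frac >= MISSINGNESS_CAP] = np.nan
        out[name] = score
    return out


def keep_oldest_sibling(cohort: pd.DataFrame) -> pd.DataFrame:
    """Retain one row per family: the lowest birth order.

    Singleton families pass through unchanged.  Duplicate (family, birth
    order) pairs are rejected — they make "oldest" ill-defined.
    """
    if cohort.empty:
        return cohort.copy()
    dup = cohort.duplicated(subset=["family_id", "birth_order"]).any()
    if dup:
        raise ValueError("duplicate (family_id, birth_order) pairs present")
    idx = cohort.groupby("family_id")["birth_order"].idxmin()
    return cohort.loc[np.sort(idx.to_numpy())].copy()


def standardize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Z-standardize each scale column (NaNs preserved); person_id untouched."""
    out = scores.copy()
    for name in SCALE_NAMES:
        col = out[name].to_numpy(dtype=float)
        mu = np.nanmean(col)
        sd = np.nanstd(col, ddof=1)
        out[name] = (col - mu) / sd
    return out
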