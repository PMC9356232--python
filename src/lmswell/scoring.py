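"""Questionnaire scoring and dual-continua mental-health classification.

Two instruments carry the two mental-health dimensions:

* **MHC-SF** (Mental Health Continuum–Short Form): 14 items on a 0–5
  frequency scale; emotional well-being items 1–3, social 4–8,
  psychological 9–14.  Keyes' diagnostic rule assigns *flourishing* when at
  least one emotional item and six or more of the eleven social+psychological
  items are experienced "almost every day" or "every day", *languishing* with
  the mirrored rule on "never"/"once or twice", and *moderate* otherwise.
* **K-MDI** (Korean Mental Disorder Inventory): 13 symptom-discomfort items
  on 0–4 plus one daily-life dysfunction item on 0–3; the disorder flag
  requires at least one high symptom AND a high dysfunction rating.

Crossing the (collapsed) well-being side with the disorder flag yields the
four dual-continua groups.  A 4-item academic-distress scale (CCAPS-34
subset, 0–4 each, summed to 0–16) is scored alongside as the subjective
adjustment outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EMOTIONAL_IDX = slice(0, 3)     # items 1-3
SOCIAL_PSYCH_IDX = slice(3, 14)  # items 4-14 (social 4-8, psychological 9-14)


class WellbeingCategory(str, Enum):
    FLOURISHING = "flourishing"
    MODERATE = "moderate"
    LANGUISHING = "languishing"


class MentalHealthGroup(str, Enum):
    """Four dual-continua groups from (well-being side) × (disorder flag)."""

    FLOURISHING_MODERATE = "flourishing_and_moderate"
    PURE_LANGUISHING = "pure_languishing"
    PURE_DISORDER = "pure_mental_disorder"
    DISORDER_LANGUISHING = "mental_disorder_and_languishing"


#: canonical ordering used by every table and report
GROUP_ORDER: tuple[MentalHealthGroup, ...] = (
    MentalHealthGroup.FLOURISHING_MODERATE,
    MentalHealthGroup.PURE_LANGUISHING,
    MentalHealthGroup.PURE_DISORDER,
    MentalHealthGroup.DISORDER_LANGUISHING,
)


@dataclass(frozen=True)
class ScoringThresholds:
    """Configurable cutoffs for the categorical rules.

    MHC-SF high/low follow Keyes' convention (high = 4–5, low = 0–1).  The
    K-MDI cutoffs are not published with the instrument's national-survey
    source; top-of-scale bands are used and surfaced here so reports can
    flag them.
    """

    mhcsf_high: int = 4   # item >= this counts as "high" (scale 0-5)
    mhcsf_low: int = 1    # item <= this counts as "low"
    mhcsf_n_items: int = 6  # of the 11 social+psychological items
    kmdi_symptom_high: int = 3     # symptom item >= this (scale 0-4)
    kmdi_dysfunction_high: int = 2  # dysfunction item >= this (scale 0-3)


DEFAULT_THRESHOLDS = ScoringThresholds()


def _check_items(items: Sequence[int], n: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (n,):
        raise ValueError(f"{name} requires exactly {n} items, got shape {arr.shape}")
    bad = np.nonzero((arr < lo) | (arr > hi))[0]
    if bad.size:
        raise ValueError(
            f"{name} item {bad[0] + 1} out of range [{lo}, {hi}]: {arr[bad[0]]}"
        )
    return arr


def score_mhcsf(
    items: Sequence[int], thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> tuple[int, WellbeingCategory]:
    """Total (0–70) and well-being category from the 14 MHC-SF items.

    If both the flourishing and languishing rules fire (possible only through
    disjoint high/low item subsets), the case is logged and resolved as
    moderate.
    """
    arr = _check_items(items, 14, 0, 5, "MHC-SF")
    total = int(arr.sum())
    emo, rest = arr[EMOTIONAL_IDX], arr[SOCIAL_PSYCH_IDX]
    t = thresholds
    flourishing = (emo >= t.mhcsf_high).any() and (rest >= t.mhcsf_high).sum() >= t.mhcsf_n_items
    languishing = (emo <= t.mhcsf_low).any() and (rest <= t.mhcsf_low).sum() >= t.mhcsf_n_items
    if flourishing and languishing:
        logger.warning("MHC-SF items %s satisfy both diagnostic rules; scored moderate", arr)
        return total, WellbeingCategory.MODERATE
    if flourishing:
        return total, WellbeingCategory.FLOURISHING
    if languishing:
        return total, WellbeingCategory.LANGUISHING
    return total, WellbeingCategory.MODERATE


def score_kmdi(
    symptom_items: Sequence[int],
    dysfunction_item: int,
    thresholds: ScoringThresholds = DEFAULT_THRESHOLDS,
) -> tuple[int, bool]:
    """Total over all 14 items and the binary disorder flag.

    Disorder requires BOTH at least one high symptom rating and a high
    dysfunction rating — discomfort without impairment does not qualify.
    """
    sym = _check_items(symptom_items, 13, 0, 4, "K-MDI symptom")
    if not 0 <= int(dysfunction_item) <= 3:
        raise ValueError(f"K-MDI dysfunction item out of range [0, 3]: {dysfunction_item}")
    total = int(sym.sum()) + int(dysfunction_item)
    t = thresholds
    disorder = bool(
        (sym >= t.kmdi_symptom_high).any() and dysfunction_item >= t.kmdi_dysfunction_high
    )
    return total, disorder


def score_ccaps(items: Sequence[int], as_mean: bool = False) -> float:
    """Academic distress: sum of the 4 CCAPS items (0–16).

    ``as_mean`` returns the 0–4 item mean instead, for CCAPS-34 convention
    compatibility; all descriptives here use the sum.
    """
    arr = _check_items(items, 4, 0, 4, "CCAPS")
    return float(arr.mean()) if as_mean else float(arr.sum())


def classify_dual_continua(
    wellbeing_category: WellbeingCategory, disorder: bool
) -> MentalHealthGroup:
    """Map (well-being side, disorder flag) to the four-group taxonomy.

    Flourishing and moderate are collapsed on the well-being dimension.
    """
    languishing = WellbeingCategory(wellbeing_category) == WellbeingCategory.LANGUISHING
    if disorder:
        return (
            MentalHealthGroup.DISORDER_LANGUISHING
            if languishing
            else MentalHealthGroup.PURE_DISORDER
        )
    return (
        MentalHealthGroup.PURE_LANGUISHING
        if languishing
        else MentalHealthGroup.FLOURISHING_MODERATE
    )


MHCSF_COLS = [f"mhcsf_{i}" for i in range(1, 15)]
KMDI_COLS = [f"kmdi_{i}" for i in range(1, 15)]
CCAPS_COLS = [f"ccaps_{i}" for i in range(1, 5)]


def score_survey_table(
    surveys: pd.DataFrame, thresholds: ScoringThresholds = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Score every row of an item-response table.

    Expects columns ``mhcsf_1..14``, ``kmdi_1..14`` (item 14 is the
    dysfunction item), ``ccaps_1..4``; returns the input plus totals,
    category, disorder flag, group label and academic distress.
    """
    missing = [c for c in MHCSF_COLS + KMDI_COLS + CCAPS_COLS if c not in surveys.columns]
    if missing:
        raise ValueError(f"survey table missing item columns: {missing}")
    out = surveys.copy()
    records = []
    for _, row in surveys.iterrows():
        total_wb, cat = score_mhcsf(row[MHCSF_COLS].to_numpy(dtype=int), thresholds)
        total_md, dis = score_kmdi(
            row[KMDI_COLS[:-1]].to_numpy(dtype=int), int(row[KMDI_COLS[-1]]), thresholds
        )
        records.append(
            {
                "mhcsf_total": total_wb,
                "wellbeing_category": cat.value,
                "kmdi_total": total_md,
                "disorder": dis,
                "group": classify_dual_continua(cat, dis).value,
                "academic_distress": score_ccaps(row[CCAPS_COLS].to_numpy(dtype=int)),
            }
        )
    return pd.concat([out.reset_index(drop=True), pd.DataFrame(records)], axis=1)


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's α internal consistency for an items-by-row matrix."""
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-d matrix with at least two items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1 - item_var / total_var))
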