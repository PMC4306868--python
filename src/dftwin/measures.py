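"""Construction of diet and physical-activity risk measures from raw survey items.

Raw inputs, one row per respondent:

- ``fastfood_days``: days with fast food in the past week (0-7);
- ``veg_1`` .. ``veg_12``: ate-this-vegetable-yesterday binaries;
- ``breakfast_days``, ``lunch_days``, ``dinner_days``: days each meal was
  eaten in the past week (0-7);
- ``sport_cat``, ``cycle_cat``, ``exercise_cat``: past-week activity
  frequency categories — 0 "not at all", 1 "1-2 times", 2 "3-4 times",
  3 "5 or more times".

Derived measures (higher = more at-risk): ``fast_food`` (validated
pass-through), ``low_veg`` (1 iff no vegetable eaten yesterday),
``meal_dep`` (proportion of 21 weekly meals skipped), ``low_sport`` /
``low_cycle`` / ``low_exercise`` (reverse-coded activity categories) and
``insuff_ex`` (1 iff fewer than five activity bouts per week across all
three items).

Missing values propagate: any required item missing (or out of range)
makes the derived value missing, and respondents drop from a model via
listwise deletion downstream, never by imputation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "meal_deprivation",
    "low_vegetable",
    "reverse_activity",
    "insufficient_exercise",
    "build_measures",
    "BOUT_MIDPOINTS",
    "VEG_COLUMNS",
    "DERIVED_COLUMNS",
]

VEG_COLUMNS = tuple(f"veg_{i}" for i in range(1, 13))
DERIVED_COLUMNS = (
    "fast_food",
    "low_veg",
    "meal_dep",
    "low_sport",
    "low_cycle",
    "low_exercise",
    "insuff_ex",
)

#: Bouts per week imputed to each frequency category when summing toward
#: the five-session guideline: interval midpoints for "1-2" and "3-4",
#: the guideline value itself for the open-ended "5 or more" category.
BOUT_MIDPOINTS: Mapping[int, float] = {0: 0.0, 1: 1.5, 2: 3.5, 3: 5.0}


def _validated(values, low: int, high: int) -> np.ndarray:
    """Float array with out-of-range or non-integer entries set to NaN."""
    arr = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < low) | (arr > high) | (arr != np.floor(arr))
    return np.where(bad, np.nan, arr)


def meal_deprivation(breakfast_days, lunch_days, dinner_days):
    """Proportion of the week's 21 main meals that were skipped.

    ``((7-b) + (7-l) + (7-d)) / 21`` for days-eaten counts in 0-7; 0 means
    every meal eaten, 1 means every meal skipped.  Accepts scalars or
    arrays; invalid or missing inputs yield NaN.
    """
    b = _validated(breakfast_days, 0, 7)
    l = _validated(lunch_days, 0, 7)
    d = _validated(dinner_days, 0, 7)
    out = ((7 - b) + (7 - l) + (7 - d)) / 21.0
    if out.ndim == 0:
        return float(out)
    return out


def low_vegetable(veg_flags):
    """1 iff none of the twelve vegetables was eaten yesterday.

    ``veg_flags`` is a length-12 sequence of 0/1 flags, or a 2-D array /
    DataFrame with twelve columns.  Any observed 1 forces 0 regardless of
    missingness; if every observed flag is 0 but some flag is missing the
    result is missing (consumption cannot be ruled out).
    """
    arr = np.asarray(veg_flags, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != len(VEG_COLUMNS):
        raise ValueError(f"expected {len(VEG_COLUMNS)} vegetable flags, got {arr.shape[1]}")
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(arr) & (arr != 0) & (arr != 1)
    arr = np.where(bad, np.nan, arr)
    any_eaten = np.nanmax(np.where(np.isnan(arr), -np.inf, arr), axis=1) == 1
    any_missing = np.isnan(arr).any(axis=1)
    out = np.where(any_eaten, 0.0, np.where(any_missing, np.nan, 1.0))
    return float(out[0]) if squeeze else out


def reverse_activity(category):
    """Reverse-code a 0-3 frequency category so higher = less active."""
    c = _validated(category, 0, 3)
    out = 3.0 - c
    if out.ndim == 0:
        return float(out)
    return out


def insufficient_exercise(sport_cat, cycle_cat, exercise_cat, bout_map: Mapping[int, float] = BOUT_MIDPOINTS):
    """1 iff fewer than five activity bouts per week across all three items.

    Raw (not reverse-coded) categories are mapped to weekly bout counts
    via ``bout_map`` and summed; the threshold follows the five-session
    physical-activity guideline.  Any missing item yields missing output.
    """
    lut = np.array([bout_map[k] for k in range(4)], dtype=float)
    total = np.zeros_like(_validated(sport_cat, 0, 3))
    missing = np.zeros_like(total, dtype=bool)
    for cat in (sport_cat, cycle_cat, exercise_cat):
        c = _validated(cat, 0, 3)
        miss = np.isnan(c)
        missing |= miss
        total = total + lut[np.where(miss, 0, c).astype(int)]
    out = np.where(missing, np.nan, (total < 5.0).astype(float))
    if out.ndim == 0:
        return float(out)
    return out


def build_measures(raw: pd.DataFrame) -> pd.DataFrame:
    """Append the seven derived risk measures to a raw survey table.

    Requires the raw item columns documented in the module docstring;
    identifier columns (``pair_id``, ``twin_index``, ``zygosity``,
    ``outcome``) pass through untouched when present.
    """
    needed = (
        ["fastfood_days", "breakfast_days", "lunch_days", "dinner_days",
         "sport_cat", "cycle_cat", "exercise_cat"] + list(VEG_COLUMNS)
    )
    missing_cols = [c for c in needed if c not in raw.columns]
    if missing_cols:
        raise KeyError(f"raw survey columns missing: {missing_cols}")

    out = raw.copy()
    out["fast_food"] = _validated(raw["fastfood_days"], 0, 7)
    out["low_veg"] = low_vegetable(raw[list(VEG_COLUMNS)].to_numpy())
    out["meal_dep"] = meal_deprivation(
        raw["breakfast_days"], raw["lunch_days"], raw["dinner_days"]
    )
    out["low_sport"] = reverse_activity(raw["sport_cat"])
    out["low_cycle"] = reverse_activity(raw["cycle_cat"])
    out["low_exercise"] = reverse_activity(raw["exercise_cat"])
    out["insuff_ex"] = insufficient_exercise(
        raw["sport_cat"], raw["cycle_cat"], raw["exercise_cat"]
    )
    return out
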