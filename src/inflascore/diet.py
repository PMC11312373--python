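"""Diet-quality scoring: the 0–6 healthy-diet covariate and three published
dietary-pattern indices (HEI-2020, Mediterranean, DASH).

The healthy-diet covariate awards one point per criterion met:

* red meat at most 3 times/week
* vegetables at least 4 tablespoons/day
* fruit at least 3 servings/day
* fish at least 4 times/week
* grains at least 5 servings/week
* urinary sodium at most 70.6 mmol/L

and flags a "healthy diet" at 3+ points.

The pattern indices follow their canonical published definitions:
HEI-2020 as 13 density-based components linearly interpolated between
published minimum/maximum standards (0–100); MED as a Trichopoulou-style
0–9 count against cohort sex-specific medians (moderate-alcohol range rule);
DASH as a Fung-style sum of cohort quintile ranks over 8 components
(8–40, sodium/red meat/sweets reversed).  The HEI component standards ship
as an editable CSV so alternative cut-offs can be swapped in.

Scores are returned as NaN for participants with incomplete diet data —
the missing-data signal that drops them from diet analyses while keeping
them in the main analyses.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .score import bin_exposure

HEALTHY_DIET_CRITERIA = (
    ("red_meat_wk", "le", 3.0),
    ("veg_tbsp_day", "ge", 4.0),
    ("fruit_serv_day", "ge", 3.0),
    ("fish_wk", "ge", 4.0),
    ("grains_serv_wk", "ge", 5.0),
    ("urinary_na_mmol", "le", 70.6),
)

#: beneficial MED components scored 1 when >= the sex-specific cohort median
MED_BENEFICIAL = (
    "med_veg_g",
    "med_legume_g",
    "med_fruit_nut_g",
    "med_cereal_g",
    "med_fish_g",
    "fatty_acid_ratio",
)
#: detrimental MED components scored 1 when < the sex-specific cohort median
MED_DETRIMENTAL = ("med_meat_g", "med_dairy_g")
#: moderate alcohol window (g/day) by sex
MED_ALCOHOL_RANGE = {"man": (10.0, 50.0), "woman": (5.0, 25.0)}

DASH_BENEFICIAL = (
    "dash_fruit",
    "dash_veg",
    "dash_nuts_legumes",
    "dash_whole_grains",
    "dash_lowfat_dairy",
)
DASH_ADVERSE = ("dash_sodium_mg", "dash_red_meat", "dash_sweets")


def load_hei_standards() -> pd.DataFrame:
    """Packaged HEI-2020 component standards (editable CSV)."""
    ref = importlib.resources.files("inflascore.data").joinpath("hei2020_standards.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def _require(intake: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in intake.columns]
    if missing:
        raise DataError(f"intake table is missing columns: {missing}")


def average_recalls(recalls: pd.DataFrame, id_col: str = "id") -> pd.DataFrame:
    """Average repeated 24-hour recalls (1–5 per participant) before scoring.

    ``recalls`` is long-format: one row per (participant, recall) with
    numeric intake columns.  Returns one row per participant with the
    per-column mean and an ``n_recalls`` count.
    """
    if id_col not in recalls.columns:
        raise DataError(f"recall table needs an {id_col!r} column")
    g = recalls.groupby(id_col, sort=True)
    out = g.mean(numeric_only=True)
    out["n_recalls"] = g.size()
    return out.reset_index()


def healthy_diet_score(intake: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """The 0–6 point healthy-diet covariate and its >=3-point flag.

    Rows with any missing component get NaN points and a <NA> flag.
    """
    _require(intake, [c for c, _, _ in HEALTHY_DIET_CRITERIA])
    pts = pd.Series(0.0, index=intake.index)
    complete = pd.Series(True, index=intake.index)
    for col, op, cut in HEALTHY_DIET_CRITERIA:
        x = pd.to_numeric(intake[col], errors="coerce")
        complete &= x.notna()
        met = (x <= cut) if op == "le" else (x >= cut)
        pts += met.astype(float)
    pts[~complete] = np.nan
    flag = (pts >= 3).astype("boolean")
    flag[~complete] = pd.NA
    return pts, flag


def hei2020_score(
    intake: pd.DataFrame, standards: pd.DataFrame | None = None
) -> pd.Series:
    """HEI-2020 total score (0–100).

    Adequacy components score ``max_points`` at/above the published
    standard density and 0 at the zero standard; moderation components
    reverse the direction.  Densities are per 1,000 kcal; ratio and
    percent-of-energy components are used as given.
    """
    std = load_hei_standards() if standards is None else standards
    _require(intake, ["energy_kcal", *std["column"]])
    energy = pd.to_numeric(intake["energy_kcal"], errors="coerce")
    per1000 = energy / 1000.0
    total = pd.Series(0.0, index=intake.index)
    complete = energy.notna() & (energy > 0)
    for row in std.itertuples(index=False):
        x = pd.to_numeric(intake[row.column], errors="coerce")
        complete &= x.notna()
        dens = x / per1000 if row.basis == "density" else x
        frac = (dens - row.std_zero) / (row.std_max - row.std_zero)
        total += row.max_points * frac.clip(0.0, 1.0)
    total[~complete] = np.nan
    return total


def med_score(intake: pd.DataFrame, sex: pd.Series) -> pd.Series:
    """Mediterranean diet score, 0–9, against sex-specific cohort medians.

    Six beneficial components (vegetables, legumes, fruit+nuts, cereal,
    fish, MUFA:SFA ratio) score 1 at/above the median of the same-sex
    cohort; meat and dairy score 1 below it; alcohol scores 1 inside the
    sex-specific moderate window.  Medians are computed on the rows passed
    in, so the score is defined relative to this analysis population.
    """
    cols = [*MED_BENEFICIAL, *MED_DETRIMENTAL, "alcohol_g"]
    _require(intake, cols)
    sex = pd.Series(sex, index=intake.index).astype(str)
    total = pd.Series(0.0, index=intake.index)
    complete = pd.Series(True, index=intake.index)
    for s in sex.unique():
        mask = sex == s
        sub = intake.loc[mask]
        for col in MED_BENEFICIAL + MED_DETRIMENTAL:
            x = pd.to_numeric(sub[col], errors="coerce")
            complete.loc[mask] &= x.notna()
            med = x.median()
            if col in MED_BENEFICIAL:
                total.loc[mask] += (x >= med).astype(float)
            else:
                total.loc[mask] += (x < med).astype(float)
        lo, hi = MED_ALCOHOL_RANGE.get(s, (10.0, 50.0))
        alc = pd.to_numeric(sub["alcohol_g"], errors="coerce")
        complete.loc[mask] &= alc.notna()
        total.loc[mask] += ((alc >= lo) & (alc <= hi)).astype(float)
    total[~complete] = np.nan
    return total


def dash_score(intake: pd.DataFrame) -> pd.Series:
    """DASH score, 8–40: sum of cohort quintile ranks over 8 components.

    Beneficial components (fruit, vegetables, nuts/legumes, whole grains,
    low-fat dairy) contribute their quintile rank 1–5; sodium, red/processed
    meat and sweets contribute the reversed rank (6 − quintile).
    """
    cols = [*DASH_BENEFICIAL, *DASH_ADVERSE]
    _require(intake, cols)
    total = pd.Series(0.0, index=intake.index)
    complete = pd.Series(True, index=intake.index)
    for col in cols:
        x = pd.to_numeric(intake[col], errors="coerce")
        complete &= x.notna()
    for col in cols:
        x = pd.to_numeric(intake[col], errors="coerce")
        filled = x.fillna(x.median())  # placeholder; incomplete rows end as NaN
        rank = bin_exposure(filled, k=5, prefix="Q").cat.codes.astype(float) + 1
        rank.index = intake.index
        if col in DASH_ADVERSE:
            rank = 6 - rank
        total += rank
    total[~complete] = np.nan
    return total


def bin_tertiles(scores, prefix: str = "T") -> pd.Series:
    """Tertile labels T1..T3 (lowest = T1); NaN scores stay unassigned."""
    s = pd.Series(scores)
    finite = s.notna().to_numpy()
    codes = np.full(len(s), -1, dtype=int)
    binned = bin_exposure(s[finite].to_numpy(), k=3, prefix=prefix)
    codes[finite] = binned.cat.codes.to_numpy()
    cat = pd.Categorical.from_codes(
        codes, categories=[f"{prefix}{i}" for i in (1, 2, 3)], ordered=True
    )
    return pd.Series(cat, index=s.index)
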