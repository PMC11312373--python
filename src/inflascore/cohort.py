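"""Seed-reproducible synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, in
place of the application-gated biobank data: baseline demographics and
biomarker marginals matched to the study's overall baseline table,
correlated diet and inflammation through a shared latent "lifestyle"
factor, a proportional-hazards event process driven by the participant's
eventual INFLA-Score quartile, and censoring as the minimum of loss to
follow-up, death and a fixed administrative date.

Biomarkers are drawn through a Gaussian factor copula: each marker's
normal coordinate is ``w·(λ·L + γ·F) + √(1−w²(λ²+γ²))·ε`` with L the
lifestyle factor (shared with diet intakes), F a common between-marker
factor, and w the marker loading (negative for lymphocytes so that higher
latent inflammation raises the neutrophil-to-lymphocyte ratio).  The
normal coordinate is mapped through its CDF onto a log-normal (CRP) or
gamma (cell counts) marginal and truncated at a clinically plausible cap.

Event times are Weibull increments from baseline,
``t = scale · (E / e^lp)^{1/shape}`` with E ~ Exp(1) and the linear
predictor lp the sum of the quartile effect and any configured covariate
effects, so the exposure groups obey exact proportional hazards and the
exponential special case (shape 1) has a closed-form rate ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DataError
from .config import MARKER_LOADINGS, CohortConfig
from .score import bin_exposure, compute_infla_score, compute_nlr, fit_decile_map

_DATE_COLS = ("baseline_date", "death_date", "loss_date")

COLUMNS = [
    "id", "sex", "sex_male", "age_baseline", "baseline_date",
    "crp", "wbc", "plt", "neut", "lymph",
    "bmi", "met_minutes", "townsend",
    "race_british", "smoking", "smoking_previous", "smoking_current",
    "drinking_current", "hypertension", "cvd", "cancer", "diabetes",
    "respiratory", "mineral_supp", "vitamin_supp", "nsaid_use",
    "chol_bp_dm_med",
    "n_recalls",
    "red_meat_wk", "veg_tbsp_day", "fruit_serv_day", "fish_wk",
    "grains_serv_wk", "urinary_na_mmol",
    "energy_kcal", "fruit_total_cup", "fruit_whole_cup", "veg_total_cup",
    "greens_beans_cup", "whole_grains_oz", "refined_grains_oz", "dairy_cup",
    "protein_oz", "seafood_plant_oz", "sodium_g", "added_sugar_pct_energy",
    "sat_fat_pct_energy", "fatty_acid_ratio",
    "med_veg_g", "med_legume_g", "med_fruit_nut_g", "med_cereal_g",
    "med_fish_g", "med_meat_g", "med_dairy_g", "alcohol_g",
    "dash_fruit", "dash_veg", "dash_nuts_legumes", "dash_whole_grains",
    "dash_lowfat_dairy", "dash_sodium_mg", "dash_red_meat", "dash_sweets",
    "infla_score", "infla_q",
    "death_date", "death_cause_icd10", "loss_date",
    "hospital_dates", "hospital_icd10",
]

#: illustrative default ICD-10 categories for age-related hospitalizations;
#: studies should supply their own disease list via configuration.
DEFAULT_AGING_CODES = [
    "I20-I25", "I48", "I50", "I60-I64", "I70", "J40-J44", "E10-E14",
    "N18", "M15-M19", "M80-M81", "G20", "G30", "H25", "C18", "C34",
    "C50", "C61", "K57", "E78", "F00-F03", "I10-I15", "J18", "N40",
]
_AGING_SAMPLE = ["I25", "I48", "I50", "I63", "J44", "E11", "N18", "M16",
                 "M81", "G30", "H25", "C18", "C34", "C61", "K57", "I10"]


def _marginal_ppf(u: np.ndarray, params: dict) -> np.ndarray:
    mean, sd = params["mean"], params["sd"]
    if params.get("dist", "gamma") == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        x = np.exp(mu + np.sqrt(sigma2) * stats.norm.ppf(u))
    else:
        shape = (mean / sd) ** 2
        scale = mean / shape
        x = stats.gamma.ppf(u, a=shape, scale=scale)
    return np.clip(x, 1e-3, params.get("cap", np.inf))


def _weibull_time(rng, n, shape, scale, lp, cap=200.0):
    # times are capped far beyond the administrative horizon so calendar
    # arithmetic stays in-range; capped times are always censored anyway
    e = rng.exponential(size=n)
    return np.minimum(scale * (e / np.exp(lp)) ** (1.0 / shape), cap)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table (one row per participant).

    ``seed`` overrides ``config.seed`` when given.  The returned frame has
    the full column schema even when ``n_participants`` is zero.
    """
    config.validate()
    n = config.n_participants
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["id"] = np.arange(1, n + 1)
    male = rng.random(n) < config.prop_male
    df["sex"] = np.where(male, "man", "woman")
    df["sex_male"] = male.astype(int)
    lo, hi = config.age_range
    df["age_baseline"] = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, n)), lo, hi
    ).astype(int)
    start = pd.Timestamp(config.baseline_start)
    span = (pd.Timestamp(config.baseline_end) - start).days
    df["baseline_date"] = start + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")

    # --- latent factors and biomarkers ------------------------------------
    lam, g = config.diet_inflammation_loading, config.cross_marker_loading
    lifestyle = rng.normal(size=n)
    common = rng.normal(size=n)
    shared = lam * lifestyle + g * common
    shared_var = lam * lam + g * g
    for m, params in config.biomarker_params.items():
        w = MARKER_LOADINGS.get(m, 1.0)
        resid_sd = np.sqrt(max(1.0 - w * w * shared_var, 1e-9))
        z = w * shared + resid_sd * rng.normal(size=n)
        df[m] = _marginal_ppf(stats.norm.cdf(z), params)

    # --- covariates --------------------------------------------------------
    df["bmi"] = np.clip(rng.normal(27.4, 4.8, n), 15, 60)
    df["met_minutes"] = rng.gamma(1.5, 800.0, n)
    df["townsend"] = np.clip(rng.normal(-1.32, 3.08, n), -8, 12)
    prev = config.covariate_prevalences
    p_cur, p_prev = prev["smoking_current"], prev["smoking_previous"]
    u = rng.random(n)
    df["smoking"] = np.select(
        [u < p_cur, u < p_cur + p_prev], ["current", "previous"], default="never"
    )
    df["smoking_previous"] = (df["smoking"] == "previous").astype(int)
    df["smoking_current"] = (df["smoking"] == "current").astype(int)
    for flag in ("race_british", "drinking_current", "hypertension", "cvd",
                 "cancer", "diabetes", "respiratory", "mineral_supp",
                 "vitamin_supp", "nsaid_use", "chol_bp_dm_med"):
        df[flag] = (rng.random(n) < prev[flag]).astype(int)

    # --- diet --------------------------------------------------------------
    has_diet = rng.random(n) < config.diet_recall_fraction
    df["n_recalls"] = np.where(has_diet, 1 + rng.binomial(4, 0.4, n), 0)

    def logn(mu, sd, loading=0.0):
        return np.exp(mu + loading * lifestyle + sd * rng.normal(size=n))

    for col, (mu, sd, loading) in config.diet_component_params.items():
        df[col] = logn(mu, sd, loading)

    df["energy_kcal"] = np.clip(rng.normal(2100, 450, n), 800, 5000)
    df["fruit_total_cup"] = 0.5 * df["fruit_serv_day"] * logn(0.0, 0.2)
    df["fruit_whole_cup"] = df["fruit_total_cup"] * np.clip(rng.beta(4, 2, n), 0.05, 1)
    df["veg_total_cup"] = 0.35 * df["veg_tbsp_day"] * logn(0.0, 0.2)
    df["greens_beans_cup"] = 0.25 * df["veg_total_cup"] * logn(0.0, 0.5)
    df["whole_grains_oz"] = logn(np.log(0.9), 0.6, -0.15)
    df["refined_grains_oz"] = logn(np.log(5.0), 0.4, +0.10)
    df["dairy_cup"] = logn(np.log(1.6), 0.5)
    df["protein_oz"] = logn(np.log(5.5), 0.35)
    df["seafood_plant_oz"] = logn(np.log(1.0), 0.7, -0.10)
    df["sodium_g"] = logn(np.log(2.6), 0.30, +0.10)
    df["added_sugar_pct_energy"] = np.clip(logn(np.log(11.0), 0.40, +0.12), 0, 45)
    df["sat_fat_pct_energy"] = np.clip(logn(np.log(10.5), 0.25, +0.08), 2, 30)
    mufa = logn(np.log(13.0), 0.30, -0.05)
    pufa = logn(np.log(6.5), 0.35, -0.05)
    sfa = df["sat_fat_pct_energy"] * df["energy_kcal"] / 900.0
    df["fatty_acid_ratio"] = (mufa + pufa) / sfa

    df["med_veg_g"] = df["veg_total_cup"] * 150.0 * logn(0.0, 0.1)
    df["med_legume_g"] = logn(np.log(18.0), 0.8, -0.10)
    df["med_fruit_nut_g"] = df["fruit_total_cup"] * 140.0 + logn(np.log(8.0), 0.9, -0.10)
    df["med_cereal_g"] = (df["whole_grains_oz"] + df["refined_grains_oz"]) * 28.0 * logn(0.0, 0.15)
    df["med_fish_g"] = df["fish_wk"] * 100.0 / 7.0
    df["med_meat_g"] = df["red_meat_wk"] * 120.0 / 7.0 * logn(0.0, 0.2)
    df["med_dairy_g"] = df["dairy_cup"] * 240.0
    drinker = rng.random(n) > 0.08
    df["alcohol_g"] = np.where(drinker, logn(np.log(12.0), 0.8), 0.0)

    df["dash_fruit"] = df["fruit_serv_day"]
    df["dash_veg"] = df["veg_total_cup"] * 2.0
    df["dash_nuts_legumes"] = (df["med_legume_g"] + 0.3 * df["seafood_plant_oz"] * 28) / 30.0
    df["dash_whole_grains"] = df["whole_grains_oz"]
    df["dash_lowfat_dairy"] = df["dairy_cup"] * np.clip(rng.beta(3, 2, n), 0.02, 1)
    df["dash_sodium_mg"] = df["sodium_g"] * 1000.0
    df["dash_red_meat"] = df["red_meat_wk"] / 7.0
    df["dash_sweets"] = logn(np.log(1.2), 0.6, +0.10)

    diet_cols = [c for c in COLUMNS if c in df.columns and c not in
                 ("id", "sex", "sex_male", "age_baseline", "baseline_date",
                  "crp", "wbc", "plt", "neut", "lymph", "bmi", "met_minutes",
                  "townsend", "race_british", "smoking", "smoking_previous",
                  "smoking_current", "drinking_current", "hypertension", "cvd",
                  "cancer", "diabetes", "respiratory", "mineral_supp",
                  "vitamin_supp", "nsaid_use", "chol_bp_dm_med", "n_recalls")]
    df.loc[~has_diet, diet_cols] = np.nan

    # --- exposure: the eventual INFLA quartile drives the hazard -----------
    panel = df[["crp", "wbc", "plt", "neut", "lymph"]].copy()
    panel["nlr"] = compute_nlr(panel["neut"], panel["lymph"])
    dmap = fit_decile_map(panel)
    df["infla_score"] = compute_infla_score(panel, dmap)["infla_score"]
    df["infla_q"] = bin_exposure(df["infla_score"], k=4)

    lp_death = np.array([config.true_log_hrs[q] for q in df["infla_q"].astype(str)])
    lp_hosp = np.array([config.hosp_log_hrs.get(q, 0.0) for q in df["infla_q"].astype(str)])
    centers = {"age_baseline": config.age_mean, "sex_male": config.prop_male}
    for cov, beta in config.covariate_log_hrs.items():
        lp_death = lp_death + beta * (df[cov].to_numpy(float) - centers.get(cov, 0.0))
    for cov, beta in config.hosp_covariate_log_hrs.items():
        lp_hosp = lp_hosp + beta * (df[cov].to_numpy(float) - centers.get(cov, 0.0))

    bh, hh = config.baseline_hazard, config.hosp_hazard
    t_death = _weibull_time(rng, n, bh["shape"], bh["scale"], lp_death)
    t_hosp = _weibull_time(rng, n, hh["shape"], hh["scale"], lp_hosp)

    df["death_date"] = df["baseline_date"] + pd.to_timedelta(
        np.round(t_death * 365.25), unit="D"
    )
    causes = list(config.death_cause_weights)
    wts = np.array(list(config.death_cause_weights.values()), float)
    df["death_cause_icd10"] = rng.choice(causes, size=n, p=wts / wts.sum())

    if config.loss_to_followup_rate > 0:
        t_loss = np.minimum(
            rng.exponential(1.0 / config.loss_to_followup_rate, n), 200.0
        )
        df["loss_date"] = df["baseline_date"] + pd.to_timedelta(
            np.round(t_loss * 365.25), unit="D"
        )
    else:
        df["loss_date"] = pd.NaT

    # hospitalization record lists: the aging-related admission plus an
    # occasional unrelated one, newline-free strings for CSV round-tripping
    aging_code = rng.choice(_AGING_SAMPLE, size=n)
    hosp_date = df["baseline_date"] + pd.to_timedelta(np.round(t_hosp * 365.25), unit="D")
    other = rng.random(n) < 0.15
    t_other = np.minimum(rng.exponential(40.0, n), 200.0)
    other_date = df["baseline_date"] + pd.to_timedelta(np.round(t_other * 365.25), unit="D")
    dates, codes = [], []
    admin = pd.Timestamp(config.admin_censor_date)
    for i in range(n):
        d, c = [], []
        if hosp_date.iloc[i] <= admin:
            d.append(hosp_date.iloc[i].date().isoformat())
            c.append(aging_code[i])
        if other[i] and other_date.iloc[i] <= admin:
            d.append(other_date.iloc[i].date().isoformat())
            c.append("Z51")
        dates.append(";".join(d))
        codes.append(";".join(c))
    df["hospital_dates"] = dates
    df["hospital_icd10"] = codes

    return df[COLUMNS]


def split_record_list(joined: str) -> list[str]:
    """Split the semicolon-joined hospitalization record columns."""
    if joined is None or (isinstance(joined, float) and np.isnan(joined)) or joined == "":
        return []
    return str(joined).split(";")


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """RFC-4180 CSV with ISO-8601 dates; round-trips via read_cohort_csv."""
    out = df.copy()
    for c in _DATE_COLS:
        if c in out.columns:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    # %.17g + round_trip parsing makes the float round trip lossless, so a
    # stage rerun from cached CSVs reproduces downstream tables exactly
    out.to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in _DATE_COLS:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


def cohort_summary(
    df: pd.DataFrame, premature: pd.Series | None = None
) -> pd.DataFrame:
    """Baseline-characteristics report, optionally split by premature death.

    Continuous variables are shown as ``mean ± SD``, binary flags and
    categorical variables as ``n (%)`` per level.  Raises
    :class:`DataError` for an empty table.
    """
    if len(df) == 0:
        raise DataError("cannot summarise an empty cohort")

    groups = {"Overall": df}
    if premature is not None:
        flag = pd.Series(premature).astype(bool)
        groups["Non-premature death"] = df.loc[~flag.to_numpy()]
        groups["Premature death"] = df.loc[flag.to_numpy()]

    continuous = ["age_baseline", "bmi", "met_minutes", "townsend",
                  "crp", "wbc", "plt", "neut", "lymph"]
    binary = ["race_british", "drinking_current", "hypertension", "cvd",
              "cancer", "diabetes", "respiratory", "mineral_supp",
              "vitamin_supp", "nsaid_use", "chol_bp_dm_med"]

    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        row = {"variable": var}
        for name, sub in groups.items():
            x = pd.to_numeric(sub[var], errors="coerce")
            sd = x.std(ddof=1)
            row[name] = f"{x.mean():.4g} ± {0.0 if np.isnan(sd) else sd:.3g}"
        rows.append(row)
    if "sex" in df.columns:
        for level in ("man", "woman"):
            row = {"variable": f"sex={level}"}
            for name, sub in groups.items():
                k = int((sub["sex"] == level).sum())
                row[name] = f"{k} ({100 * k / max(len(sub), 1):.1f}%)"
            rows.append(row)
    if "smoking" in df.columns:
        for level in ("never", "previous", "current"):
            row = {"variable": f"smoking={level}"}
            for name, sub in groups.items():
                k = int((sub["smoking"] == level).sum())
                row[name] = f"{k} ({100 * k / max(len(sub), 1):.1f}%)"
            rows.append(row)
    for var in binary:
        if var not in df.columns:
            continue
        row = {"variable": var}
        for name, sub in groups.items():
            k = int(pd.to_numeric(sub[var], errors="coerce").fillna(0).sum())
            row[name] = f"{k} ({100 * k / max(len(sub), 1):.1f}%)"
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["group_sizes"] = {name: len(sub) for name, sub in groups.items()}
    return out
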