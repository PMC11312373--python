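"""Cox proportional-hazards analysis of quartile exposures.

The estimand throughout is the hazard ratio (HR) of an outcome (age-related
hospitalization or premature death) for each exposure quartile versus the
lowest quartile Q1, with Wald 95% confidence intervals exp(β ± 1.96·SE),
a Wald trend test over the ordinal quartile coding 1..k, and a restricted
cubic spline (RCS) dose-response curve with a likelihood-ratio test of
nonlinearity.

Partial-likelihood maximisation is delegated to ``statsmodels`` PHReg,
which implements both the Efron (default; appropriate for the heavy ties
produced by coarse time units) and Breslow tie corrections.  The RCS basis
is the natural-spline parameterisation of Harrell: piecewise cubic between
knots, linear beyond the boundary knots, giving k−1 degrees of freedom for
k knots (default 4 knots at the 5th/35th/65th/95th percentiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigError, DataError, FitError

Z95 = float(stats.norm.ppf(0.975))

#: full covariate adjustment set used in the primary models, in the order
#: the columns appear in the synthetic cohort.
DEFAULT_ADJUSTMENT = (
    "age_baseline",
    "sex_male",
    "race_british",
    "smoking_previous",
    "smoking_current",
    "drinking_current",
    "bmi",
    "met_minutes",
    "townsend",
    "healthy_diet",
    "hypertension",
    "mineral_supp",
    "vitamin_supp",
    "nsaid_use",
    "chol_bp_dm_med",
    "cvd",
    "cancer",
    "diabetes",
    "respiratory",
)


@dataclass
class ModelSpec:
    """What to fit: outcome, exposure, adjustment, ties, spline settings."""

    outcome: str = "premature_death"  # or "hospitalization"
    exposure: str = "infla_q"
    adjust: tuple[str, ...] = DEFAULT_ADJUSTMENT
    stratify_by: str | None = None
    ties: str = "efron"
    n_knots: int = 4
    knot_percentiles: tuple[float, ...] = (5.0, 35.0, 65.0, 95.0)

    def __post_init__(self):
        if self.ties not in ("efron", "breslow"):
            raise ConfigError("ties must be 'efron' or 'breslow'")
        if self.stratify_by is not None and self.stratify_by in self.adjust:
            self.adjust = tuple(c for c in self.adjust if c != self.stratify_by)

    @property
    def time_col(self) -> str:
        return "time" if self.outcome == "premature_death" else "hosp_time"

    @property
    def event_col(self) -> str:
        return "event" if self.outcome == "premature_death" else "hosp_event"


@dataclass
class HazardRatioEstimate:
    """One HR with its Wald CI; the tidy-row unit of every results table."""

    term: str
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    p: float
    n_events: int
    n_total: int
    stratum: str = ""

    def as_row(self) -> dict:
        return self.__dict__.copy()


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        if c not in df.columns:
            raise DataError(f"missing covariate column {c!r}")
        col = df[c]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
        else:
            X[c] = pd.to_numeric(col).astype(float)
    return X


def cox_fit(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates,
    ties: str = "efron",
) -> pd.DataFrame:
    """Fit a Cox model; tidy per-term output.

    Returns one row per design column: ``term, coef, log_hr_se, hr,
    ci_low, ci_high, p``.  Raises :class:`FitError` for zero events,
    constant covariates, or non-convergence/separation (detected as
    non-finite or absurd standard errors).
    """
    from statsmodels.duration.hazard_regression import PHReg

    time = pd.to_numeric(df[time_col]).to_numpy(float)
    event = pd.to_numeric(df[event_col]).to_numpy(float)
    if len(df) == 0:
        raise FitError("empty table")
    if event.sum() < 1:
        raise FitError("no events in data")
    X = _design(df, covariates)
    sd = X.to_numpy(float).std(axis=0)
    const = [c for c, s in zip(X.columns, sd) if s == 0]
    if const:
        raise FitError(f"constant covariate(s): {const}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = PHReg(time, X.to_numpy(float), status=event, ties=ties)
            res = model.fit(disp=False)
        except Exception as exc:  # pragma: no cover - backend-specific failures
            raise FitError(f"Cox fit failed: {exc}") from exc
    beta = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)) or np.any(se > 50):
        raise FitError("Cox fit did not converge (possible complete separation)")
    out = pd.DataFrame(
        {
            "term": list(X.columns),
            "coef": beta,
            "log_hr_se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - Z95 * se),
            "ci_high": np.exp(beta + Z95 * se),
            "p": 2 * stats.norm.sf(np.abs(beta / se)),
        }
    )
    out.attrs["n_total"] = int(len(df))
    out.attrs["n_events"] = int(event.sum())
    out.attrs["loglik"] = float(res.model.loglike(res.params))
    out.attrs["cov"] = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return out


def trend_test(
    df: pd.DataFrame,
    time_col: str,
    event_col: str,
    exposure_col: str,
    adjust=(),
    ties: str = "efron",
) -> tuple[float, float]:
    """Wald trend test: exposure recoded as a single ordinal term 1..k.

    Returns (coefficient, p-value).
    """
    codes = pd.Series(pd.Categorical(df[exposure_col]).codes, index=df.index)
    if (codes < 0).any():
        raise DataError("exposure has unassigned categories")
    if codes.nunique() < 2:
        raise FitError("trend test needs >= 2 exposure levels")
    work = df.copy()
    work["_ordinal"] = codes.astype(float) + 1.0
    fit = cox_fit(work, time_col, event_col, ["_ordinal", *adjust], ties=ties)
    row = fit.loc[fit["term"] == "_ordinal"].iloc[0]
    return float(row["coef"]), float(row["p"])


def prune_inestimable(df: pd.DataFrame, event_col: str, adjust) -> tuple[str, ...]:
    """Drop adjustment covariates the data cannot identify.

    A binary flag with no variation, or with zero events on one of its
    levels, has an unbounded partial-likelihood maximum (quasi-separation);
    such covariates are removed rather than letting the fit run off to
    infinity.  Continuous covariates are kept unless constant.
    """
    event = pd.to_numeric(df[event_col]).to_numpy(float)
    keep = []
    for c in adjust:
        x = pd.to_numeric(df[c], errors="coerce").to_numpy(float)
        vals = np.unique(x[np.isfinite(x)])
        if vals.size < 2:
            continue
        if set(vals) <= {0.0, 1.0}:
            if event[x == 1].sum() == 0 or event[x == 0].sum() == 0:
                continue
        keep.append(c)
    return tuple(keep)


def quartile_fit(
    df: pd.DataFrame,
    spec: ModelSpec,
    stratum_label: str = "",
    prune: bool = True,
) -> pd.DataFrame:
    """HRs for exposure quartiles (Q2..Qk vs Q1) under the spec's adjustment.

    The returned tidy table has one row per non-reference quartile plus the
    reference row (HR 1), with ``p_trend``, ``n_events`` and ``n_total`` in
    ``DataFrame.attrs``.
    """
    exp_col = spec.exposure
    levels = list(pd.Categorical(df[exp_col]).categories)
    if len(levels) < 2:
        raise FitError("exposure must have >= 2 levels")
    adjust = (
        prune_inestimable(df, spec.event_col, spec.adjust) if prune else spec.adjust
    )
    fit = cox_fit(
        df, spec.time_col, spec.event_col, [exp_col, *adjust], ties=spec.ties
    )
    rows = [
        HazardRatioEstimate(
            term=levels[0], hr=1.0, ci_low=1.0, ci_high=1.0, log_hr_se=0.0, p=np.nan,
            n_events=fit.attrs["n_events"], n_total=fit.attrs["n_total"],
            stratum=stratum_label,
        ).as_row()
    ]
    for lev in levels[1:]:
        term = f"{exp_col}_{lev}"
        sub = fit.loc[fit["term"] == term]
        if sub.empty:
            continue
        r = sub.iloc[0]
        rows.append(
            HazardRatioEstimate(
                term=lev, hr=r["hr"], ci_low=r["ci_low"], ci_high=r["ci_high"],
                log_hr_se=r["log_hr_se"], p=r["p"],
                n_events=fit.attrs["n_events"], n_total=fit.attrs["n_total"],
                stratum=stratum_label,
            ).as_row()
        )
    out = pd.DataFrame(rows)
    coef, p_trend = trend_test(
        df, spec.time_col, spec.event_col, exp_col, adjust=adjust, ties=spec.ties
    )
    out.attrs.update(fit.attrs)
    out.attrs["trend_coef"] = coef
    out.attrs["p_trend"] = p_trend
    out["p_trend"] = p_trend
    return out


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_knots(x: np.ndarray, percentiles=(5.0, 35.0, 65.0, 95.0)) -> np.ndarray:
    k = np.percentile(np.asarray(x, float), percentiles)
    if np.unique(k).size != len(k):
        raise DataError("spline knots are not distinct; choose other percentiles")
    return k


def rcs_basis(x, knots) -> np.ndarray:
    """Harrell's restricted (natural) cubic spline basis.

    Column 0 is x itself; columns 1..k-2 are the cubic terms constrained to
    linearity beyond the boundary knots, scaled by (t_k − t_1)^2 so all
    columns live on comparable scales.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise DataError("need at least 3 knots for a restricted cubic spline")
    scale = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


def rcs_curve(
    df: pd.DataFrame,
    score_col: str,
    spec: ModelSpec,
    grid: np.ndarray | None = None,
    ref_value: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Spline dose-response curve for a continuous exposure, plus p-nonlinearity.

    Fits the Cox model with the RCS expansion of ``score_col`` alongside the
    adjustment set; the nonlinearity p-value is the likelihood-ratio test of
    the k−2 nonlinear basis terms against the linear-only model.  The curve
    is referenced to the exposure median (HR = 1 there) unless ``ref_value``
    is given; pointwise 95% CIs come from the delta method on the contrast
    of basis rows.
    """
    x = pd.to_numeric(df[score_col]).to_numpy(float)
    knots = rcs_knots(x, spec.knot_percentiles[: spec.n_knots])
    basis = rcs_basis(x, knots)
    ncols = basis.shape[1]
    names = [f"_rcs{i}" for i in range(ncols)]
    work = df.copy()
    for i, nm in enumerate(names):
        work[nm] = basis[:, i]
    adjust = prune_inestimable(work, spec.event_col, spec.adjust)
    full = cox_fit(work, spec.time_col, spec.event_col, [*names, *adjust],
                   ties=spec.ties)
    lin = cox_fit(work, spec.time_col, spec.event_col, [names[0], *adjust],
                  ties=spec.ties)
    lr = 2.0 * (full.attrs["loglik"] - lin.attrs["loglik"])
    p_nonlin = float(stats.chi2.sf(max(lr, 0.0), df=ncols - 1))

    if ref_value is None:
        ref_value = float(np.median(x))
    if grid is None:
        grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 101)
    gb = rcs_basis(grid, knots)
    rb = rcs_basis(np.array([ref_value]), knots)
    contrast = gb - rb  # each row: basis difference vs reference
    beta = full.set_index("term").loc[names, "coef"].to_numpy()
    cov = full.attrs["cov"].loc[names, names].to_numpy()
    lp = contrast @ beta
    var = np.einsum("ij,jk,ik->i", contrast, cov, contrast)
    se = np.sqrt(np.maximum(var, 0.0))
    curve = pd.DataFrame(
        {
            "score": grid,
            "hr": np.exp(lp),
            "ci_low": np.exp(lp - Z95 * se),
            "ci_high": np.exp(lp + Z95 * se),
        }
    )
    curve.attrs["knots"] = knots
    curve.attrs["ref_value"] = ref_value
    curve.attrs["p_nonlinearity"] = p_nonlin
    return curve, p_nonlin


# ---------------------------------------------------------------------------
# subgroup and sensitivity runners


def subgroup_run(df: pd.DataFrame, spec: ModelSpec, strata_col: str) -> pd.DataFrame:
    """Independent quartile fits within each level of ``strata_col``.

    The stratifier is removed from the adjustment set.  Strata where the
    model is inestimable (no events, degenerate exposure) are reported with
    NaN estimates rather than aborting the run.
    """
    sub_spec = ModelSpec(
        outcome=spec.outcome, exposure=spec.exposure, adjust=spec.adjust,
        stratify_by=strata_col, ties=spec.ties,
        n_knots=spec.n_knots, knot_percentiles=spec.knot_percentiles,
    )
    pieces = []
    for level, chunk in df.groupby(strata_col, observed=True, sort=True):
        label = f"{strata_col}={level}"
        try:
            est = quartile_fit(chunk, sub_spec, stratum_label=label)
        except (FitError, DataError):
            est = pd.DataFrame(
                [{"term": "(inestimable)", "hr": np.nan, "ci_low": np.nan,
                  "ci_high": np.nan, "log_hr_se": np.nan, "p": np.nan,
                  "n_events": int(pd.to_numeric(chunk[sub_spec.event_col]).sum()),
                  "n_total": len(chunk), "stratum": label, "p_trend": np.nan}]
            )
        pieces.append(est)
    if not pieces:
        raise DataError(f"no strata found in column {strata_col!r}")
    return pd.concat(pieces, ignore_index=True)


PREVALENT_DISEASE_FLAGS = ("cvd", "cancer", "diabetes", "respiratory")


def sensitivity_run(df: pd.DataFrame, which: int, spec: ModelSpec) -> pd.DataFrame:
    """The three robustness re-analyses.

    1. exclude participants with prevalent CVD/cancer/diabetes/respiratory
       disease at baseline;
    2. re-divide the exposure score into quintiles and refit;
    3. exclude participants with follow-up shorter than two years.

    Returns the refitted quartile (or quintile) table; the retained sample
    size is in ``attrs['n_total']``.
    """
    from .score import bin_exposure

    if which == 1:
        keep = ~df[list(PREVALENT_DISEASE_FLAGS)].astype(bool).any(axis=1)
        sub, sub_spec = df.loc[keep], spec
    elif which == 2:
        sub = df.copy()
        sub["infla_q5"] = bin_exposure(sub["infla_score"], k=5)
        sub_spec = ModelSpec(
            outcome=spec.outcome, exposure="infla_q5", adjust=spec.adjust,
            ties=spec.ties, n_knots=spec.n_knots,
            knot_percentiles=spec.knot_percentiles,
        )
    elif which == 3:
        sub = df.loc[pd.to_numeric(df[spec.time_col]) >= 2.0]
        sub_spec = spec
    else:
        raise ConfigError("sensitivity analysis must be 1, 2 or 3")
    if len(sub) == 0:
        raise DataError("sensitivity filter removed every participant")
    return quartile_fit(sub, sub_spec)
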