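"""Joint and modification analysis of diet quality and inflammation.

Participants are cross-classified by dietary-pattern tertile (T1 lowest
quality) and INFLA-Score quartile (Q1 lowest inflammation) into 12 cells.
The joint analysis fits a single Cox model with 11 indicator terms against
the reference cell (T1, Q4) — worst diet with highest inflammation — so
every HR reads as "risk relative to the least favourable profile".
The modification analysis refits the quartile model independently within
each diet tertile (Q1 reference within tertile), mirroring the stratified
presentation of effect modification; an optional product-term Wald test of
interaction is provided as an extension.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import DataError, FitError
from .survival import ModelSpec, cox_fit, prune_inestimable, quartile_fit

REFERENCE_CELL = ("T1", "Q4")


def cross_group(
    diet_tertile: pd.Series, infla_quartile: pd.Series, reference=REFERENCE_CELL
) -> pd.Series:
    """12-level (tertile, quartile) cross-classification.

    Rows missing either label come back as NaN (excluded downstream; the
    count is available from ``isna().sum()``).  Categories are ordered with
    the reference cell first so design matrices drop it automatically.
    """
    idx = diet_tertile.index if hasattr(diet_tertile, "index") else None
    t = pd.Categorical(diet_tertile)
    q = pd.Categorical(infla_quartile)
    labels = pd.Series(
        [
            np.nan if (pd.isna(a) or pd.isna(b)) else f"{a},{b}"
            for a, b in zip(t, q)
        ],
        index=idx,
    )
    ref = f"{reference[0]},{reference[1]}"
    cats = [f"{a},{b}" for a in t.categories for b in q.categories]
    if ref not in cats:
        raise DataError(f"reference cell {ref!r} absent from observed categories")
    ordered = [ref] + [c for c in cats if c != ref]
    return pd.Series(
        pd.Categorical(labels, categories=ordered), index=labels.index
    )


def joint_fit(
    df: pd.DataFrame,
    tertile_col: str,
    quartile_col: str,
    spec: ModelSpec,
) -> pd.DataFrame:
    """HRs of the 11 diet×inflammation cells versus the (T1, Q4) reference.

    A single Cox fit with 11 indicators plus the adjustment set; cells that
    are empty or have no events are reported as inestimable (NaN row).
    """
    cell = cross_group(df[tertile_col], df[quartile_col])
    work = df.loc[cell.notna()].copy()
    work["_cell"] = cell.dropna()
    n_excluded = int(cell.isna().sum())
    adjust = prune_inestimable(work, spec.event_col, spec.adjust)
    fit = cox_fit(
        work, spec.time_col, spec.event_col, ["_cell", *adjust], ties=spec.ties
    )
    levels = list(work["_cell"].cat.categories)
    rows = [
        {
            "cell": levels[0], "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
            "p": np.nan, "reference": True,
        }
    ]
    for lev in levels[1:]:
        sub = fit.loc[fit["term"] == f"_cell_{lev}"]
        if sub.empty:
            rows.append({"cell": lev, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "reference": False})
        else:
            r = sub.iloc[0]
            rows.append({"cell": lev, "hr": r["hr"], "ci_low": r["ci_low"],
                         "ci_high": r["ci_high"], "p": r["p"], "reference": False})
    out = pd.DataFrame(rows)
    counts = work["_cell"].value_counts()
    out["n"] = out["cell"].map(counts).fillna(0).astype(int)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["n_events"] = fit.attrs["n_events"]
    out.attrs["n_total"] = fit.attrs["n_total"]
    return out


def modification_fit(
    df: pd.DataFrame,
    tertile_col: str,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Quartile HRs and trend tests within each diet tertile.

    Three independent Cox fits (Q1 reference inside each tertile), the
    stratified-refit presentation of effect modification.  Tertiles where
    the fit is inestimable are reported as such; at least one tertile must
    be estimable.
    """
    pieces = []
    ok = 0
    for level in pd.Categorical(df[tertile_col]).categories:
        chunk = df.loc[df[tertile_col] == level]
        label = f"{tertile_col}={level}"
        try:
            est = quartile_fit(chunk, spec, stratum_label=label)
            ok += 1
        except (FitError, DataError):
            est = pd.DataFrame(
                [{"term": "(inestimable)", "hr": np.nan, "ci_low": np.nan,
                  "ci_high": np.nan, "log_hr_se": np.nan, "p": np.nan,
                  "n_events": 0, "n_total": len(chunk), "stratum": label,
                  "p_trend": np.nan}]
            )
        pieces.append(est)
    if ok == 0:
        raise FitError("no diet tertile produced an estimable model")
    return pd.concat(pieces, ignore_index=True)


def interaction_wald(
    df: pd.DataFrame,
    tertile_col: str,
    spec: ModelSpec,
) -> float:
    """Extension: Wald p for an ordinal diet×inflammation product term."""
    work = df.copy()
    work["_ord_t"] = pd.Categorical(work[tertile_col]).codes.astype(float) + 1
    work["_ord_q"] = pd.Categorical(work[spec.exposure]).codes.astype(float) + 1
    if (work["_ord_t"] <= 0).any() or (work["_ord_q"] <= 0).any():
        raise DataError("missing tertile/quartile labels")
    work["_inter"] = work["_ord_t"] * work["_ord_q"]
    adjust = prune_inestimable(work, spec.event_col, spec.adjust)
    fit = cox_fit(
        work, spec.time_col, spec.event_col,
        ["_ord_t", "_ord_q", "_inter", *adjust], ties=spec.ties,
    )
    return float(fit.loc[fit["term"] == "_inter", "p"].iloc[0])
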