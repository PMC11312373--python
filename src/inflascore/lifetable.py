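"""Life-table attribution of survival time to inflammation exposure groups.

Given a sex-specific reference schedule of central death rates m(a) for
ages 40–100, the exposure-group prevalences p_g and the hazard ratios of
premature death h_g versus the lowest quartile, group-specific rates are
calibrated so that the population mixture reproduces the reference
schedule exactly:

    m_Q1(a) = m_ref(a) / Σ_g p_g · h_g,      m_g(a) = h_g · m_Q1(a)

so Σ_g p_g · m_g(a) = m_ref(a) at every age.  Standard single-year
life-table arithmetic (mid-interval deaths, terminal closure at 100 via
L(100) = l(100)/m(100)) then yields remaining life expectancy e(a) per
group, and the expectancy gap Δe_g(a) = e_Q1(a) − e_g(a) is the average
survival time lost by group g relative to the lowest-inflammation group.

Hazard ratios are treated as age-constant over 40–100.  Confidence bounds
are propagated by re-running the calibration with the group's HR set to
each CI bound (other groups at point estimates); a log-normal parametric
bootstrap is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from ._exceptions import ConfigError, DataError

AGE_LO, AGE_HI = 40, 100
AGES = np.arange(AGE_LO, AGE_HI + 1)

#: Calibration targets for the synthetic UK-like reference schedule:
#: period life expectancy at ages 40 and 60 (ONS national life tables,
#: 2018–2020 vintage).
UK_EXPECTANCY_TARGETS = {"man": (40.2, 22.3), "woman": (43.4, 25.0)}


@dataclass
class ReferenceLifeTable:
    """Sex-specific central death rates m(a) on the contiguous age grid 40..100."""

    sex: str
    m: np.ndarray

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != AGES.shape:
            raise DataError(
                f"need one rate per age {AGE_LO}..{AGE_HI} ({AGES.size} values), "
                f"got {self.m.shape}"
            )
        if np.any(self.m < 0) or np.any(~np.isfinite(self.m)):
            raise DataError("death rates must be finite and >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sex: str) -> "ReferenceLifeTable":
        """Build from a tidy table with columns sex, age, m."""
        sub = df[df["sex"] == sex].sort_values("age")
        if not np.array_equal(sub["age"].to_numpy(), AGES):
            raise DataError(f"life table for {sex!r} must cover ages {AGE_LO}..{AGE_HI}")
        return cls(sex=sex, m=sub["m"].to_numpy(float))


@dataclass
class GroupSpec:
    """Exposure groups: prevalences and premature-death hazard ratios vs Q1.

    ``hr`` maps group label -> point HR; the reference group must have HR
    exactly 1.  ``hr_ci`` optionally maps label -> (low, high).
    """

    prevalence: dict[str, float]
    hr: dict[str, float]
    hr_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    reference: str = "Q1"

    def __post_init__(self):
        if set(self.prevalence) != set(self.hr):
            raise ConfigError("prevalence and hr must cover the same groups")
        if self.reference not in self.hr:
            raise ConfigError(f"reference group {self.reference!r} missing")
        if self.hr[self.reference] != 1.0:
            raise ConfigError("reference group must have hr exactly 1")
        tot = sum(self.prevalence.values())
        if not np.isclose(tot, 1.0, atol=1e-9):
            raise ConfigError(f"prevalences must sum to 1, got {tot}")
        if any(h <= 0 for h in self.hr.values()):
            raise ConfigError("hazard ratios must be > 0")

    @property
    def groups(self) -> list[str]:
        return list(self.hr)


def calibrate_group_rates(
    ref: ReferenceLifeTable, spec: GroupSpec
) -> dict[str, np.ndarray]:
    """Group-specific rate schedules whose prevalence mixture equals the reference."""
    divisor = sum(spec.prevalence[g] * spec.hr[g] for g in spec.groups)
    m_ref_group = ref.m / divisor
    return {g: spec.hr[g] * m_ref_group for g in spec.groups}


def build_life_table(m: np.ndarray) -> pd.DataFrame:
    """Single-year life table from central death rates on ages 40..100.

    q(a) = m/(1 + 0.5 m); l(40) = 1 with downward recursion; person-years
    L(a) = l(a) − 0.5 d(a) assuming mid-interval deaths; the open terminal
    interval is closed with L(100) = l(100)/m(100).  Remaining expectancy
    e(a) = T(a)/l(a).
    """
    m = np.asarray(m, dtype=float)
    if m.shape != AGES.shape:
        raise DataError(f"need rates for ages {AGE_LO}..{AGE_HI}")
    if np.any(m < 0):
        raise DataError("negative death rate")
    q = m / (1.0 + 0.5 * m)
    l = np.empty_like(q)
    l[0] = 1.0
    for i in range(1, len(q)):
        l[i] = l[i - 1] * (1.0 - q[i - 1])
    d = l * q
    L = l - 0.5 * d
    L[-1] = l[-1] / max(m[-1], 1e-12)
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / np.maximum(l, 1e-300), 0.0)
    return pd.DataFrame({"age": AGES, "m": m, "q": q, "l": l, "d": d, "L": L, "T": T, "e": e})


def group_life_tables(
    ref: ReferenceLifeTable, spec: GroupSpec
) -> dict[str, pd.DataFrame]:
    rates = calibrate_group_rates(ref, spec)
    return {g: build_life_table(m) for g, m in rates.items()}


def _expectancy_at(table: pd.DataFrame, age: int) -> float:
    if not (AGE_LO <= age <= AGE_HI):
        raise DataError(f"index age must lie in {AGE_LO}..{AGE_HI}")
    return float(table.loc[table["age"] == age, "e"].iloc[0])


def expectancy_gap(
    ref: ReferenceLifeTable,
    spec: GroupSpec,
    index_age: int,
    ci: bool = True,
) -> pd.DataFrame:
    """Life-expectancy deficit of each group versus the reference group.

    Returns one row per non-reference group with Δe = e_ref − e_g at
    ``index_age`` and, when CI bounds were supplied, the gap recomputed
    with that group's HR at each bound (other groups held at their point
    estimates).  A lower HR bound gives the smaller gap, so the interval
    is (gap at hr_low, gap at hr_high).
    """
    tables = group_life_tables(ref, spec)
    e_ref = _expectancy_at(tables[spec.reference], index_age)
    rows = []
    for g in spec.groups:
        if g == spec.reference:
            continue
        gap = e_ref - _expectancy_at(tables[g], index_age)
        row = {"group": g, "index_age": index_age, "gap_years": gap}
        if ci and g in spec.hr_ci:
            for bound, name in zip(spec.hr_ci[g], ("gap_low", "gap_high")):
                pert = GroupSpec(
                    prevalence=dict(spec.prevalence),
                    hr={**spec.hr, g: float(bound)},
                    reference=spec.reference,
                )
                t = group_life_tables(ref, pert)
                row[name] = _expectancy_at(t[spec.reference], index_age) - _expectancy_at(
                    t[g], index_age
                )
        rows.append(row)
    return pd.DataFrame(rows)


def expectancy_gap_bootstrap(
    ref: ReferenceLifeTable,
    spec: GroupSpec,
    index_age: int,
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Parametric-bootstrap gap CIs: log-normal HR draws from the Wald CIs."""
    rng = np.random.default_rng(seed)
    rows = []
    draws = {}
    for g in spec.groups:
        if g == spec.reference or g not in spec.hr_ci:
            continue
        lo, hi = spec.hr_ci[g]
        se = (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054)
        draws[g] = np.exp(rng.normal(np.log(spec.hr[g]), se, size=n_draws))
    for i in range(n_draws):
        hr = {g: float(draws[g][i]) if g in draws else spec.hr[g] for g in spec.groups}
        pert = GroupSpec(prevalence=dict(spec.prevalence), hr=hr, reference=spec.reference)
        t = group_life_tables(ref, pert)
        e_ref = _expectancy_at(t[spec.reference], index_age)
        rows.append({g: e_ref - _expectancy_at(t[g], index_age) for g in draws})
    boot = pd.DataFrame(rows)
    out = []
    for g in boot.columns:
        lo, hi = np.percentile(boot[g], [2.5, 97.5])
        out.append(
            {"group": g, "index_age": index_age, "gap_low": lo, "gap_high": hi}
        )
    return pd.DataFrame(out)


def gompertz_rates(a: float, b: float) -> np.ndarray:
    """Gompertz central death rates m(x) = a·exp(b·(x−40)) on ages 40..100."""
    if a <= 0 or b <= 0:
        raise ConfigError("Gompertz parameters must be positive")
    return a * np.exp(b * (AGES - AGE_LO))


def calibrate_gompertz(e40: float, e60: float) -> tuple[float, float]:
    """Solve for Gompertz (a, b) matching remaining expectancies at 40 and 60."""

    def eqs(p):
        m = gompertz_rates(np.exp(p[0]), p[1])
        t = build_life_table(m)
        return [_expectancy_at(t, 40) - e40, _expectancy_at(t, 60) - e60]

    sol = fsolve(eqs, [np.log(1e-3), 0.09], full_output=False)
    a, b = float(np.exp(sol[0])), float(sol[1])
    resid = eqs([np.log(a), b])
    if max(abs(r) for r in resid) > 1e-6:
        raise DataError("Gompertz calibration failed to converge")
    return a, b


def synthetic_uk_reference(sex: str) -> ReferenceLifeTable:
    """Synthetic stand-in for a UK national period life table.

    A Gompertz mortality schedule calibrated so that remaining life
    expectancy at ages 40 and 60 matches published ONS national values
    (2018–2020).  It is a smooth approximation, not the ONS table itself.
    """
    if sex not in UK_EXPECTANCY_TARGETS:
        raise ConfigError(f"sex must be one of {list(UK_EXPECTANCY_TARGETS)}")
    a, b = calibrate_gompertz(*UK_EXPECTANCY_TARGETS[sex])
    return ReferenceLifeTable(sex=sex, m=gompertz_rates(a, b))


def read_life_table(path) -> pd.DataFrame:
    """Read a tidy reference life table CSV with columns sex, age, m."""
    df = pd.read_csv(path)
    need = {"sex", "age", "m"}
    if not need.issubset(df.columns):
        raise DataError(f"life table file must have columns {sorted(need)}")
    return df
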