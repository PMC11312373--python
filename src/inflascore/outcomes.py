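"""Follow-up and outcome derivation.

Follow-up runs from the baseline assessment visit to the earliest of loss
to follow-up, death, or the administrative censoring date (1 Feb 2022 by
default).  Premature death is death before age 75; deaths at 75 or older
are treated as censoring events for the premature-death analysis (at the
death date by default, optionally at the 75th birthday).  Causes of death
and hospitalizations are classified by ICD-10 code ranges matched at the
three-character category level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DataError

ADMIN_CENSOR_DATE = pd.Timestamp("2022-02-01")
PREMATURE_AGE = 75.0
DAYS_PER_YEAR = 365.25

#: default cause-of-death groups
DEFAULT_CAUSE_GROUPS = {
    "chd": ["I20-I25"],
    "stroke": ["I60-I64", "I69"],
    "cvd": ["I20-I25", "I60-I64", "I69"],
    "respiratory": ["J00-J99"],
    "cancer": ["C00-C97"],
    "diabetes": ["E10-E14"],
}

_CODE_RE = re.compile(r"^([A-Z])(\d{2})")


def _code_key(code: str) -> tuple[str, int]:
    """(letter, number) of the 3-character ICD-10 category; sub-codes ignored."""
    m = _CODE_RE.match(str(code).strip().upper())
    if not m:
        raise DataError(f"malformed ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


@dataclass
class Icd10RangeSet:
    """Named groups of ICD-10 code ranges, e.g. ``{"chd": ["I20-I25"]}``.

    Ranges are inclusive and must stay within one letter block.  Matching
    is at 3-character resolution ("I21.4" matches "I20-I25").
    """

    groups: dict[str, list[tuple[tuple[str, int], tuple[str, int]]]] = field(
        default_factory=dict
    )

    @classmethod
    def from_ranges(cls, spec: dict[str, list[str]]) -> "Icd10RangeSet":
        groups = {}
        for name, ranges in spec.items():
            parsed = []
            for r in ranges:
                parts = str(r).split("-")
                lo = _code_key(parts[0])
                hi = _code_key(parts[-1]) if len(parts) > 1 else lo
                if len(parts) > 1 and "-" not in r:
                    raise DataError(f"bad range {r!r}")
                if lo[0] != hi[0] or lo[1] > hi[1]:
                    raise DataError(f"ill-formed ICD-10 range {r!r}")
                parsed.append((lo, hi))
            groups[name] = parsed
        return cls(groups=groups)

    def group_of(self, code: str) -> str | None:
        """First group (insertion order) whose ranges contain ``code``."""
        letter, num = _code_key(code)
        for name, ranges in self.groups.items():
            for (l0, n0), (_, n1) in ranges:
                if letter == l0 and n0 <= num <= n1:
                    return name
        return None

    def __contains__(self, code: str) -> bool:
        return self.group_of(code) is not None


def default_cause_ranges() -> Icd10RangeSet:
    return Icd10RangeSet.from_ranges(DEFAULT_CAUSE_GROUPS)


def classify_cause(icd10: str, ranges: Icd10RangeSet) -> str | None:
    """Cause group of a death/diagnosis code, or None when unclassified."""
    return ranges.group_of(icd10)


def load_code_list(path) -> list[str]:
    """Read an ICD-10 range list: one range per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def follow_up(
    baseline_date,
    death_date=None,
    loss_date=None,
    admin_date=ADMIN_CENSOR_DATE,
) -> tuple[float, str]:
    """Follow-up time in years and the terminal status.

    The terminal date is the earliest of death, loss to follow-up, and the
    administrative censoring date; status is correspondingly ``"death"``,
    ``"loss"`` or ``"admin"``.  Ties resolve in that priority order.
    """
    base = pd.Timestamp(baseline_date)
    candidates = []
    for status, d in (("death", death_date), ("loss", loss_date), ("admin", admin_date)):
        if d is not None and not pd.isna(d):
            d = pd.Timestamp(d)
            if d < base:
                raise DataError(f"{status} date {d.date()} precedes baseline {base.date()}")
            candidates.append((d, status))
    if not candidates:
        raise DataError("no terminal date available (admin date missing?)")
    end = min(c[0] for c in candidates)
    status = next(s for d, s in candidates if d == end)
    return (end - base).days / DAYS_PER_YEAR, status


def premature_flag(age_baseline: float, elapsed_years: float, status: str) -> bool:
    """True iff the participant died before age 75.

    Age at death is baseline age plus elapsed follow-up years (baseline age
    is recorded in whole years; the induced <1 y discretisation is noted in
    the methods documentation).
    """
    if status != "death":
        return False
    return (age_baseline + elapsed_years) < PREMATURE_AGE


def aging_hospitalization_flag(
    hospital_codes, hospital_dates, aging_ranges: Icd10RangeSet
) -> tuple[bool, pd.Timestamp | None]:
    """Whether any hospitalization code is an age-related disease.

    Returns the flag and the earliest qualifying admission date.  Raises
    :class:`ConfigError` when the age-related code list is empty — the
    disease list is study configuration, not a package constant.
    """
    if not aging_ranges.groups or all(not v for v in aging_ranges.groups.values()):
        raise ConfigError("age-related disease code list is empty")
    hits = [
        pd.Timestamp(d)
        for c, d in zip(hospital_codes, hospital_dates)
        if c is not None and not pd.isna(c) and aging_ranges.group_of(c) is not None
    ]
    if not hits:
        return False, None
    return True, min(hits)


def derive_outcomes(
    cohort: pd.DataFrame,
    cause_ranges: Icd10RangeSet | None = None,
    aging_ranges: Icd10RangeSet | None = None,
    admin_date=ADMIN_CENSOR_DATE,
    censor_ge75: str = "death",
) -> pd.DataFrame:
    """Vectorised outcome derivation for a whole cohort table.

    Expects columns ``baseline_date``, ``age_baseline``, optional
    ``death_date``, ``death_cause_icd10``, ``loss_date`` and (for the
    hospitalization outcome) ``hosp_date``/``hosp_icd10`` of the first
    age-related admission as produced by the synthetic generator or an
    upstream ingest step.

    Returns a table with, per participant:

    * ``time``/``event`` — premature-death analysis time (years) and event
      indicator; deaths at age >= 75 are censored per ``censor_ge75``
      ("death": at the death date; "age75": at the 75th birthday).
    * ``event_class`` — premature_death / censored.
    * ``cause_group`` — ICD-10 group of premature deaths, else None.
    * ``age_at_event`` — age at the terminal point.
    * ``hosp_time``/``hosp_event`` — time to first age-related
      hospitalization, censored at the terminal date.
    """
    if censor_ge75 not in ("death", "age75"):
        raise ConfigError("censor_ge75 must be 'death' or 'age75'")
    cause_ranges = cause_ranges or default_cause_ranges()
    base = pd.to_datetime(cohort["baseline_date"])
    age0 = pd.to_numeric(cohort["age_baseline"]).to_numpy(float)
    death = pd.to_datetime(cohort.get("death_date", pd.Series(pd.NaT, index=cohort.index)))
    loss = pd.to_datetime(cohort.get("loss_date", pd.Series(pd.NaT, index=cohort.index)))
    admin = pd.Timestamp(admin_date)

    end = pd.Series(admin, index=cohort.index)
    status = np.full(len(cohort), "admin", dtype=object)
    has_loss = loss.notna() & (loss < end)
    end = end.where(~has_loss, loss)
    status[has_loss.to_numpy()] = "loss"
    has_death = death.notna() & (death <= end)
    end = end.where(~has_death, death)
    status[has_death.to_numpy()] = "death"

    if ((end - base).dt.days < 0).any():
        raise DataError("terminal date precedes baseline for some participants")

    time = (end - base).dt.days.to_numpy(float) / DAYS_PER_YEAR
    age_at_event = age0 + time
    died = status == "death"
    premature = died & (age_at_event < PREMATURE_AGE)

    event = premature.astype(int)
    if censor_ge75 == "age75":
        late = died & ~premature
        capped = np.minimum(time[late], PREMATURE_AGE - age0[late])
        time = time.copy()
        time[late] = capped
        age_at_event[late] = age0[late] + capped

    causes = cohort.get("death_cause_icd10", pd.Series(None, index=cohort.index))
    cause_group = [
        classify_cause(c, cause_ranges) if (p and c is not None and not pd.isna(c)) else None
        for p, c in zip(premature, causes)
    ]

    out = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "event_class": np.where(premature, "premature_death", "censored"),
            "status": status,
            "cause_group": cause_group,
            "age_at_event": age_at_event,
        },
        index=cohort.index,
    )

    if "hosp_date" in cohort.columns:
        hosp = pd.to_datetime(cohort["hosp_date"])
        if aging_ranges is not None and "hosp_icd10" in cohort.columns:
            codes = cohort["hosp_icd10"]
            qualifies = pd.Series(
                [
                    (c is not None and not pd.isna(c) and c in aging_ranges)
                    for c in codes
                ],
                index=cohort.index,
            )
            hosp = hosp.where(qualifies, pd.NaT)
        hosp_event = (hosp.notna() & (hosp <= end)).to_numpy()
        hosp_end = hosp.where(hosp_event, end)
        out["hosp_time"] = (hosp_end - base).dt.days.to_numpy(float) / DAYS_PER_YEAR
        out["hosp_event"] = hosp_event.astype(int)
    return out
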