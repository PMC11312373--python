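"""End-to-end pipeline: simulate → score → outcomes → models → life
expectancy → joint effects → report.

Each stage reads the previous stage's CSV from the run directory and
writes tidy tables; a ``manifest.json`` records the config hash, seed and
every produced file, so re-running a stage from cached upstream outputs
reproduces its tables exactly.
"""

from __future__ import annotations

import json
import logging
import sys
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, InflaError
from .cohort import (
    cohort_summary,
    generate_cohort,
    read_cohort_csv,
    split_record_list,
    write_cohort_csv,
    DEFAULT_AGING_CODES,
)
from .config import CohortConfig
from .diet import (
    bin_tertiles,
    dash_score,
    healthy_diet_score,
    hei2020_score,
    med_score,
)
from .joint import joint_fit, modification_fit
from .lifetable import GroupSpec, expectancy_gap, synthetic_uk_reference
from .outcomes import Icd10RangeSet, aging_hospitalization_flag, derive_outcomes
from .score import bin_exposure, compute_infla_score, compute_nlr, fit_decile_map
from .survival import ModelSpec, quartile_fit, rcs_curve, sensitivity_run, subgroup_run

log = logging.getLogger("inflascore")

STAGES = ("simulate", "score", "outcomes", "fit", "life_expectancy", "joint", "report")

PATTERNS = ("hei2020", "med", "dash")


class PipelineRun:
    """State shared across stages of one run."""

    def __init__(self, config: CohortConfig, outdir, seed: int | None = None,
                 aging_codes=None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.aging_ranges = Icd10RangeSet.from_ranges(
            {"aging": list(aging_codes or DEFAULT_AGING_CODES)}
        )
        self.manifest = {
            "config_digest": config.digest(),
            "seed": self.seed,
            "outputs": {},
            "errors": {},
        }

    def _write(self, stage: str, name: str, df: pd.DataFrame) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False)
        self.manifest["outputs"].setdefault(stage, []).append(name)
        return path

    def save_manifest(self) -> None:
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    # -- stages -------------------------------------------------------------

    def simulate(self) -> pd.DataFrame:
        df = generate_cohort(self.config, seed=self.seed)
        write_cohort_csv(df, self.outdir / "cohort.csv")
        self.manifest["outputs"].setdefault("simulate", []).append("cohort.csv")
        return df

    def score(self, df: pd.DataFrame) -> pd.DataFrame:
        work = df.copy()
        work["nlr"] = compute_nlr(work["neut"], work["lymph"])
        panel = work[["crp", "wbc", "plt", "nlr"]]
        dmap = fit_decile_map(panel)
        pts = compute_infla_score(panel, dmap)
        for c in pts.columns:
            work[c] = pts[c]
        work["infla_q"] = bin_exposure(work["infla_score"], k=4)
        hd_pts, hd_flag = healthy_diet_score(work)
        work["healthy_diet_points"] = hd_pts
        work["healthy_diet"] = hd_flag.astype(float).fillna(0.0)
        work["hei2020"] = hei2020_score(work)
        work["med"] = med_score(work, work["sex"])
        work["dash"] = dash_score(work)
        for p in PATTERNS:
            work[f"{p}_t"] = bin_tertiles(work[p])
        write_cohort_csv(work, self.outdir / "scored.csv")
        self.manifest["outputs"].setdefault("score", []).append("scored.csv")
        return work

    def outcomes(self, df: pd.DataFrame) -> pd.DataFrame:
        work = df.copy()
        first_dates, first_codes = [], []
        for dates, codes in zip(work["hospital_dates"], work["hospital_icd10"]):
            ds, cs = split_record_list(dates), split_record_list(codes)
            if ds:
                flag, when = aging_hospitalization_flag(cs, ds, self.aging_ranges)
            else:
                flag, when = False, None
            if flag:
                i = ds.index(when.date().isoformat()) if when.date().isoformat() in ds else 0
                first_dates.append(when)
                first_codes.append(cs[i])
            else:
                first_dates.append(pd.NaT)
                first_codes.append(None)
        work["hosp_date"] = first_dates
        work["hosp_icd10"] = first_codes
        out = derive_outcomes(
            work, aging_ranges=self.aging_ranges,
            admin_date=self.config.admin_censor_date,
        )
        analysis = pd.concat([work, out], axis=1)
        write_cohort_csv(analysis, self.outdir / "analysis.csv")
        self.manifest["outputs"].setdefault("outcomes", []).append("analysis.csv")
        summary = cohort_summary(analysis, premature=analysis["event"] == 1)
        self._write("outcomes", "table1_summary.csv", summary)
        return analysis

    def fit(self, analysis: pd.DataFrame) -> dict[str, pd.DataFrame]:
        results = {}
        for outcome in ("premature_death", "hospitalization"):
            spec = ModelSpec(outcome=outcome)
            est = quartile_fit(analysis, spec)
            self._write("fit", f"hr_{outcome}.csv", est)
            results[outcome] = est
            curve, p_nl = rcs_curve(analysis, "infla_score", spec)
            curve["p_nonlinearity"] = p_nl
            self._write("fit", f"rcs_{outcome}.csv", curve)
            results[f"rcs_{outcome}"] = curve
            for strata in ("sex", "hypertension"):
                sub = subgroup_run(analysis, spec, strata)
                self._write("fit", f"subgroup_{outcome}_{strata}.csv", sub)
            for which in (1, 2, 3):
                try:
                    sens = sensitivity_run(analysis, which, spec)
                    self._write("fit", f"sensitivity{which}_{outcome}.csv", sens)
                except InflaError as exc:
                    self.manifest["errors"][f"sensitivity{which}_{outcome}"] = str(exc)
        return results

    def life_expectancy(self, analysis: pd.DataFrame) -> pd.DataFrame:
        """Gaps vs Q1 from this cohort's sex-specific premature-death HRs."""
        rows = []
        for sex in ("man", "woman"):
            sub = analysis.loc[analysis["sex"] == sex]
            spec = ModelSpec(outcome="premature_death", stratify_by="sex_male")
            est = quartile_fit(sub, spec).set_index("term")
            prev = sub["infla_q"].value_counts(normalize=True).to_dict()
            gspec = GroupSpec(
                prevalence={q: float(prev.get(q, 0.0)) for q in est.index},
                hr={q: (1.0 if q == "Q1" else float(est.loc[q, "hr"])) for q in est.index},
                hr_ci={q: (float(est.loc[q, "ci_low"]), float(est.loc[q, "ci_high"]))
                       for q in est.index if q != "Q1"},
            )
            ref = synthetic_uk_reference(sex)
            for age in (40, 60):
                gap = expectancy_gap(ref, gspec, index_age=age)
                gap.insert(0, "sex", sex)
                rows.append(gap)
        out = pd.concat(rows, ignore_index=True)
        self._write("life_expectancy", "life_expectancy_gaps.csv", out)
        return out

    def joint(self, analysis: pd.DataFrame) -> dict[str, pd.DataFrame]:
        diet = analysis.dropna(subset=[f"{p}_t" for p in PATTERNS])
        results = {}
        for outcome in ("premature_death", "hospitalization"):
            spec = ModelSpec(outcome=outcome)
            for p in PATTERNS:
                jf = joint_fit(diet, f"{p}_t", "infla_q", spec)
                self._write("joint", f"joint_{p}_{outcome}.csv", jf)
                mf = modification_fit(diet, f"{p}_t", spec)
                self._write("joint", f"modification_{p}_{outcome}.csv", mf)
                results[f"{p}_{outcome}"] = (jf, mf)
        return results

    def report(self, analysis: pd.DataFrame) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        spec = ModelSpec(outcome="premature_death")
        curve, p_nl = rcs_curve(analysis, "infla_score", spec)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve["score"], curve["hr"], color="firebrick")
        ax.fill_between(curve["score"], curve["ci_low"], curve["ci_high"],
                        alpha=0.2, color="firebrick")
        ax.axhline(1.0, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("INFLA-Score")
        ax.set_ylabel("HR (premature death)")
        ax.set_title(f"Dose-response (p nonlinearity = {p_nl:.3g})")
        fig.tight_layout()
        fig.savefig(self.outdir / "rcs_premature_death.png", dpi=120)
        plt.close(fig)
        self.manifest["outputs"].setdefault("report", []).append(
            "rcs_premature_death.png"
        )


def run_pipeline(
    config: CohortConfig | str | Path,
    outdir,
    seed: int | None = None,
    stages=STAGES,
    aging_codes=None,
) -> Path:
    """Run the pipeline end to end; returns the run directory.

    ``config`` may be a :class:`CohortConfig` or a path to its YAML file.
    A stage failure is recorded in the manifest (with the error message)
    and aborts subsequent stages, leaving a partial manifest behind.
    """
    if not isinstance(config, CohortConfig):
        config = CohortConfig.from_yaml(config)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    run = PipelineRun(config, outdir, seed=seed, aging_codes=aging_codes)
    handlers: dict[str, object] = {}
    df = analysis = None
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = _time.perf_counter()
            if stage == "simulate":
                df = run.simulate()
            elif stage == "score":
                if df is None:
                    df = read_cohort_csv(run.outdir / "cohort.csv")
                df = run.score(df)
            elif stage == "outcomes":
                if df is None:
                    df = read_cohort_csv(run.outdir / "scored.csv")
                analysis = run.outcomes(df)
            elif stage == "fit":
                if analysis is None:
                    analysis = _load_analysis(run.outdir)
                handlers["fit"] = run.fit(analysis)
            elif stage == "life_expectancy":
                if analysis is None:
                    analysis = _load_analysis(run.outdir)
                run.life_expectancy(analysis)
            elif stage == "joint":
                if analysis is None:
                    analysis = _load_analysis(run.outdir)
                run.joint(analysis)
            elif stage == "report":
                if analysis is None:
                    analysis = _load_analysis(run.outdir)
                run.report(analysis)
            log.info("stage %-16s %6.2fs", stage, _time.perf_counter() - t0)
    except InflaError as exc:
        run.manifest["errors"][stage] = str(exc)
        run.save_manifest()
        raise
    run.save_manifest()
    return run.outdir


def _load_analysis(outdir: Path) -> pd.DataFrame:
    path = Path(outdir) / "analysis.csv"
    if not path.exists():
        raise ConfigError(
            f"{path} not found: run the outcomes stage first (or 'all')"
        )
    df = read_cohort_csv(path)
    for c in ("infla_q",):
        df[c] = pd.Categorical(df[c], ordered=True)
    for c in (f"{p}_t" for p in PATTERNS):
        if c in df.columns:
            df[c] = pd.Categorical(df[c], ordered=True)
    return df
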