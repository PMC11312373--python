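"""Diet-quality scoring: healthy-diet points, HEI-2020, MED, DASH, tertiles."""

import numpy as np
import pandas as pd
import pytest

from inflascore import (
    BinningError,
    CohortConfig,
    average_recalls,
    bin_tertiles,
    dash_score,
    generate_cohort,
    healthy_diet_score,
    hei2020_score,
    med_score,
)
from inflascore.diet import (
    DASH_ADVERSE,
    DASH_BENEFICIAL,
    MED_BENEFICIAL,
    MED_DETRIMENTAL,
    load_hei_standards,
)

HD_COLS = ["red_meat_wk", "veg_tbsp_day", "fruit_serv_day", "fish_wk",
           "grains_serv_wk", "urinary_na_mmol"]


def hd_frame(rows):
    return pd.DataFrame(rows, columns=HD_COLS)


class TestHealthyDiet:
    def test_all_criteria_met_scores_six(self):
        pts, flag = healthy_diet_score(hd_frame([[2.0, 5.0, 3.5, 5.0, 6.0, 60.0]]))
        assert pts.iloc[0] == 6 and bool(flag.iloc[0])

    def test_none_met_scores_zero(self):
        pts, flag = healthy_diet_score(hd_frame([[7.0, 1.0, 0.5, 0.0, 2.0, 150.0]]))
        assert pts.iloc[0] == 0 and not bool(flag.iloc[0])

    def test_three_points_is_healthy_threshold(self):
        # red meat, vegetables and sodium criteria met; the rest missed
        pts, flag = healthy_diet_score(hd_frame([[3.0, 4.0, 1.0, 1.0, 2.0, 70.6]]))
        assert pts.iloc[0] == 3 and bool(flag.iloc[0])
        pts2, flag2 = healthy_diet_score(hd_frame([[3.0, 4.0, 1.0, 1.0, 2.0, 71.0]]))
        assert pts2.iloc[0] == 2 and not bool(flag2.iloc[0])

    def test_missing_component_gives_missing_signal(self):
        pts, flag = healthy_diet_score(hd_frame([[2.0, np.nan, 3.5, 5.0, 6.0, 60.0]]))
        assert np.isnan(pts.iloc[0]) and pd.isna(flag.iloc[0])


def perfect_hei_row(std):
    """Intakes exactly at every adequacy maximum / moderation minimum."""
    row = {"energy_kcal": 2000.0}
    for r in std.itertuples(index=False):
        target = r.std_max
        row[r.column] = target * 2.0 if r.basis == "density" else target
    return pd.DataFrame([row])


class TestHei2020:
    def test_perfect_diet_scores_100(self):
        std = load_hei_standards()
        assert hei2020_score(perfect_hei_row(std)).iloc[0] == pytest.approx(100.0)

    def test_empty_diet_scores_only_moderation_floor(self):
        std = load_hei_standards()
        row = perfect_hei_row(std)
        for r in std.itertuples(index=False):
            if r.kind == "adequacy":
                row[r.column] = 0.0 if r.basis == "density" else r.std_zero
        # adequacy all zero; moderation still perfect
        expected = std.loc[std["kind"] == "moderation", "max_points"].sum()
        assert hei2020_score(row).iloc[0] == pytest.approx(expected)

    def test_linear_interpolation_halfway(self):
        std = load_hei_standards()
        row = perfect_hei_row(std)
        # halve the whole-grain density: that component drops to 5 of 10
        row["whole_grains_oz"] = 0.75 * 2.0  # density 0.75 vs standard 1.5
        assert hei2020_score(row).iloc[0] == pytest.approx(95.0)

    def test_monotone_in_beneficial_component(self, rng):
        std = load_hei_standards()
        base = perfect_hei_row(std)
        worse = base.copy()
        worse["fruit_total_cup"] = 0.1
        better = base.copy()
        better["fruit_total_cup"] = 5.0
        assert hei2020_score(worse).iloc[0] <= hei2020_score(better).iloc[0]

    def test_range_bounds_random_intakes(self, rng):
        std = load_hei_standards()
        n = 200
        data = {"energy_kcal": rng.uniform(1000, 3500, n)}
        for r in std.itertuples(index=False):
            data[r.column] = rng.uniform(0, 3 * max(r.std_max, r.std_zero), n)
        s = hei2020_score(pd.DataFrame(data))
        assert ((s >= 0) & (s <= 100)).all()


class TestMed:
    def brute_force(self, intake, sex):
        """Per-component oracle applying the median rules explicitly."""
        out = np.zeros(len(intake))
        for s in ("man", "woman"):
            m = (sex == s).to_numpy()
            sub = intake.loc[m]
            score = np.zeros(m.sum())
            for c in MED_BENEFICIAL:
                score += (sub[c] >= sub[c].median()).to_numpy()
            for c in MED_DETRIMENTAL:
                score += (sub[c] < sub[c].median()).to_numpy()
            lo, hi = (10, 50) if s == "man" else (5, 25)
            score += ((sub["alcohol_g"] >= lo) & (sub["alcohol_g"] <= hi)).to_numpy()
            out[m] = score
        return out

    def test_matches_componentwise_oracle(self, rng):
        n = 300
        intake = pd.DataFrame(
            {c: rng.gamma(2.0, 30.0, n) for c in (*MED_BENEFICIAL, *MED_DETRIMENTAL)}
        )
        intake["alcohol_g"] = rng.gamma(1.5, 10.0, n)
        sex = pd.Series(np.where(rng.random(n) < 0.5, "man", "woman"))
        got = med_score(intake, sex)
        np.testing.assert_array_equal(got.to_numpy(), self.brute_force(intake, sex))

    def test_at_median_everywhere(self):
        # constant components: everyone sits exactly at the median, so all
        # beneficial components score and no detrimental component does
        n = 20
        intake = pd.DataFrame(
            {c: np.ones(n) for c in (*MED_BENEFICIAL, *MED_DETRIMENTAL)}
        )
        intake["alcohol_g"] = np.zeros(n)
        got = med_score(intake, pd.Series(["man"] * n))
        assert (got == len(MED_BENEFICIAL)).all()

    def test_range(self, rng):
        n = 150
        intake = pd.DataFrame(
            {c: rng.gamma(2.0, 30.0, n) for c in (*MED_BENEFICIAL, *MED_DETRIMENTAL)}
        )
        intake["alcohol_g"] = rng.gamma(1.5, 10.0, n)
        got = med_score(intake, pd.Series(["woman"] * n))
        assert got.between(0, 9).all()


class TestDash:
    def frame(self):
        n = 10
        data = {}
        for c in DASH_BENEFICIAL:
            data[c] = np.arange(1.0, n + 1)
        for c in DASH_ADVERSE:
            data[c] = np.arange(n, 0.0, -1)
        return pd.DataFrame(data)

    def test_best_and_worst_rows_hit_bounds(self):
        s = dash_score(self.frame())
        assert s.max() == 40 and s.min() == 8

    def test_sodium_increase_never_raises_score(self, rng):
        df = self.frame()
        s0 = dash_score(df)
        worse = df.copy()
        worse.loc[4, "dash_sodium_mg"] = worse["dash_sodium_mg"].max() + 100
        s1 = dash_score(worse)
        assert s1.iloc[4] <= s0.iloc[4]

    def test_missing_component_gives_nan(self):
        df = self.frame()
        df.loc[0, "dash_fruit"] = np.nan
        s = dash_score(df)
        assert np.isnan(s.iloc[0]) and s.iloc[1:].notna().all()


class TestTertilesAndAveraging:
    def test_uniform_scores_three_equal_bins(self):
        t = bin_tertiles(np.arange(30.0))
        assert t.value_counts().tolist() == [10, 10, 10]

    def test_constant_scores_rejected(self):
        with pytest.raises(BinningError):
            bin_tertiles(np.ones(30))

    def test_nan_scores_stay_unassigned(self):
        t = bin_tertiles(pd.Series([1.0, 2.0, 3.0, np.nan, 5.0, 6.0]))
        assert t.isna().sum() == 1

    def test_recall_averaging_order_invariance(self, rng):
        """Scoring pre-averaged intakes equals scoring the recall means."""
        n, reps = 40, 3
        recalls = pd.DataFrame(
            {
                "id": np.repeat(np.arange(n), reps),
                **{c: rng.gamma(2.0, 2.0, n * reps) for c in HD_COLS},
            }
        )
        avg = average_recalls(recalls)
        manual = recalls.groupby("id").mean(numeric_only=True).reset_index()
        pts_a, _ = healthy_diet_score(avg)
        pts_b, _ = healthy_diet_score(manual)
        np.testing.assert_array_equal(pts_a.to_numpy(), pts_b.to_numpy())
        assert (avg["n_recalls"] == reps).all()


class TestGeneratedCohortScores:
    def test_scores_within_bounds_on_synthetic_diet(self):
        df = generate_cohort(CohortConfig(n_participants=2000, seed=5))
        diet = df.dropna(subset=["energy_kcal"])
        hei = hei2020_score(diet)
        med = med_score(diet, diet["sex"])
        dash = dash_score(diet)
        assert hei.between(0, 100).all()
        assert med.between(0, 9).all()
        assert dash.between(8, 40).all()
        # participants without recalls carry the missing signal
        assert df["energy_kcal"].isna().sum() > 0
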