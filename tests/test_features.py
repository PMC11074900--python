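"""Dietary feature families: summary stats, intervals, locations, patterns,
diversity/frequency, and z-score banding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mealprint as mp
from mealprint.features import (DietaryFeatureExtractor, ZScoreBander,
                                allday_pattern, diversity_and_meal_frequency,
                                interval_features, location_shares,
                                pattern_frequency, summary_stats,
                                zscore_and_band)

from oracles import direct_mad


def meal_rows(rows):
    df = pd.DataFrame(rows, columns=["student_id", "date", "meal_class",
                                     "start_time", "expenditure",
                                     "cafeteria_id", "item_ids"])
    df["item_ids"] = df["item_ids"].map(frozenset)
    return df


# -- summary statistics -----------------------------------------------------

def test_summary_stats_constant_and_simple_lists():
    s = summary_stats([5, 5, 5])
    assert (s.mad, s.min, s.max) == (0, 5, 5)
    s = summary_stats([1, 2, 3, 4, 5])
    assert s.median == 3 and s.mad == 1  # |x-3| = {2,1,0,1,2}, median 1


def test_summary_stats_empty_is_an_error():
    with pytest.raises(ValueError, match="empty"):
        summary_stats([])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
       st.floats(-1e5, 1e5), st.floats(0.01, 100))
def test_mad_translation_and_scale_equivariance(xs, shift, scale):
    base = summary_stats(xs).mad
    assert summary_stats([x + shift for x in xs]).mad == pytest.approx(base, abs=1e-6, rel=1e-9)
    assert summary_stats([x * scale for x in xs]).mad == pytest.approx(base * scale, rel=1e-9, abs=1e-9)


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
def test_mad_matches_enumeration_oracle(xs):
    assert summary_stats(xs).mad == pytest.approx(direct_mad(xs), rel=1e-12, abs=1e-9)


def test_mean_absolute_deviation_toggle():
    s = summary_stats([0, 0, 10], mad_kind="mean")
    # mean 10/3; deviations 10/3, 10/3, 20/3; mean = 40/9
    assert s.mad == pytest.approx(40 / 9)


# -- intervals, locations, patterns ----------------------------------------

def test_interval_features_pairs_and_absent_meals():
    day = meal_rows([
        ("s", "d", "breakfast", 27000, 4.0, 1, {"a"}),   # 07:30
        ("s", "d", "lunch", 43200, 9.0, 1, {"b"}),       # 12:00
    ])
    gaps = interval_features(day)
    assert gaps == {"bre_lun": 16200}
    only_dinner = meal_rows([("s", "d", "dinner", 66000, 9.0, 1, {"a"})])
    assert interval_features(only_dinner) == {}


def test_allday_pattern_bijection_over_subsets():
    classes = {"B": ["breakfast"], "L": ["lunch"], "D": ["dinner"],
               "BL": ["breakfast", "lunch"], "LD": ["lunch", "dinner"],
               "BD": ["breakfast", "dinner"],
               "BLD": ["breakfast", "lunch", "dinner"]}
    seen = set()
    for want, present in classes.items():
        day = meal_rows([("s", "d", c, 43200, 1.0, 1, {"x"}) for c in present])
        got = allday_pattern(day)
        assert got == want
        seen.add(got)
    assert seen == set(classes)
    with pytest.raises(ValueError):
        allday_pattern(meal_rows([]))


def test_pattern_frequency_ratios():
    pats = ["LD"] * 5 + ["BLD"] * 15
    freq = pattern_frequency(pats)
    assert freq["LD"] == 0.25 and freq["BLD"] == 0.75
    assert sum(freq.values()) == pytest.approx(1)
    all_bld = pattern_frequency(["BLD"] * 10)
    assert all_bld["BLD"] == 1 and all(v == 0 for k, v in all_bld.items() if k != "BLD")


def test_location_shares_counting():
    meals = meal_rows([("s", f"d{i}", "lunch", 43200, 1.0, caf, {"x"})
                       for i, caf in enumerate([1] * 6 + [3] * 4)])
    shares = location_shares(meals)
    assert shares[("overall", 1)] == 0.6
    assert shares[("lunch", 1)] == 0.6 and shares[("lunch", 3)] == 0.4
    assert shares[("lunch", 2)] == 0.0
    assert np.isnan(shares[("breakfast", 1)])  # zero denominator -> missing
    all_caf2 = meal_rows([("s", "d", "lunch", 43200, 1.0, 2, {"x"})])
    s2 = location_shares(all_caf2)
    assert (s2[("overall", 1)], s2[("overall", 2)], s2[("overall", 3)]) == (0, 1.0, 0)


def test_diversity_and_meal_frequency_counts():
    rows = []
    for i in range(11):
        rows.append((f"s", f"2020-10-{i+1:02d}", "breakfast", 26400, 3.0, 1,
                     {"i1", "i2", "i3"}))
    meals = meal_rows(rows)
    diversity, freq = diversity_and_meal_frequency(meals, n_calendar_days=22)
    assert diversity == 3.0
    assert freq["breakfast"] == 0.5 and freq["lunch"] == 0.0


# -- extractor on a simulated month ----------------------------------------

def test_extractor_matches_tally_oracles(tiny_meals):
    """Wide-matrix cells equal per-student brute-force recomputation."""
    cfg, _, meals = tiny_meals
    feats = DietaryFeatureExtractor(cfg.calendar).fit_transform(meals)
    cal = cfg.calendar
    weekdays = set(cal.loc[cal["day_type"] == "weekday", "date"])
    wd = meals[meals["date"].isin(weekdays)]
    for student in list(feats.index)[:12]:
        sub = wd[wd["student_id"] == student]
        lunches = sub.loc[sub["meal_class"] == "lunch", "start_time"]
        if len(lunches):
            assert feats.loc[student, "time.weekday.lunch.mad"] == pytest.approx(
                direct_mad(lunches), abs=1e-9)
            assert feats.loc[student, "time.weekday.lunch.min"] == lunches.min()
        # interval oracle: per-day lunch-dinner gap
        gaps = []
        for _, day in sub.groupby("date"):
            t = dict(zip(day["meal_class"], day["start_time"]))
            if "lunch" in t and "dinner" in t:
                gaps.append(t["dinner"] - t["lunch"])
        if gaps:
            assert feats.loc[student, "interval.weekday.lun_din.mean"] == pytest.approx(
                np.mean(gaps))
        # pattern tally oracle
        pats = [allday_pattern(day) for _, day in sub.groupby("date")]
        if pats:
            assert feats.loc[student, "pattern.weekday.BLD"] == pytest.approx(
                pats.count("BLD") / len(pats))
        # breakfast frequency over weekday calendar days
        n_b = sub.loc[sub["meal_class"] == "breakfast", "date"].nunique()
        assert feats.loc[student, "frequency.weekday.breakfast"] == pytest.approx(
            n_b / len(weekdays))


def test_pattern_frequencies_sum_to_one(tiny_meals):
    cfg, _, meals = tiny_meals
    feats = DietaryFeatureExtractor(cfg.calendar).fit_transform(meals)
    for day_type in ("weekday", "weekend"):
        cols = [c for c in feats.columns if c.startswith(f"pattern.{day_type}.")]
        observed = feats[f"meta.{day_type}.n_days_observed"] > 0
        sums = feats.loc[observed, cols].sum(axis=1)
        assert np.allclose(sums, 1.0)


def test_extractor_is_deterministic(tiny_meals):
    cfg, _, meals = tiny_meals
    f1 = DietaryFeatureExtractor(cfg.calendar).fit_transform(meals)
    f2 = DietaryFeatureExtractor(cfg.calendar).fit_transform(meals)
    pd.testing.assert_frame_equal(f1, f2)


# -- z-scores and SD bands ---------------------------------------------------

def test_zscore_of_mean_is_zero_band_normal():
    df = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
    z, bands, dropped = zscore_and_band(df)
    assert z.loc[1, "f"] == pytest.approx(0)
    assert bands.loc[1, "f"] == "Normal"
    assert dropped == []


def test_zscore_sample_vs_population_sd():
    df = pd.DataFrame({"f": [0.0, 0.0, 10.0]})
    z_sample, bands, _ = zscore_and_band(df, ddof=1)
    assert z_sample.loc[2, "f"] == pytest.approx(1.1547, abs=1e-4)
    z_pop, _, _ = zscore_and_band(df, ddof=0)
    assert z_pop.loc[2, "f"] == pytest.approx(np.sqrt(2), abs=1e-4)
    # zeros sit at z = -0.577 under the sample SD: inside the Normal band
    assert bands.loc[2, "f"] == "Always" and bands.loc[0, "f"] == "Normal"


def test_zscore_normalisation_identity(rng):
    df = pd.DataFrame(rng.normal(3, 2, (50, 4)), columns=list("abcd"))
    z, _, _ = zscore_and_band(df)
    assert np.allclose(z.mean(), 0, atol=1e-9)
    assert np.allclose(z.std(ddof=1), 1, atol=1e-9)


def test_zero_variance_feature_dropped_and_missing_propagates():
    df = pd.DataFrame({"const": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, np.nan]})
    bander = ZScoreBander()
    z = bander.fit_transform(df)
    assert bander.dropped_ == ["const"]
    assert "const" not in z.columns
    assert np.isnan(z.loc[2, "ok"])
    assert pd.isna(bander.to_bands(z).loc[2, "ok"])
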