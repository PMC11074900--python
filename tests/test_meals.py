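"""Anchored 2-hour meal segmentation, slot classification, deduplication."""

import numpy as np
import pandas as pd
import pytest

import mealprint as mp
from mealprint.meals import (MEAL_SLOTS, Meal, MealSegmenter, classify_meal,
                             dedupe_meal_classes, segment_meals)

from conftest import make_transactions
from oracles import brute_force_segments, brute_force_slot


def hms(h, m=0, s=0):
    return h * 3600 + m * 60 + s


def test_two_transactions_within_window_form_one_meal():
    tx = make_transactions([hms(7, 0), hms(7, 45)], amount=[3.0, 2.5])
    meals = segment_meals(tx)
    assert len(meals) == 1
    assert meals[0].start_time == hms(7, 0)
    assert meals[0].expenditure == 5.5
    assert meals[0].n_transactions == 2


def test_gap_beyond_window_anchors_new_meal():
    tx = make_transactions([hms(11, 30), hms(12, 0), hms(17, 40)])
    meals = segment_meals(tx)
    assert [m.start_time for m in meals] == [hms(11, 30), hms(17, 40)]
    assert [m.n_transactions for m in meals] == [2, 1]


def test_anchored_not_sliding_window():
    """The window runs from the anchor, not from the latest member."""
    t0 = hms(7, 0)
    tx = make_transactions([t0, t0 + 7000, t0 + 7300])
    meals = segment_meals(tx)
    assert [m.n_transactions for m in meals] == [2, 1]


def test_empty_and_unsorted_inputs():
    assert segment_meals(make_transactions([])) == []
    with pytest.raises(ValueError, match="sorted"):
        segment_meals(make_transactions([hms(12), hms(8)]))
    mixed = pd.concat([make_transactions([hms(8)], student="A"),
                       make_transactions([hms(9)], student="B")])
    with pytest.raises(ValueError, match="single student-day"):
        segment_meals(mixed)


def test_batch_segmenter_matches_bruteforce_oracle(rng):
    """1000 random student-days, batch output == literal scan-and-reanchor."""
    frames = []
    for day in range(1000):
        n = rng.integers(1, 13)
        times = np.sort(rng.integers(0, 86400, n))
        frames.append(make_transactions(
            times, student=f"S{day % 97}", date=f"2020-10-{day % 28 + 1:02d}",
            amount=np.round(rng.uniform(1, 20, n), 2).tolist()))
    log = pd.concat(frames, ignore_index=True)
    # collapse exact duplicates of the sort key so both sides group identically
    log = log.drop_duplicates(["student_id", "date", "time"]).reset_index(drop=True)

    seg = MealSegmenter()
    batch = seg.fit_transform(log)
    all_meals = pd.concat([batch, seg.dropped_], ignore_index=True)

    n_expected = 0
    for (stu, date), day_tx in log.groupby(["student_id", "date"]):
        day_tx = day_tx.sort_values("time")
        groups = brute_force_segments(day_tx["time"].tolist())
        n_expected += len(groups)
        got = all_meals[(all_meals["student_id"] == stu) & (all_meals["date"] == date)]
        got = got.sort_values("start_time")
        assert len(got) == len(groups)
        for meal_row, idx in zip(got.itertuples(), groups):
            members = day_tx.iloc[idx]
            assert meal_row.start_time == members["time"].iloc[0]
            assert meal_row.expenditure == pytest.approx(members["amount"].sum(), abs=0.005)
            assert meal_row.n_transactions == len(idx)
    assert len(all_meals) == n_expected


@pytest.mark.parametrize("t,expected_class,flagged", [
    (hms(7, 10), "breakfast", False),
    (hms(6, 30), "breakfast", False),
    (hms(13, 0), "lunch", False),       # inclusive upper bound
    (hms(11, 0), "lunch", False),
    (hms(17, 30), "dinner", False),
    (hms(9, 45), "breakfast", True),    # equidistant: tie to the earlier slot
    (hms(10, 0), "lunch", True),
    (hms(23, 0), "dinner", True),
    (hms(2, 0), "breakfast", True),
])
def test_classify_meal_slots(t, expected_class, flagged):
    meal = Meal("s", "2020-10-05", t, 5.0, 1, frozenset({"x"}), 1)
    assert classify_meal(meal) == expected_class
    assert meal.out_of_slot == flagged


def test_classification_matches_oracle(rng):
    for t in rng.integers(0, 86400, 500):
        meal = Meal("s", "d", int(t), 1.0, 1, frozenset({"x"}), 1)
        cls = classify_meal(meal)
        want_cls, want_flag = brute_force_slot(int(t))
        assert (cls, meal.out_of_slot) == (want_cls, want_flag)


def _meal(t, cls=None, flagged=False):
    m = Meal("s", "2020-10-05", t, 5.0, 1, frozenset({"x"}), 1)
    if cls is None:
        classify_meal(m)
    else:
        m.meal_class, m.out_of_slot = cls, flagged
    return m


def test_dedupe_no_collision_is_identity():
    meals = [_meal(hms(7)), _meal(hms(12))]
    kept, dropped = dedupe_meal_classes(meals)
    assert kept == meals and dropped == []


def test_dedupe_prefers_in_slot_then_earlier():
    in_slot = _meal(hms(11, 10))
    flagged = _meal(hms(13, 40))
    assert flagged.meal_class == "lunch" and flagged.out_of_slot
    kept, dropped = dedupe_meal_classes([in_slot, flagged])
    assert kept == [in_slot] and dropped == [flagged]

    early = _meal(hms(11, 10))
    late = _meal(hms(12, 50))
    kept, _ = dedupe_meal_classes([early, late])
    assert kept == [early]


def test_dedupe_adversarial_days_leave_one_per_class(rng):
    for _ in range(50):
        times = sorted(rng.integers(0, 86400, rng.integers(2, 8)))
        meals = [_meal(int(t)) for t in times]
        kept, dropped = dedupe_meal_classes(meals)
        classes = [m.meal_class for m in kept]
        assert len(classes) == len(set(classes))
        assert len(kept) + len(dropped) == len(meals)


def test_at_most_three_meals_per_day_closest_to_slots(rng):
    times = [hms(1), hms(4), hms(7), hms(12), hms(15), hms(18), hms(22)]
    tx = make_transactions(times)
    meals = MealSegmenter().fit_transform(tx)
    assert len(meals) <= 3
    # the three in/near-slot anchors survive
    assert set(meals["start_time"]) == {hms(7), hms(12), hms(18)}


def test_segmentation_idempotent(tiny_meals):
    """Feeding meals back through as one-transaction events is a no-op."""
    _, _, meals = tiny_meals
    as_tx = pd.DataFrame({
        "student_id": meals["student_id"], "date": meals["date"],
        "time": meals["start_time"], "amount": meals["expenditure"],
        "cafeteria_id": meals["cafeteria_id"],
        "item_id": meals["item_ids"].map(lambda s: "+".join(sorted(s))),
    })
    again = MealSegmenter().fit_transform(as_tx)
    assert len(again) == len(meals)
    a = again.sort_values(["student_id", "date", "start_time"]).reset_index(drop=True)
    b = meals.sort_values(["student_id", "date", "start_time"]).reset_index(drop=True)
    assert (a["start_time"].to_numpy() == b["start_time"].to_numpy()).all()
    assert np.allclose(a["expenditure"], b["expenditure"])
    assert (a["meal_class"].to_numpy() == b["meal_class"].to_numpy()).all()


def test_expenditure_conserved_through_dedupe(rng):
    times = sorted(rng.integers(0, 86400, 20))
    tx = make_transactions(times, amount=np.round(rng.uniform(1, 10, 20), 2).tolist())
    seg = MealSegmenter()
    kept = seg.fit_transform(tx)
    total = kept["expenditure"].sum() + seg.dropped_["expenditure"].sum()
    assert total == pytest.approx(tx["amount"].sum(), abs=1e-6)


def test_tied_timestamps_are_order_insensitive(rng):
    tx = make_transactions([hms(12), hms(12), hms(12, 30)],
                           amount=[1.0, 2.0, 3.0], items=["a", "b", "c"])
    shuffled = tx.sample(frac=1, random_state=1).reset_index(drop=True)
    m1 = MealSegmenter().fit_transform(tx)
    m2 = MealSegmenter().fit_transform(shuffled)
    pd.testing.assert_frame_equal(m1, m2)


def test_drop_out_of_slot_switch():
    tx = make_transactions([hms(9, 45)])
    kept = MealSegmenter(drop_out_of_slot=True).fit_transform(tx)
    assert len(kept) == 0
    kept = MealSegmenter(drop_out_of_slot=False).fit_transform(tx)
    assert len(kept) == 1 and kept["out_of_slot"].item()
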