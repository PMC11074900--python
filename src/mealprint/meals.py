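"""Meal segmentation and classification from raw cafeteria transactions.

A *meal* is a burst of electronic payments: the first transaction anchors the
meal and every later transaction within two hours of that anchor belongs to it.
Each meal is then assigned to one of three cafeteria operating slots
(breakfast 06:30-08:30, lunch 11:00-13:00, dinner 17:30-19:30) by its anchor
time; meals starting outside every slot are reassigned to the nearest slot and
flagged.  At most one meal per class per student-day survives deduplication,
and at most three meals per day are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Two-hour grouping window, in seconds: a transaction joins the current meal
#: iff its time is within this many seconds of the meal's first transaction.
MEAL_WINDOW_S = 7200

#: Cafeteria operating slots, seconds since midnight, both bounds inclusive.
MEAL_SLOTS: dict[str, tuple[int, int]] = {
    "breakfast": (6 * 3600 + 30 * 60, 8 * 3600 + 30 * 60),  # 06:30-08:30
    "lunch": (11 * 3600, 13 * 3600),                        # 11:00-13:00
    "dinner": (17 * 3600 + 30 * 60, 19 * 3600 + 30 * 60),   # 17:30-19:30
}

MEAL_CLASSES = ("breakfast", "lunch", "dinner")

#: Maximum meals retained per student-day.
MAX_MEALS_PER_DAY = 3

TRANSACTION_COLUMNS = ["student_id", "date", "time", "amount", "cafeteria_id", "item_id"]

MEAL_COLUMNS = [
    "student_id", "date", "meal_class", "start_time", "expenditure",
    "cafeteria_id", "item_ids", "n_items", "n_transactions", "out_of_slot",
]


@dataclass
class Meal:
    """One segmented eating episode."""

    student_id: str
    date: str
    start_time: int
    expenditure: float
    cafeteria_id: int
    item_ids: frozenset
    n_transactions: int
    meal_class: str | None = None
    out_of_slot: bool = False


def segment_meals(transactions: pd.DataFrame) -> list[Meal]:
    """Segment one student-day of transactions into meals.

    Greedy anchored grouping: the first transaction anchors the first meal;
    each subsequent transaction joins the current meal iff it falls within
    ``MEAL_WINDOW_S`` of the anchor, otherwise it anchors a new meal.

    Parameters
    ----------
    transactions : DataFrame with the transaction schema, all rows sharing
        one ``student_id`` and ``date``, sorted ascending by ``time``.

    Returns
    -------
    list of Meal, in time order, unclassified (``meal_class`` is None).

    Raises
    ------
    ValueError if the rows mix students/dates or are unsorted.
    """
    if len(transactions) == 0:
        return []
    if transactions["student_id"].nunique() > 1 or transactions["date"].nunique() > 1:
        raise ValueError("segment_meals expects a single student-day of transactions")
    times = transactions["time"].to_numpy()
    if np.any(np.diff(times) < 0):
        raise ValueError("transactions must be sorted ascending by time")

    meals: list[Meal] = []
    rows = transactions.to_dict("records")
    current: list[dict] = []
    anchor = None
    for row in rows:
        if anchor is None or row["time"] > anchor + MEAL_WINDOW_S:
            if current:
                meals.append(_finish(current))
            current = [row]
            anchor = row["time"]
        else:
            current.append(row)
    meals.append(_finish(current))
    return meals


def _finish(rows: list[dict]) -> Meal:
    items: set = set()
    for r in rows:
        items.update(str(r["item_id"]).split("+"))
    return Meal(
        student_id=rows[0]["student_id"],
        date=rows[0]["date"],
        start_time=int(rows[0]["time"]),
        expenditure=round(float(sum(r["amount"] for r in rows)), 2),
        cafeteria_id=int(rows[0]["cafeteria_id"]),
        item_ids=frozenset(items),
        n_transactions=len(rows),
    )


def slot_gap(start_time, meal_class: str):
    """Distance in seconds from a start time to a slot interval (0 inside)."""
    lo, hi = MEAL_SLOTS[meal_class]
    t = np.asarray(start_time)
    return np.maximum(np.maximum(lo - t, t - hi), 0)


def classify_meal(meal: Meal) -> str:
    """Assign a meal class by the anchor time.

    In-slot times map to their slot; out-of-slot times map to the nearest
    slot by absolute gap (ties to the earlier slot) and the meal is flagged
    ``out_of_slot``.
    """
    gaps = [int(slot_gap(meal.start_time, c)) for c in MEAL_CLASSES]
    k = int(np.argmin(gaps))  # argmin takes the first minimum: ties -> earlier slot
    meal.meal_class = MEAL_CLASSES[k]
    meal.out_of_slot = gaps[k] > 0
    return meal.meal_class


def dedupe_meal_classes(meals: list[Meal]) -> tuple[list[Meal], list[Meal]]:
    """Resolve class collisions within one student-day.

    If two meals share a class, keep the in-slot one; if both or neither are
    in slot, keep the earlier.  Returns (kept, dropped), kept in time order.
    """
    best: dict[str, Meal] = {}
    dropped: list[Meal] = []
    for m in meals:
        if m.meal_class is None:
            raise ValueError("dedupe_meal_classes requires classified meals")
        cur = best.get(m.meal_class)
        if cur is None:
            best[m.meal_class] = m
        else:
            # sort key: in-slot first, then earlier start
            keep, drop = sorted([cur, m], key=lambda x: (x.out_of_slot, x.start_time))
            best[m.meal_class] = keep
            dropped.append(drop)
    kept = sorted(best.values(), key=lambda x: x.start_time)
    return kept, dropped


@dataclass
class MealSegmenter:
    """Batch transformer: raw transaction log -> deduplicated meals table.

    sklearn-style: ``transform`` maps the full transaction DataFrame (any
    number of students and days) to a meals DataFrame with one row per
    retained meal.  Stateless; ``fit`` is a no-op kept for pipeline
    compatibility.  Dropped meals (class collisions, >3 meals/day trims) are
    recorded on the instance after each transform.

    Parameters
    ----------
    drop_out_of_slot : if True, out-of-slot meals are discarded instead of
        being reassigned to the nearest slot (default False: reassign+flag).
    """

    drop_out_of_slot: bool = False
    dropped_: pd.DataFrame = field(default=None, repr=False)

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"drop_out_of_slot": self.drop_out_of_slot}

    def set_params(self, **params):
        for k, v in params.items():
            if k != "drop_out_of_slot":
                raise ValueError(f"unknown parameter {k!r}")
            self.drop_out_of_slot = v
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(X)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        if len(X) == 0:
            self.dropped_ = pd.DataFrame(columns=MEAL_COLUMNS)
            return pd.DataFrame(columns=MEAL_COLUMNS)
        df = X.sort_values(
            ["student_id", "date", "time", "amount", "item_id"], kind="mergesort"
        ).reset_index(drop=True)
        key = df["student_id"].astype(str) + "\x1f" + df["date"].astype(str)
        meal_idx = _anchored_segments(key.to_numpy(), df["time"].to_numpy(float))
        df["_meal"] = meal_idx
        meals = _aggregate(df)
        meals = _classify_frame(meals)
        meals, dropped = _dedupe_and_trim(meals, self.drop_out_of_slot)
        self.dropped_ = dropped.reset_index(drop=True)
        return meals.reset_index(drop=True)


def _anchored_segments(key: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Vectorised anchored 2 h grouping over many student-days.

    Iteratively peels off one meal per student-day: take the earliest
    unassigned transaction per day as the anchor, absorb everything within
    the window, repeat.  The iteration count is the maximum number of meals
    on any day, so this is a handful of vectorised passes.
    """
    n = len(times)
    meal = np.full(n, -1, dtype=np.int64)
    remaining = np.ones(n, dtype=bool)
    k = 0
    while remaining.any():
        idx = np.flatnonzero(remaining)
        sub = pd.Series(times[idx], index=pd.Index(key[idx]))
        anchors = sub.groupby(level=0, sort=False).transform("first").to_numpy()
        member = times[idx] <= anchors + MEAL_WINDOW_S
        meal[idx[member]] = k
        remaining[idx[member]] = False
        k += 1
    return meal


def _aggregate(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby(["student_id", "date", "_meal"], sort=True)
    meals = g.agg(
        start_time=("time", "first"),
        expenditure=("amount", "sum"),
        cafeteria_id=("cafeteria_id", "first"),
        n_transactions=("time", "size"),
    ).reset_index()
    items = (
        df.assign(_items=df["item_id"].astype(str))
        .groupby(["student_id", "date", "_meal"], sort=True)["_items"]
        .agg(lambda s: frozenset(x for v in s for x in v.split("+")))
        .reset_index(name="item_ids")
    )
    meals = meals.merge(items, on=["student_id", "date", "_meal"])
    meals["n_items"] = meals["item_ids"].map(len)
    meals["expenditure"] = meals["expenditure"].round(2)
    meals["start_time"] = meals["start_time"].astype(int)
    return meals.drop(columns="_meal")


def _classify_frame(meals: pd.DataFrame) -> pd.DataFrame:
    t = meals["start_time"].to_numpy()
    gaps = np.stack([slot_gap(t, c) for c in MEAL_CLASSES], axis=1)
    k = np.argmin(gaps, axis=1)
    meals["meal_class"] = np.asarray(MEAL_CLASSES, dtype=object)[k]
    meals["out_of_slot"] = gaps[np.arange(len(meals)), k] > 0
    meals["_slot_gap"] = gaps[np.arange(len(meals)), k]
    return meals


def _dedupe_and_trim(meals: pd.DataFrame, drop_out_of_slot: bool) -> tuple[pd.DataFrame, pd.DataFrame]:
    dropped_parts = []
    if drop_out_of_slot:
        dropped_parts.append(meals[meals["out_of_slot"]])
        meals = meals[~meals["out_of_slot"]]

    # >3 meals/day: keep the 3 whose start times are closest to any slot
    order = meals.sort_values(
        ["student_id", "date", "_slot_gap", "start_time"], kind="mergesort"
    )
    rank = order.groupby(["student_id", "date"], sort=False).cumcount()
    keep_mask = pd.Series(rank.to_numpy() < MAX_MEALS_PER_DAY, index=order.index)
    dropped_parts.append(order[~keep_mask])
    meals = order[keep_mask]

    # class collisions: prefer in-slot, then earlier
    order = meals.sort_values(
        ["student_id", "date", "meal_class", "out_of_slot", "start_time"],
        kind="mergesort",
    )
    first = ~order.duplicated(["student_id", "date", "meal_class"], keep="first")
    dropped_parts.append(order[~first])
    kept = order[first].sort_values(
        ["student_id", "date", "start_time"], kind="mergesort"
    )

    dropped = pd.concat(dropped_parts) if dropped_parts else meals.iloc[:0]
    return kept.drop(columns="_slot_gap"), dropped.drop(columns="_slot_gap", errors="ignore")


def segment_transactions(transactions: pd.DataFrame, drop_out_of_slot: bool = False) -> pd.DataFrame:
    """Functional wrapper over :class:`MealSegmenter`."""
    return MealSegmenter(drop_out_of_slot=drop_out_of_slot).fit_transform(transactions)


def meals_to_csv(meals: pd.DataFrame, path) -> None:
    out = meals.copy()
    out["item_ids"] = out["item_ids"].map(lambda s: "+".join(sorted(s)))
    out.to_csv(path, index=False)


def meals_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"student_id": str, "date": str})
    df["item_ids"] = df["item_ids"].map(lambda s: frozenset(str(s).split("+")))
    return df
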