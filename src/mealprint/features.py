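"""Per-student dietary behaviour features, stratified by weekday/weekend.

Six feature families are computed from the deduplicated meals table:

* time — summary statistics of meal start times per meal class;
* interval — statistics of pairwise gaps (breakfast-lunch, lunch-dinner,
  breakfast-dinner) within a day;
* expenditure — statistics of per-meal spending per class;
* location — share of visits to each of the three cafeterias, overall and
  per meal class;
* diversity & frequency — mean distinct food items per observed day and the
  fraction of calendar days on which each meal class was eaten;
* all-day patterns — the frequency of each of the 7 non-empty meal-class
  subsets (B, L, D, BL, LD, BD, BLD) over observed days.

Summary statistics are mean, median, MAD, max and min, where MAD is the
*median* absolute deviation from the median, unscaled (no 1.4826 consistency
factor): deviations are reported in the raw unit (seconds, yuan) as an
eating-regularity index.  A ``mad_kind="mean"`` toggle switches to the mean
absolute deviation.

Feature columns are named ``family.daytype[.mealclass].statistic``, e.g.
``time.weekday.lunch.mad``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meals import MEAL_CLASSES

STAT_NAMES = ("mean", "median", "mad", "max", "min")
PATTERNS = ("B", "L", "D", "BL", "LD", "BD", "BLD")
_PATTERN_CODE = {1: "B", 2: "L", 4: "D", 3: "BL", 6: "LD", 5: "BD", 7: "BLD"}
_CLASS_BIT = {"breakfast": 1, "lunch": 2, "dinner": 4}
PAIRS = (("breakfast", "lunch"), ("lunch", "dinner"), ("breakfast", "dinner"))
_PAIR_NAME = {("breakfast", "lunch"): "bre_lun", ("lunch", "dinner"): "lun_din",
              ("breakfast", "dinner"): "bre_din"}
DAY_TYPES = ("weekday", "weekend")


@dataclass
class SummaryStats:
    mean: float
    median: float
    mad: float
    max: float
    min: float


def summary_stats(values, mad_kind: str = "median") -> SummaryStats:
    """Five-number summary with a robust dispersion term.

    MAD defaults to median(|x - median(x)|); ``mad_kind="mean"`` gives the
    mean absolute deviation from the mean instead.

    Raises ValueError on an empty input — an empty feature cell is recorded
    as missing upstream, never as zero.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("summary_stats: empty input (feature should be marked missing)")
    if mad_kind == "median":
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
    elif mad_kind == "mean":
        mad = float(np.mean(np.abs(x - np.mean(x))))
    else:
        raise ValueError(f"unknown mad_kind {mad_kind!r}")
    return SummaryStats(
        mean=float(np.mean(x)), median=float(np.median(x)), mad=mad,
        max=float(np.max(x)), min=float(np.min(x)),
    )


def interval_features(day_meals: pd.DataFrame) -> dict:
    """Pairwise start-time gaps (seconds) for one student-day of deduped meals."""
    times = dict(zip(day_meals["meal_class"], day_meals["start_time"]))
    out = {}
    for a, b in PAIRS:
        if a in times and b in times:
            out[_PAIR_NAME[(a, b)]] = int(times[b]) - int(times[a])
    return out


def allday_pattern(day_meals: pd.DataFrame) -> str:
    """All-day pattern = the set of meal classes eaten that day."""
    classes = set(day_meals["meal_class"])
    if not classes:
        raise ValueError("allday_pattern: a day with zero meals has no pattern")
    return _PATTERN_CODE[sum(_CLASS_BIT[c] for c in classes)]


def pattern_frequency(daily_patterns) -> dict:
    """Frequency of each of the 7 patterns over days with >=1 meal."""
    s = pd.Series(list(daily_patterns))
    if len(s) == 0:
        return {p: np.nan for p in PATTERNS}
    counts = s.value_counts()
    return {p: float(counts.get(p, 0)) / len(s) for p in PATTERNS}


def location_shares(meals: pd.DataFrame, n_cafeterias: int = 3) -> dict:
    """Cafeteria visit shares, overall and per meal class, for one student."""
    out = {}
    counts = meals["cafeteria_id"].value_counts()
    total = len(meals)
    for k in range(1, n_cafeterias + 1):
        out[("overall", k)] = float(counts.get(k, 0)) / total if total else np.nan
    for cls in MEAL_CLASSES:
        sub = meals[meals["meal_class"] == cls]
        counts = sub["cafeteria_id"].value_counts()
        for k in range(1, n_cafeterias + 1):
            out[(cls, k)] = float(counts.get(k, 0)) / len(sub) if len(sub) else np.nan
    return out


def diversity_and_meal_frequency(meals: pd.DataFrame, n_calendar_days: int) -> tuple:
    """(mean distinct items per observed day, per-class fraction of calendar days)."""
    day_items = meals.groupby("date")["item_ids"].agg(lambda s: len(frozenset().union(*s)))
    diversity = float(day_items.mean()) if len(day_items) else np.nan
    freq = {}
    for cls in MEAL_CLASSES:
        n_days = meals.loc[meals["meal_class"] == cls, "date"].nunique()
        freq[cls] = n_days / n_calendar_days if n_calendar_days else np.nan
    return diversity, freq


class DietaryFeatureExtractor:
    """Transformer: deduplicated meals table -> wide per-student feature matrix.

    Parameters
    ----------
    calendar : DataFrame with columns date, day_type — defines which dates
        are weekday vs weekend and the meal-frequency denominators.
    pattern_denominator : "observed_days" (default) divides pattern counts by
        days with >=1 recorded meal; "calendar_days" divides by all calendar
        days of the day-type.
    mad_kind : "median" (default) or "mean" — see :func:`summary_stats`.
    n_cafeterias : catalogue of cafeteria ids expected in the log.
    """

    def __init__(self, calendar: pd.DataFrame, pattern_denominator: str = "observed_days",
                 mad_kind: str = "median", n_cafeterias: int = 3):
        if pattern_denominator not in ("observed_days", "calendar_days"):
            raise ValueError(f"unknown pattern_denominator {pattern_denominator!r}")
        self.calendar = calendar
        self.pattern_denominator = pattern_denominator
        self.mad_kind = mad_kind
        self.n_cafeterias = n_cafeterias

    def get_params(self, deep: bool = True) -> dict:
        return {"calendar": self.calendar, "pattern_denominator": self.pattern_denominator,
                "mad_kind": self.mad_kind, "n_cafeterias": self.n_cafeterias}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, meals: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(meals)

    def fit_transform(self, meals: pd.DataFrame, y=None) -> pd.DataFrame:
        if len(meals) == 0:
            return pd.DataFrame()
        cal = self.calendar
        df = meals.merge(cal, on="date", how="left")
        if df["day_type"].isna().any():
            bad = df.loc[df["day_type"].isna(), "date"].unique()[:3]
            raise ValueError(f"meals on dates missing from the calendar: {list(bad)}")
        students = pd.Index(sorted(meals["student_id"].unique()), name="student_id")
        parts = []
        for day_type in DAY_TYPES:
            sub = df[df["day_type"] == day_type]
            n_cal_days = int((cal["day_type"] == day_type).sum())
            parts.append(self._day_type_features(sub, students, day_type, n_cal_days))
        return pd.concat(parts, axis=1)

    # -- internals ---------------------------------------------------------

    def _stats_block(self, frame: pd.DataFrame, keys: list, value: str,
                     students: pd.Index, prefix_of) -> pd.DataFrame:
        """Per-group five-number summaries, reshaped to wide per-student."""
        if len(frame) == 0:
            return pd.DataFrame(index=students)
        g = frame.groupby(keys)[value]
        agg = g.agg(mean="mean", median="median", max="max", min="min")
        if self.mad_kind == "median":
            center = g.transform("median")
            agg["mad"] = (frame[value] - center).abs().groupby(
                [frame[k] for k in keys]).median()
        else:
            center = g.transform("mean")
            agg["mad"] = (frame[value] - center).abs().groupby(
                [frame[k] for k in keys]).mean()
        out = pd.DataFrame(index=students)
        agg = agg.reset_index()
        level_keys = [k for k in keys if k != "student_id"]
        for _, grp in agg.groupby(level_keys) if level_keys else [((), agg)]:
            prefix = prefix_of(grp.iloc[0])
            block = grp.set_index("student_id")[list(STAT_NAMES)]
            block.columns = [f"{prefix}.{s}" for s in STAT_NAMES]
            out = out.join(block)
        return out

    def _day_type_features(self, sub: pd.DataFrame, students: pd.Index,
                           day_type: str, n_cal_days: int) -> pd.DataFrame:
        blocks = [pd.DataFrame(index=students)]

        # time and expenditure statistics per meal class
        blocks.append(self._stats_block(
            sub, ["student_id", "meal_class"], "start_time", students,
            lambda r: f"time.{day_type}.{r['meal_class']}"))
        blocks.append(self._stats_block(
            sub, ["student_id", "meal_class"], "expenditure", students,
            lambda r: f"expenditure.{day_type}.{r['meal_class']}"))

        # pairwise intervals
        wide = sub.pivot_table(index=["student_id", "date"], columns="meal_class",
                               values="start_time", aggfunc="first")
        gaps = []
        for a, b in PAIRS:
            if a in wide.columns and b in wide.columns:
                gap = (wide[b] - wide[a]).dropna()
                gaps.append(pd.DataFrame({
                    "student_id": gap.index.get_level_values("student_id"),
                    "pair": _PAIR_NAME[(a, b)], "gap": gap.to_numpy(),
                }))
        if gaps:
            gaps = pd.concat(gaps, ignore_index=True)
            blocks.append(self._stats_block(
                gaps, ["student_id", "pair"], "gap", students,
                lambda r: f"interval.{day_type}.{r['pair']}"))

        # location shares
        total = sub.groupby("student_id").size()
        caf = sub.groupby(["student_id", "cafeteria_id"]).size().unstack(fill_value=0)
        caf = caf.reindex(columns=range(1, self.n_cafeterias + 1), fill_value=0)
        overall = caf.div(total, axis=0)
        overall.columns = [f"location.{day_type}.overall.caf{k}" for k in overall.columns]
        blocks.append(overall.reindex(students))
        for cls in MEAL_CLASSES:
            cls_sub = sub[sub["meal_class"] == cls]
            cls_tot = cls_sub.groupby("student_id").size()
            caf = cls_sub.groupby(["student_id", "cafeteria_id"]).size().unstack(fill_value=0)
            caf = caf.reindex(columns=range(1, self.n_cafeterias + 1), fill_value=0)
            share = caf.div(cls_tot, axis=0)
            share.columns = [f"location.{day_type}.{cls}.caf{k}" for k in share.columns]
            blocks.append(share.reindex(students))

        # diversity: mean distinct items per observed day
        exploded = sub[["student_id", "date", "item_ids"]].copy()
        exploded["item_ids"] = exploded["item_ids"].map(list)
        exploded = exploded.explode("item_ids")
        day_count = exploded.groupby(["student_id", "date"])["item_ids"].nunique()
        diversity = day_count.groupby("student_id").mean()
        diversity.name = f"diversity.{day_type}.mean_items"
        blocks.append(diversity.reindex(students).to_frame())

        # meal frequency over calendar days of this day-type
        for cls in MEAL_CLASSES:
            n_days = (sub[sub["meal_class"] == cls]
                      .groupby("student_id")["date"].nunique())
            freq = (n_days / n_cal_days) if n_cal_days else n_days * np.nan
            freq = freq.reindex(students).fillna(0.0 if n_cal_days else np.nan)
            freq.name = f"frequency.{day_type}.{cls}"
            blocks.append(freq.to_frame())

        # all-day patterns over observed days
        bits = sub["meal_class"].map(_CLASS_BIT)
        code = bits.groupby([sub["student_id"], sub["date"]]).sum()
        pat = code.map(_PATTERN_CODE)
        counts = (pat.groupby(["student_id", pat]).size()
                  .unstack(fill_value=0).reindex(columns=PATTERNS, fill_value=0))
        observed = pat.groupby("student_id").size()
        if self.pattern_denominator == "observed_days":
            denom = observed
        else:
            denom = pd.Series(n_cal_days, index=observed.index, dtype=float)
        pat_freq = counts.div(denom, axis=0)
        pat_freq.columns = [f"pattern.{day_type}.{p}" for p in pat_freq.columns]
        blocks.append(pat_freq.reindex(students))

        obs = observed.reindex(students).fillna(0).astype(float)
        obs.name = f"meta.{day_type}.n_days_observed"
        blocks.append(obs.to_frame())

        return pd.concat(blocks, axis=1)


class ZScoreBander:
    """Standardise features over the cohort and code SD bands.

    ``fit`` learns per-column mean and SD over all included students (the
    three groups pooled), dropping zero-variance columns with a log entry;
    ``transform`` returns z-scores; :meth:`to_bands` maps z to the SD bands
    Rare (z < -1), Normal (-1 <= z <= 1) and Always (z > 1).  ``ddof``
    selects sample (1, default) or population (0) SD.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def get_params(self, deep: bool = True) -> dict:
        return {"ddof": self.ddof}

    def set_params(self, **params):
        for k, v in params.items():
            if k != "ddof":
                raise ValueError(f"unknown parameter {k!r}")
            self.ddof = v
        return self

    def fit(self, X: pd.DataFrame, y=None):
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=self.ddof)
        keep = sd > 0
        self.dropped_ = list(X.columns[~keep])
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        self.columns_ = list(X.columns[keep])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.columns_] - self.mean_) / self.sd_

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    @staticmethod
    def to_bands(z: pd.DataFrame) -> pd.DataFrame:
        band = pd.DataFrame("Normal", index=z.index, columns=z.columns, dtype=object)
        band = band.where(z >= -1, "Rare").where(z <= 1, "Always")
        return band.where(z.notna(), np.nan)


def zscore_and_band(features: pd.DataFrame, ddof: int = 1):
    """(z matrix, band matrix, dropped zero-variance columns) for a cohort."""
    bander = ZScoreBander(ddof=ddof)
    z = bander.fit_transform(features)
    return z, bander.to_bands(z), bander.dropped_


def data_dictionary(columns) -> pd.DataFrame:
    """Human-readable description of each feature column."""
    fam_desc = {
        "time": "meal start time (seconds since midnight)",
        "interval": "gap between meal starts (seconds)",
        "expenditure": "per-meal spending (yuan)",
        "location": "share of visits to a cafeteria",
        "diversity": "mean distinct food items per observed day",
        "frequency": "fraction of calendar days with this meal",
        "pattern": "fraction of observed days with this all-day pattern",
        "meta": "bookkeeping",
    }
    rows = []
    for col in columns:
        fam = col.split(".", 1)[0]
        rows.append({"column": col, "family": fam,
                     "description": fam_desc.get(fam, "")})
    return pd.DataFrame(rows)
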