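"""Synthetic cafeteria-transaction and screening-survey generator.

Emulates a one-month campus study in which every meal is paid electronically:
three cafeterias, three daily meal slots, and a screening survey (PHQ-9,
GAD-7, PSS-14, ISI) taken once.  Students belong to one of three groups —
healthy controls (HC), mild depression, moderate-severe depression — and the
group presets encode the behavioural contrasts of interest: higher breakfast
skipping, larger lunch/dinner timing jitter, a dinner-expenditure shift and
lower food diversity in moderate-severe depression, plus survey scores whose
PHQ-9/GAD-7 coupling supports mediation analyses.

The generative laws, per (student, calendar day, meal class):

* skip ~ Bernoulli(p_skip[class, day-type]); otherwise a meal is emitted;
* meal time ~ Normal(mean, jitter_sd) truncated to the class's operating
  slot, so downstream slot classification is unambiguous;
* expenditure ~ LogNormal(log_mean, log_sd), rounded to cents;
* distinct items ~ 1 + Poisson(items_rate - 1), drawn without replacement
  from a 50-item per-cafeteria catalogue;
* the meal is split into 1/2/3 transactions with probabilities 0.7/0.2/0.1,
  amounts partitioned by a uniform Dirichlet, extra transaction times drawn
  uniformly between the anchor time and the slot end.

Everything is driven by one ``numpy`` Generator, so a fixed (config, seed)
pair reproduces the output byte for byte.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .meals import MEAL_CLASSES, MEAL_SLOTS

GROUPS = ("HC", "mild", "moderate_severe")
DAY_TYPES = ("weekday", "weekend")
INSTRUMENT_RANGES = {"phq9": (0, 27), "gad7": (0, 21), "pss14": (0, 56), "isi": (0, 28)}
#: PHQ-9 screening bands per group (inclusive).
PHQ9_BANDS = {"HC": (0, 4), "mild": (5, 9), "moderate_severe": (10, 27)}
#: HC must additionally screen negative on the comorbidity instruments.
HC_CAPS = {"gad7": 4, "pss14": 28, "isi": 7}

N_CAFETERIAS = 3
CATALOGUE_SIZE = 50  # distinct item ids per cafeteria
TXN_SPLIT_PROBS = (0.7, 0.2, 0.1)  # P(1), P(2), P(3) transactions per meal

SURVEY_COLUMNS = [
    "student_id", "age", "gender", "bmi_class", "education",
    "phq9", "gad7", "pss14", "isi",
]


class ValidationError(ValueError):
    """Raised when a preset or config field fails validation."""


@dataclass
class SurveyParams:
    """Location/scale per screening instrument plus the PHQ-9/GAD-7 coupling.

    ``coupling`` is the correlation between the latent (pre-discretisation)
    PHQ-9 and GAD-7 draws.
    """

    phq9_loc: float
    phq9_scale: float
    gad7_loc: float
    gad7_scale: float
    pss14_loc: float
    pss14_scale: float
    isi_loc: float
    isi_scale: float
    coupling: float = 0.6


@dataclass
class Demographics:
    age_mean: float = 19.5
    age_sd: float = 1.45
    p_male: float = 0.39
    bmi_probs: tuple = (0.13, 0.73, 0.14)       # lt18.5 / 18.5-24 / gt24
    edu_probs: tuple = (0.986, 0.009, 0.005)    # undergrad / postgrad / doctoral


@dataclass
class GroupPreset:
    """All generative parameters for one screening group."""

    group_name: str
    p_skip: dict                    # day_type -> meal_class -> prob
    meal_time_mean: dict            # meal_class -> seconds since midnight
    meal_time_jitter_sd: dict       # meal_class -> seconds
    expenditure_log_mean: dict      # meal_class -> log(yuan)
    expenditure_log_sd: dict        # meal_class -> log-scale SD
    items_rate: float               # mean distinct items per meal
    cafeteria_probs: tuple
    survey_score_params: SurveyParams
    demographics: Demographics = field(default_factory=Demographics)

    def validate(self) -> None:
        if self.group_name not in GROUPS:
            raise ValidationError(f"group_name: unknown group {self.group_name!r}")
        for day_type in DAY_TYPES:
            for cls in MEAL_CLASSES:
                p = self.p_skip[day_type][cls]
                if not 0 <= p <= 1:
                    raise ValidationError(f"p_skip[{day_type}][{cls}]: {p} not in [0,1]")
        for cls in MEAL_CLASSES:
            lo, hi = MEAL_SLOTS[cls]
            m = self.meal_time_mean[cls]
            if not lo <= m <= hi:
                raise ValidationError(
                    f"meal_time_mean[{cls}]: {m} outside operating slot [{lo},{hi}]"
                )
            if self.meal_time_jitter_sd[cls] < 0:
                raise ValidationError(f"meal_time_jitter_sd[{cls}]: negative")
            if self.expenditure_log_sd[cls] < 0:
                raise ValidationError(f"expenditure_log_sd[{cls}]: negative")
        if self.items_rate < 0:
            raise ValidationError("items_rate: negative")
        probs = np.asarray(self.cafeteria_probs, float)
        if len(probs) != N_CAFETERIAS or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValidationError("cafeteria_probs: must be a 3-vector summing to 1")
        if not -1 <= self.survey_score_params.coupling <= 1:
            raise ValidationError("survey_score_params.coupling: not in [-1,1]")


@dataclass
class SimulationConfig:
    n_per_group: dict               # group -> count
    calendar: pd.DataFrame          # columns date (ISO str), day_type
    seed: int
    presets: dict                   # group -> GroupPreset
    n_cafeterias: int = N_CAFETERIAS

    def validate(self) -> None:
        for g in GROUPS:
            n = self.n_per_group.get(g, 0)
            if n < 0 or int(n) != n:
                raise ValidationError(f"n_per_group[{g}]: must be a non-negative integer")
        if len(self.calendar) == 0:
            raise ValidationError("calendar: empty")
        dates = pd.to_datetime(self.calendar["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValidationError("calendar: dates must be strictly increasing")
        if set(self.calendar["day_type"]) - set(DAY_TYPES):
            raise ValidationError("calendar: day_type must be weekday/weekend")
        if self.n_cafeterias != N_CAFETERIAS:
            raise ValidationError("n_cafeterias: fixed at 3")
        for g, preset in self.presets.items():
            preset.validate()


def make_calendar(
    start: str = "2020-10-01",
    end: str = "2020-10-31",
    holiday_overrides: dict | None = None,
) -> pd.DataFrame:
    """Calendar with weekday/weekend from the real day-of-week.

    ``holiday_overrides`` maps ISO date strings to a day_type, for studies in
    which a public holiday should count as a weekend (default: none).
    """
    dates = pd.date_range(start, end, freq="D")
    day_type = np.where(dates.dayofweek >= 5, "weekend", "weekday")
    cal = pd.DataFrame({"date": dates.strftime("%Y-%m-%d"), "day_type": day_type})
    for date, kind in (holiday_overrides or {}).items():
        cal.loc[cal["date"] == date, "day_type"] = kind
    return cal


def default_presets() -> dict:
    """Presets encoding the canonical group contrasts.

    Timing jitter is calibrated so that the implied in-slot median absolute
    deviations sit near reported campus values (lunch ~17-19 min, dinner
    ~23-26 min, increasing with depression severity); breakfast skipping,
    dinner expenditure and item diversity shift in moderate-severe
    depression; survey locations/scales follow typical screening-cohort
    summaries for each band.
    """

    def p_skip(bw, lw, dw, be, le, de):
        return {
            "weekday": {"breakfast": bw, "lunch": lw, "dinner": dw},
            "weekend": {"breakfast": be, "lunch": le, "dinner": de},
        }

    times = {"breakfast": 26400, "lunch": 43200, "dinner": 66000}  # 07:20/12:00/18:20

    def preset(name, skip, jitter, dinner_log_mean, items_rate, survey, demo):
        return GroupPreset(
            group_name=name,
            p_skip=skip,
            meal_time_mean=dict(times),
            meal_time_jitter_sd=jitter,
            expenditure_log_mean={
                "breakfast": float(np.log(4.0)),
                "lunch": float(np.log(10.0)),
                "dinner": dinner_log_mean,
            },
            expenditure_log_sd={"breakfast": 0.35, "lunch": 0.30, "dinner": 0.30},
            items_rate=items_rate,
            cafeteria_probs=(0.40, 0.35, 0.25),
            survey_score_params=survey,
            demographics=demo,
        )

    return {
        "HC": preset(
            "HC",
            p_skip(0.25, 0.10, 0.10, 0.35, 0.12, 0.12),
            {"breakfast": 1200.0, "lunch": 1520.0, "dinner": 2085.0},
            float(np.log(10.0)),
            3.2,
            SurveyParams(1.42, 1.41, 0.49, 0.92, 15.77, 6.79, 1.78, 1.86),
            Demographics(19.46, 1.49, 0.3888, (0.1265, 0.7313, 0.1422), (0.9856, 0.0102, 0.0042)),
        ),
        "mild": preset(
            "mild",
            p_skip(0.28, 0.10, 0.10, 0.40, 0.12, 0.12),
            {"breakfast": 1250.0, "lunch": 1568.0, "dinner": 2104.0},
            float(np.log(11.0)),
            3.1,
            SurveyParams(6.58, 1.33, 3.60, 2.74, 23.08, 6.50, 5.42, 3.46),
            Demographics(19.48, 1.35, 0.3439, (0.1550, 0.7129, 0.1321), (0.9913, 0.0055, 0.0032)),
        ),
        "moderate_severe": preset(
            "moderate_severe",
            p_skip(0.45, 0.12, 0.10, 0.55, 0.14, 0.12),
            {"breakfast": 1400.0, "lunch": 1687.0, "dinner": 2329.0},
            float(np.log(11.5)),
            2.6,
            SurveyParams(12.94, 3.31, 7.47, 4.26, 32.41, 6.63, 8.93, 5.79),
            Demographics(19.64, 1.52, 0.4302, (0.1279, 0.7326, 0.1395), (0.9884, 0.0058, 0.0058)),
        ),
    }


def default_config(n_per_group=None, seed: int = 0, calendar: pd.DataFrame | None = None) -> SimulationConfig:
    if n_per_group is None:
        n_per_group = {"HC": 200, "mild": 200, "moderate_severe": 200}
    return SimulationConfig(
        n_per_group=dict(n_per_group),
        calendar=calendar if calendar is not None else make_calendar(),
        seed=int(seed),
        presets=default_presets(),
    )


def _truncnorm(rng, loc, scale, lo, hi, size):
    if scale == 0:
        return np.full(size, float(loc))
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return sps.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def survey_scores_for_group(group_name: str, preset: GroupPreset, rng, n: int = 1) -> pd.DataFrame:
    """Draw ``n`` survey score rows consistent with the group's screening band.

    PHQ-9 is a discretised truncated normal inside the band; GAD-7 is coupled
    to the latent PHQ-9 with correlation ``coupling`` then discretised and
    clipped to its range; PSS-14 and ISI are discretised truncated normals.
    HC draws are truncated below the HC screening caps (GAD-7 < 5,
    PSS-14 < 29, ISI < 8) so screening closure holds by construction.
    """
    preset.validate()
    sp = preset.survey_score_params
    lo, hi = PHQ9_BANDS[group_name]
    phq_lat = _truncnorm(rng, sp.phq9_loc, sp.phq9_scale, lo - 0.499, hi + 0.499, n)
    phq = np.clip(np.rint(phq_lat), lo, hi).astype(int)

    z = (phq_lat - sp.phq9_loc) / max(sp.phq9_scale, 1e-12)
    rho = sp.coupling
    eps = rng.standard_normal(n)
    gad_lat = sp.gad7_loc + sp.gad7_scale * (rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps)
    gad_hi = HC_CAPS["gad7"] if group_name == "HC" else INSTRUMENT_RANGES["gad7"][1]
    gad = np.clip(np.rint(gad_lat), 0, gad_hi).astype(int)

    def comorbid(loc, scale, cap_key, range_key):
        hi_ = HC_CAPS[cap_key] if group_name == "HC" else INSTRUMENT_RANGES[range_key][1]
        x = _truncnorm(rng, loc, scale, -0.499, hi_ + 0.499, n)
        return np.clip(np.rint(x), 0, hi_).astype(int)

    pss = comorbid(sp.pss14_loc, sp.pss14_scale, "pss14", "pss14")
    isi = comorbid(sp.isi_loc, sp.isi_scale, "isi", "isi")
    return pd.DataFrame({"phq9": phq, "gad7": gad, "pss14": pss, "isi": isi})


def _demographics(demo: Demographics, rng, n: int) -> pd.DataFrame:
    age = np.clip(np.rint(rng.normal(demo.age_mean, demo.age_sd, n)), 16, 35).astype(int)
    gender = np.where(rng.random(n) < demo.p_male, "male", "female")
    bmi = rng.choice(np.array(["lt18.5", "18.5-24", "gt24"], dtype=object), size=n,
                     p=np.asarray(demo.bmi_probs) / np.sum(demo.bmi_probs))
    edu = rng.choice(np.array(["undergrad", "postgrad", "doctoral"], dtype=object), size=n,
                     p=np.asarray(demo.edu_probs) / np.sum(demo.edu_probs))
    return pd.DataFrame({"age": age, "gender": gender, "bmi_class": bmi, "education": edu})


def _group_transactions(ids, preset: GroupPreset, calendar: pd.DataFrame, rng) -> pd.DataFrame:
    """Vectorised transaction log for one group (all students x days x classes)."""
    n_students, n_days = len(ids), len(calendar)
    dates = calendar["date"].to_numpy()
    is_weekend = (calendar["day_type"] == "weekend").to_numpy()

    frames = []
    for cls in MEAL_CLASSES:
        p_skip_day = np.where(
            is_weekend, preset.p_skip["weekend"][cls], preset.p_skip["weekday"][cls]
        )
        eat = rng.random((n_students, n_days)) >= p_skip_day[None, :]
        n_meals = int(eat.sum())
        if n_meals == 0:
            continue
        stu_idx, day_idx = np.nonzero(eat)

        lo, hi = MEAL_SLOTS[cls]
        t = np.rint(
            _truncnorm(rng, preset.meal_time_mean[cls], preset.meal_time_jitter_sd[cls],
                       lo, hi, n_meals)
        ).astype(int)
        t = np.clip(t, lo, hi)
        exp = np.round(
            rng.lognormal(preset.expenditure_log_mean[cls], preset.expenditure_log_sd[cls],
                          n_meals), 2
        )
        exp = np.maximum(exp, 0.01)
        n_items = 1 + rng.poisson(max(preset.items_rate - 1.0, 0.0), n_meals)
        n_items = np.minimum(n_items, CATALOGUE_SIZE)
        caf = rng.choice(np.arange(1, N_CAFETERIAS + 1), size=n_meals,
                         p=np.asarray(preset.cafeteria_probs, float))
        n_txn = rng.choice(np.array([1, 2, 3]), size=n_meals, p=TXN_SPLIT_PROBS)

        # distinct item codes per meal, without replacement from the
        # cafeteria's catalogue; the anchor transaction carries the full set
        scores = rng.random((n_meals, CATALOGUE_SIZE)).argsort(axis=1)
        item_strings = np.empty(n_meals, dtype=object)
        first_items = np.empty(n_meals, dtype=object)
        for i in range(n_meals):
            codes = [f"C{caf[i]}-I{j:02d}" for j in scores[i, : n_items[i]]]
            item_strings[i] = "+".join(codes)
            first_items[i] = codes[0]

        # expand meals into transactions
        row_meal = np.repeat(np.arange(n_meals), n_txn)
        n_rows = len(row_meal)
        offsets = np.concatenate(([0], np.cumsum(n_txn)))[:-1]
        is_anchor = np.zeros(n_rows, dtype=bool)
        is_anchor[offsets] = True

        extra = np.rint(t[row_meal] + rng.random(n_rows) * (hi - t[row_meal])).astype(int)
        times = np.where(is_anchor, t[row_meal], extra)

        # uniform-Dirichlet split of the meal expenditure over transactions;
        # non-anchor amounts are floored to the cent and the anchor takes the
        # exact remainder, so each meal's amounts sum to the drawn expenditure
        # and every amount stays non-negative
        w = rng.gamma(1.0, 1.0, n_rows)
        wsum = np.add.reduceat(w, offsets)
        exact = exp[row_meal] * w / wsum[row_meal]
        amounts = np.floor(exact * 100 + 1e-9) / 100
        asum = np.add.reduceat(amounts, offsets)
        amounts[offsets] = np.round(exp - (asum - amounts[offsets]), 2)

        item_col = np.where(is_anchor, item_strings[row_meal], first_items[row_meal])

        frames.append(pd.DataFrame({
            "student_id": ids[stu_idx][row_meal],
            "date": dates[day_idx][row_meal],
            "time": times,
            "amount": amounts,
            "cafeteria_id": caf[row_meal],
            "item_id": item_col,
        }))
    if not frames:
        return _empty_log()
    return pd.concat(frames, ignore_index=True)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame({
        "student_id": pd.Series(dtype=object), "date": pd.Series(dtype=object),
        "time": pd.Series(dtype=int), "amount": pd.Series(dtype=float),
        "cafeteria_id": pd.Series(dtype=int), "item_id": pd.Series(dtype=object),
    })


def generate_cohort(config: SimulationConfig):
    """Generate (survey_table, transaction_log, ground_truth) for one study.

    One survey row per student; transactions only on calendar dates, each
    simulated meal contributing 1-3 rows whose first timestamp is the drawn
    meal time and whose amounts sum to the drawn expenditure.  ``ground_truth``
    echoes every preset parameter per group for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    surveys, logs = [], []
    counter = 0
    for g in GROUPS:
        n = int(config.n_per_group.get(g, 0))
        if n == 0:
            continue
        preset = config.presets[g]
        ids = np.array([f"S{counter + i:05d}" for i in range(n)], dtype=object)
        counter += n
        scores = survey_scores_for_group(g, preset, rng, n)
        demo = _demographics(preset.demographics, rng, n)
        surveys.append(pd.concat(
            [pd.DataFrame({"student_id": ids}), demo, scores], axis=1
        ).assign(group=g))
        logs.append(_group_transactions(ids, preset, config.calendar, rng))

    survey_table = (
        pd.concat(surveys, ignore_index=True) if surveys
        else pd.DataFrame(columns=SURVEY_COLUMNS + ["group"])
    )
    log = pd.concat(logs, ignore_index=True) if logs else _empty_log()
    log = log.sort_values(
        ["student_id", "date", "time", "amount", "item_id"], kind="mergesort"
    ).reset_index(drop=True)

    ground_truth = {
        "seed": config.seed,
        "n_per_group": dict(config.n_per_group),
        "presets": {g: asdict(p) for g, p in config.presets.items()},
    }
    return survey_table, log, ground_truth


def asdict_presets(presets: dict) -> dict:
    return {g: asdict(p) for g, p in presets.items()}


# ---------------------------------------------------------------------------
# CSV / YAML round-trips (external interfaces)

def seconds_to_hms(seconds) -> pd.Series:
    s = pd.Series(np.asarray(seconds, dtype=int))
    if len(s) == 0:
        return s.astype(str)
    return (
        (s // 3600).map("{:02d}".format) + ":"
        + (s % 3600 // 60).map("{:02d}".format) + ":"
        + (s % 60).map("{:02d}".format)
    )


def hms_to_seconds(hms) -> np.ndarray:
    if len(hms) == 0:
        return np.array([], dtype=int)
    parts = pd.Series(hms).str.split(":", expand=True).astype(int)
    return (parts[0] * 3600 + parts[1] * 60 + parts[2]).to_numpy()


def write_transactions_csv(log: pd.DataFrame, path) -> None:
    out = log.copy()
    out["time"] = seconds_to_hms(out["time"]).to_numpy()
    out["amount"] = out["amount"].map("{:.2f}".format)
    out.to_csv(path, index=False)


def read_transactions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"student_id": str, "date": str, "item_id": str})
    df["time"] = hms_to_seconds(df["time"])
    return df


def write_survey_csv(survey: pd.DataFrame, path, include_group: bool = False) -> None:
    cols = SURVEY_COLUMNS + (["group"] if include_group and "group" in survey else [])
    survey[cols].to_csv(path, index=False)


def read_survey_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"student_id": str})


def config_to_yaml(config: SimulationConfig, path) -> None:
    payload = {
        "seed": config.seed,
        "n_per_group": dict(config.n_per_group),
        "n_cafeterias": config.n_cafeterias,
        "calendar": config.calendar.to_dict("records"),
        "presets": {g: asdict(p) for g, p in config.presets.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def config_from_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if "seed" not in payload:
        raise ValidationError("seed: mandatory in simulation config")
    presets = {}
    for g, p in payload["presets"].items():
        sp = SurveyParams(**p.pop("survey_score_params"))
        demo = Demographics(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in p.pop("demographics").items()})
        presets[g] = GroupPreset(survey_score_params=sp, demographics=demo, **p)
    cfg = SimulationConfig(
        n_per_group=payload["n_per_group"],
        calendar=pd.DataFrame(payload["calendar"]),
        seed=int(payload["seed"]),
        presets=presets,
        n_cafeterias=payload.get("n_cafeterias", N_CAFETERIAS),
    )
    cfg.validate()
    return cfg
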