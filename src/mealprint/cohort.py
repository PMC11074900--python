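"""Screening rules, group assignment, and the cohort summary table.

Groups are assigned from four self-report totals:

* mild depression: 5 <= PHQ-9 <= 9;
* moderate-severe depression: PHQ-9 >= 10;
* healthy control (HC): PHQ-9 < 5 and GAD-7 < 5 and PSS-14 < 29 and ISI < 8;
* excluded: PHQ-9 < 5 but at least one comorbidity instrument at or above
  its cap (anxiety, abnormal stress or insomnia without depressive
  symptoms).

The four labels partition any survey table.  The summary-table comorbidity
flags deliberately use the strict thresholds GAD-7 > 5, PSS-14 > 28 and
ISI > 8 as conventionally printed in cohort tables, which differ at the
boundary from the inclusion cut-offs; both are kept as-is rather than
harmonised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GROUP_LABELS = ("HC", "mild", "moderate_severe", "excluded")
_INSTRUMENTS = ("phq9", "gad7", "pss14", "isi")

#: summary-table comorbidity flags (strict >), distinct from inclusion cuts
FLAG_THRESHOLDS = {"gad7": 5, "pss14": 28, "isi": 8}


def assign_group(record) -> str:
    """Label one survey record; ``record`` is any mapping with the four totals.

    Raises ValueError naming the instrument if a score is missing.
    """
    scores = {}
    for k in _INSTRUMENTS:
        v = record.get(k) if hasattr(record, "get") else record[k]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing score: {k}")
        scores[k] = float(v)
    phq = scores["phq9"]
    if 5 <= phq <= 9:
        return "mild"
    if phq >= 10:
        return "moderate_severe"
    if scores["gad7"] < 5 and scores["pss14"] < 29 and scores["isi"] < 8:
        return "HC"
    return "excluded"


def assign_groups(survey: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`assign_group` over a survey table."""
    for k in _INSTRUMENTS:
        if survey[k].isna().any():
            raise ValueError(f"missing score: {k}")
    phq = survey["phq9"].to_numpy(float)
    hc_ok = (
        (survey["gad7"].to_numpy(float) < 5)
        & (survey["pss14"].to_numpy(float) < 29)
        & (survey["isi"].to_numpy(float) < 8)
    )
    labels = np.select(
        [(phq >= 5) & (phq <= 9), phq >= 10, hc_ok],
        ["mild", "moderate_severe", "HC"],
        default="excluded",
    )
    return pd.Series(labels, index=survey.index, name="group")


def percent(n_cell: int, n_group: int) -> float:
    """Cell percentage as printed in cohort tables (2 decimals); NaN if empty."""
    if n_group == 0:
        return float("nan")
    return round(100.0 * n_cell / n_group, 2)


def cohort_summary(survey: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Demographic/clinical summary per group (a Table-1 style frame).

    One column per group in (HC, mild, moderate_severe); rows are n, mean
    (SD) of age and each instrument, n (%) per demographic category, and
    n (%) above each comorbidity flag threshold.  Percentages are
    100*n_cell/n_group to 2 decimals; empty groups get blank cells.
    """
    df = survey.assign(group=labels.to_numpy())
    rows = {}
    groups = [g for g in ("HC", "mild", "moderate_severe")]

    def fmt_mean_sd(series):
        if len(series.dropna()) == 0:
            return ""
        return f"{series.mean():.2f} ({series.std(ddof=1):.2f})"

    def fmt_n_pct(n_cell, n_group):
        if n_group == 0:
            return ""
        return f"{n_cell} ({percent(n_cell, n_group):.2f})"

    for g in groups:
        sub = df[df["group"] == g]
        n = len(sub)
        col = {"n": str(n), "age_mean_sd": fmt_mean_sd(sub["age"])}
        for cat, values in (
            ("gender", ("male", "female")),
            ("bmi_class", ("lt18.5", "18.5-24", "gt24")),
            ("education", ("undergrad", "postgrad", "doctoral")),
        ):
            for v in values:
                col[f"{cat}_{v}"] = fmt_n_pct(int((sub[cat] == v).sum()), n)
        for inst in _INSTRUMENTS:
            col[f"{inst}_mean_sd"] = fmt_mean_sd(sub[inst])
        for inst, thr in FLAG_THRESHOLDS.items():
            col[f"{inst}_gt{thr}"] = fmt_n_pct(int((sub[inst] > thr).sum()), n)
        rows[g] = col
    return pd.DataFrame(rows)


def exclusion_count(n_recruited: int, labels: pd.Series | None = None,
                    n_included: int | None = None) -> dict:
    """Excluded-participant arithmetic and a partition consistency check.

    Either pass the assigned ``labels`` (excluded = count of 'excluded'
    labels) or ``n_included`` (excluded = recruited - included).
    """
    if labels is not None:
        counts = labels.value_counts()
        n_excluded = int(counts.get("excluded", 0))
        total = int(counts.sum())
        consistent = n_recruited == total
    else:
        if n_included is None:
            raise ValueError("pass labels or n_included")
        n_excluded = int(n_recruited - n_included)
        consistent = n_excluded >= 0
    return {"n_recruited": int(n_recruited), "n_excluded": n_excluded,
            "consistent": bool(consistent)}
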