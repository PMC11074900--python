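"""End-to-end orchestration: simulate -> screen -> segment -> featurize ->
analyze -> classify, with reproducible artifacts.

A run is fully determined by its :class:`RunConfig`: the config (including
the global seed) is serialised into the output directory together with a
manifest recording the config hash, per-stage row counts and every dropped
record, so any run can be re-created from its artifacts.  The global seed
fans out to per-stage seeds through a fixed ``SeedSequence`` derivation, so
stages are also independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .classify import ClassifierConfig, crossval_svm
from .cohort import assign_groups, cohort_summary, exclusion_count
from .features import DietaryFeatureExtractor, ZScoreBander, data_dictionary
from .meals import MealSegmenter, meals_to_csv
from .stats import ancova, fdr_adjust, logistic_association, mediate

STAGES = ("simulate", "screen", "segment", "featurize", "analyze", "classify")


class PipelineError(RuntimeError):
    """Raised when a stage cannot proceed; message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    # either a simulation config, or paths to existing input CSVs
    simulation: sim.SimulationConfig | None = None
    transactions_csv: str | None = None
    survey_csv: str | None = None
    calendar: pd.DataFrame | None = None
    # stage toggles (defaults = study conventions)
    drop_out_of_slot: bool = False
    pattern_denominator: str = "observed_days"
    mad_kind: str = "median"
    zscore_ddof: int = 1
    fdr_scope: str = "family"            # family | none
    ancova_typ: int = 2
    n_boot: int = 5000
    mediator: str = "gad7"
    mediation_outcome: str = "pattern.weekday.BLD"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def content_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "drop_out_of_slot": self.drop_out_of_slot,
            "pattern_denominator": self.pattern_denominator,
            "mad_kind": self.mad_kind, "zscore_ddof": self.zscore_ddof,
            "fdr_scope": self.fdr_scope, "ancova_typ": self.ancova_typ,
            "n_boot": self.n_boot, "mediator": self.mediator,
            "mediation_outcome": self.mediation_outcome,
            "classifier": vars(self.classifier),
            "simulation": None if self.simulation is None else {
                "seed": self.simulation.seed,
                "n_per_group": dict(self.simulation.n_per_group),
                "presets": json.loads(json.dumps(
                    sim.asdict_presets(self.simulation.presets), default=str)),
                "calendar": self.simulation.calendar.to_dict("records"),
            },
            "transactions_csv": self.transactions_csv,
            "survey_csv": self.survey_csv,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, children)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write artifacts under ``config.outdir``, and
    return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"seed": config.seed, "stage_seeds": seeds,
                "config_hash": config.content_hash(),
                "counts": {}, "dropped": {}, "timing_s": {}}

    # -- simulate / load ----------------------------------------------------
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim_cfg = config.simulation
        survey, log, ground_truth = sim.generate_cohort(sim_cfg)
        calendar = sim_cfg.calendar
        sim.write_survey_csv(survey, outdir / "survey.csv")
        sim.write_transactions_csv(log, outdir / "transactions.csv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1, default=str)
    else:
        if not config.transactions_csv or not config.survey_csv:
            raise PipelineError("simulate", "no simulation config and no input CSVs")
        log = sim.read_transactions_csv(config.transactions_csv)
        survey = sim.read_survey_csv(config.survey_csv)
        calendar = config.calendar
        if calendar is None:
            raise PipelineError("simulate", "a calendar is required with CSV inputs")
    manifest["counts"]["transactions"] = int(len(log))
    manifest["counts"]["survey_rows"] = int(len(survey))
    manifest["timing_s"]["simulate"] = round(time.perf_counter() - t0, 3)

    # -- screen -------------------------------------------------------------
    t0 = time.perf_counter()
    labels = assign_groups(survey)
    summary = cohort_summary(survey, labels)
    summary.to_csv(outdir / "cohort_summary.csv")
    (outdir / "cohort_summary.txt").write_text(summary.to_string())
    excl = exclusion_count(len(survey), labels=labels)
    manifest["counts"]["excluded_students"] = excl["n_excluded"]
    included = survey.loc[labels != "excluded"].copy()
    included["group"] = labels[labels != "excluded"].to_numpy()
    manifest["counts"]["included_students"] = int(len(included))
    manifest["timing_s"]["screen"] = round(time.perf_counter() - t0, 3)

    # -- segment ------------------------------------------------------------
    t0 = time.perf_counter()
    if len(log) == 0:
        raise PipelineError("segment", "transaction log is empty: nothing to segment")
    segmenter = MealSegmenter(drop_out_of_slot=config.drop_out_of_slot)
    meals = segmenter.fit_transform(log)
    meals = meals[meals["student_id"].isin(included["student_id"])]
    meals_to_csv(meals, outdir / "meals.csv")
    manifest["counts"]["meals"] = int(len(meals))
    manifest["dropped"]["meals_deduped_or_trimmed"] = int(len(segmenter.dropped_))
    manifest["timing_s"]["segment"] = round(time.perf_counter() - t0, 3)

    # -- featurize ----------------------------------------------------------
    t0 = time.perf_counter()
    extractor = DietaryFeatureExtractor(
        calendar=calendar, pattern_denominator=config.pattern_denominator,
        mad_kind=config.mad_kind)
    features = extractor.fit_transform(meals)
    with_meals = set(features.index)
    analysed = included[included["student_id"].isin(with_meals)].set_index("student_id")
    manifest["dropped"]["students_without_meals"] = int(len(included) - len(analysed))
    features = features.loc[analysed.index]
    features.to_csv(outdir / "features.csv")
    data_dictionary(features.columns).to_csv(outdir / "feature_dictionary.csv", index=False)
    manifest["counts"]["feature_rows"] = int(len(features))
    manifest["counts"]["feature_columns"] = int(features.shape[1])
    manifest["timing_s"]["featurize"] = round(time.perf_counter() - t0, 3)

    # -- analyze ------------------------------------------------------------
    t0 = time.perf_counter()
    covariates = analysed[["age", "gender", "bmi_class", "education"]]
    groups = analysed["group"]
    analysable = [c for c in features.columns if not c.startswith("meta.")]
    bander = ZScoreBander(ddof=config.zscore_ddof)
    z = bander.fit_transform(features[analysable])
    bands = bander.to_bands(z)
    manifest["dropped"]["zero_variance_features"] = bander.dropped_

    ancova_rows = []
    for col in z.columns:
        try:
            r = ancova(features[col], groups, covariates, feature=col,
                       typ=config.ancova_typ)
        except ValueError:
            continue
        row = {"feature": col, "family": col.split(".", 1)[0],
               "F": r.F, "df1": r.df[0], "df2": r.df[1], "p": r.p}
        for c in r.posthoc:
            tag = f"{c.pair[0]}_vs_{c.pair[1]}"
            row[f"p_{tag}"] = c.p
            row[f"padj_{tag}"] = c.p_adjusted
            row[f"diff_{tag}"] = c.estimate
        ancova_rows.append(row)
    ancova_df = pd.DataFrame(ancova_rows)
    if len(ancova_df) and config.fdr_scope == "family":
        ancova_df["p_fdr"] = np.nan
        for fam, idx in ancova_df.groupby("family").groups.items():
            ancova_df.loc[idx, "p_fdr"] = fdr_adjust(ancova_df.loc[idx, "p"])
    ancova_df.to_csv(outdir / "stats_ancova.csv", index=False)

    logistic_rows = []
    pattern_cols = [c for c in bands.columns if c.startswith("pattern.")]
    for col in pattern_cols:
        for target in ("mild", "moderate_severe"):
            try:
                results = logistic_association(bands[col], groups, target,
                                               covariates, predictor=col)
            except Exception:
                continue
            for r in results:
                logistic_rows.append(vars(r))
    logistic_df = pd.DataFrame(logistic_rows)
    logistic_df.to_csv(outdir / "stats_logistic.csv", index=False)

    mediation = None
    med_col = config.mediation_outcome
    if med_col in features.columns and features[med_col].notna().sum() >= 10:
        x = groups.map({"HC": 0, "mild": 1, "moderate_severe": 2}).astype(float)
        try:
            mediation = mediate(x.to_numpy(), analysed[config.mediator].to_numpy(float),
                                features[med_col].to_numpy(float),
                                covariates, n_boot=config.n_boot,
                                seed=seeds["analyze"])
        except ValueError:
            mediation = None
    stats_summary = {
        "n_ancova_features": int(len(ancova_df)),
        "n_logistic_models": int(len(logistic_df)),
        "mediation": None if mediation is None else vars(mediation),
    }
    with open(outdir / "stats_summary.json", "w") as fh:
        json.dump(stats_summary, fh, indent=1, default=float)
    manifest["timing_s"]["analyze"] = round(time.perf_counter() - t0, 3)

    # -- classify -----------------------------------------------------------
    t0 = time.perf_counter()
    cls_cfg = ClassifierConfig(**{**vars(config.classifier), "seed": seeds["classify"]})
    metrics = {}
    try:
        metrics["tri"] = crossval_svm(z, groups.to_numpy(), cls_cfg).as_dict()
    except ValueError as exc:
        metrics["tri"] = {"error": str(exc)}
    binary_mask = groups.isin(["HC", "moderate_severe"]).to_numpy()
    try:
        metrics["binary"] = crossval_svm(
            z.loc[binary_mask], groups.to_numpy()[binary_mask], cls_cfg).as_dict()
    except ValueError as exc:
        metrics["binary"] = {"error": str(exc)}
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, default=float)
    pd.DataFrame({k: v for k, v in metrics.items() if "error" not in v}).T.to_csv(
        outdir / "metrics.csv")
    manifest["timing_s"]["classify"] = round(time.perf_counter() - t0, 3)

    manifest["artifacts"] = sorted(p.name for p in outdir.iterdir())
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
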