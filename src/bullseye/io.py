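"""File I/O, run configuration and the end-to-end pipeline.

The on-disk format is two UTF-8, comma-delimited CSVs with headers:

* patient table — ``patient_id, capp_mmHg, ffr, nhpr`` (empty = not
  measured), any covariate columns by name (e.g. ``hba1c``,
  ``esc_risk_score``), optionally ``truth``;
* segment table (long format) — ``patient_id, segment_id, gls``, one row
  per segment, 18 per patient.

``run_pipeline`` ties the stages together: simulate or read a cohort,
derive strain summaries and pattern flags, label truth from physiology,
evaluate the pattern against truth, screen covariates, fit the multivariate
model and compare model AUCs.  Output is a plain dict (JSON-serializable)
that embeds the config snapshot and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .diagnostics import (FFR_THRESHOLD, NHPR_THRESHOLD, confusion_table,
                          diagnostic_metrics, roc_auc)
from .model import ScreenConfig, compare_models, fit_multivariate, univariate_screen
from .pattern import TERRITORIES, PatternConfig, detect_pattern_batch
from .simulate import SEGMENT_COLUMNS, CohortConfig, generate_cohort
from .strain import N_SEGMENTS

logger = logging.getLogger("bullseye")

__all__ = ["RunConfig", "read_patient_table", "write_cohort", "derive",
           "run_pipeline", "save_report"]

#: covariates screened by default when present in the table
DEFAULT_CANDIDATES = ("hba1c", "capp_mmHg", "prior_stroke", "prior_cad",
                      "e_over_e_prime", "avg_gls", "gls_lcx", "pattern")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on besides the input files."""

    pattern: PatternConfig = field(default_factory=PatternConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ffr_threshold: float = FFR_THRESHOLD
    nhpr_threshold: float = NHPR_THRESHOLD
    convention: str = "signed"
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name, v in (("ffr_threshold", self.ffr_threshold),
                        ("nhpr_threshold", self.nhpr_threshold)):
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.convention not in ("signed", "magnitude"):
            raise ValueError(f"unknown convention {self.convention!r}")

    def snapshot(self) -> Dict:
        return dataclasses.asdict(self)


def read_patient_table(
    patients_path: str | Path,
    segments_path: str | Path,
    convention: str = "signed",
) -> pd.DataFrame:
    """Read and validate the two CSVs into one wide cohort table.

    Magnitude-convention strain input is normalized to signed on read.
    Validation problems are collected and raised together, each naming the
    offending patient/segment (and CSV line for row-level issues).
    """
    patients = pd.read_csv(patients_path)
    segments = pd.read_csv(segments_path)
    errors: List[str] = []

    for col in ("patient_id", "capp_mmHg"):
        if col not in patients.columns:
            errors.append(f"{patients_path}: missing required column {col!r}")
    if not {"ffr", "nhpr"} & set(patients.columns):
        errors.append(f"{patients_path}: need at least one of columns 'ffr'/'nhpr'")
    for col in ("patient_id", "segment_id", "gls"):
        if col not in segments.columns:
            errors.append(f"{segments_path}: missing required column {col!r}")
    if errors:
        raise ValueError("invalid input:\n" + "\n".join(errors))

    dup = patients["patient_id"].duplicated()
    for i in np.nonzero(dup.to_numpy())[0]:
        errors.append(f"{patients_path} line {i + 2}: duplicate patient_id "
                      f"{patients['patient_id'].iloc[i]!r}")

    dup = segments.duplicated(subset=["patient_id", "segment_id"])
    for i in np.nonzero(dup.to_numpy())[0]:
        errors.append(f"{segments_path} line {i + 2}: duplicate (patient_id, segment_id) "
                      f"({segments['patient_id'].iloc[i]!r}, {segments['segment_id'].iloc[i]!r})")

    bad = ~segments["segment_id"].between(1, N_SEGMENTS)
    for i in np.nonzero(bad.to_numpy())[0]:
        errors.append(f"{segments_path} line {i + 2}: segment_id out of range 1..18 "
                      f"({segments['segment_id'].iloc[i]!r})")

    bad = segments["gls"].abs() >= 100
    for i in np.nonzero(bad.to_numpy())[0]:
        errors.append(f"{segments_path} line {i + 2}: |gls| must be < 100 "
                      f"({segments['gls'].iloc[i]!r})")
    if errors:
        raise ValueError("invalid input:\n" + "\n".join(errors))

    wide = segments.pivot(index="patient_id", columns="segment_id", values="gls")
    all_ids = set(range(1, N_SEGMENTS + 1))
    present = segments.groupby("patient_id")["segment_id"].apply(set)
    for pid, ids in present.items():
        missing = sorted(all_ids - {int(i) for i in ids})
        if missing:
            errors.append(f"patient {pid!r}: missing segment ids {missing}")
    unmatched = set(patients["patient_id"]) - set(wide.index)
    for pid in sorted(unmatched):
        errors.append(f"patient {pid!r}: no segment rows")
    orphan = set(wide.index) - set(patients["patient_id"])
    for pid in sorted(orphan):
        errors.append(f"segment rows for unknown patient {pid!r}")
    if errors:
        raise ValueError("invalid input:\n" + "\n".join(errors))

    wide = wide.reindex(columns=range(1, N_SEGMENTS + 1))
    if convention == "magnitude":
        if (wide.to_numpy() < 0).any():
            raise ValueError("magnitude-convention segment table contains negative values")
        wide = -wide
    wide.columns = SEGMENT_COLUMNS
    frame = patients.merge(wide.reset_index(), on="patient_id", validate="one_to_one")

    capp_bad = ~(frame["capp_mmHg"] > 0)
    if capp_bad.any():
        pid = frame.loc[capp_bad, "patient_id"].iloc[0]
        raise ValueError(f"patient {pid!r}: capp_mmHg must be > 0")
    return frame


def write_cohort(frame: pd.DataFrame, patients_path: str | Path,
                 segments_path: str | Path) -> None:
    """Write a wide cohort table as the patient + long-format segment CSVs."""
    seg_cols = [c for c in SEGMENT_COLUMNS if c in frame.columns]
    if len(seg_cols) != N_SEGMENTS:
        raise ValueError("cohort table lacks the 18 seg_* columns")
    patients = frame.drop(columns=seg_cols)
    patients.to_csv(patients_path, index=False)
    long = frame[["patient_id", *seg_cols]].melt(
        id_vars="patient_id", var_name="segment_id", value_name="gls")
    long["segment_id"] = long["segment_id"].str.removeprefix("seg_").astype(int)
    long = long.sort_values(["patient_id", "segment_id"], kind="stable")
    long.to_csv(segments_path, index=False)


def derive(frame: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Add derived columns: strain summaries, pattern flags, physiology label.

    Adds avg_gls, gls_lad/gls_lcx/gls_rca, pattern_lad/lcx/rca, pattern
    (overall, 0/1) and phys_label (0/1) when FFR/NHPR columns are present.
    """
    config = config or RunConfig()
    frame = frame.copy()
    values = frame[SEGMENT_COLUMNS].to_numpy(dtype=float)

    n_missing = np.isnan(values).sum(axis=1)
    if (n_missing > config.pattern.allow_missing).any():
        bad = frame.loc[n_missing > config.pattern.allow_missing, "patient_id"].iloc[0]
        raise ValueError(f"patient {bad!r}: missing segments exceed allowance "
                         f"({config.pattern.allow_missing})")

    with np.errstate(invalid="ignore"):
        frame["avg_gls"] = np.nanmean(values, axis=1)
        for vessel, segs in TERRITORIES.items():
            frame[f"gls_{vessel.lower()}"] = np.nanmean(
                values[:, [s - 1 for s in segs]], axis=1)
    flags = detect_pattern_batch(values, config.pattern)
    for vessel in TERRITORIES:
        frame[f"pattern_{vessel.lower()}"] = flags[vessel].astype(int)
    frame["pattern"] = flags["overall"].astype(int)

    if {"ffr", "nhpr"} & set(frame.columns):
        ffr = frame["ffr"] if "ffr" in frame.columns else pd.Series(np.nan, index=frame.index)
        nhpr = frame["nhpr"] if "nhpr" in frame.columns else pd.Series(np.nan, index=frame.index)
        if (ffr.isna() & nhpr.isna()).any():
            pid = frame.loc[ffr.isna() & nhpr.isna(), "patient_id"].iloc[0]
            raise ValueError(f"patient {pid!r}: neither ffr nor nhpr measured")
        frame["phys_label"] = (
            (ffr <= config.ffr_threshold).fillna(False)
            | (nhpr <= config.nhpr_threshold).fillna(False)
        ).astype(int)
    return frame


def _evaluate(frame: pd.DataFrame, config: RunConfig) -> Dict:
    truth = frame["phys_label"].astype(bool).to_numpy()
    pred = frame["pattern"].astype(bool).to_numpy()
    table = confusion_table(pred, truth)
    summary = diagnostic_metrics(table)
    report: Dict = {
        "n": int(table.n),
        "prevalence": float(truth.mean()),
        "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "metrics": summary.to_dict(),
    }
    notes = []
    if table.n_pos == 0:
        notes.append("no physiology-positive patients: sensitivity/NPV/DOR undefined")
    if table.n_neg == 0:
        notes.append("no physiology-negative patients: specificity/PPV/DOR undefined")
    if notes:
        report["notes"] = notes
    if table.n_pos > 0 and table.n_neg > 0:
        report["auc"] = {
            # risk direction: less negative (higher) strain = more impaired
            "avg_gls": roc_auc(frame["avg_gls"], truth),
            "pattern": roc_auc(frame["pattern"], truth),
        }
        for vessel in TERRITORIES:
            report["auc"][f"gls_{vessel.lower()}"] = roc_auc(
                frame[f"gls_{vessel.lower()}"], truth)
    return report


def _screen_and_model(frame: pd.DataFrame, config: RunConfig) -> Dict:
    truth = frame["phys_label"].astype(int)
    if truth.nunique() < 2 or min((truth == 0).sum(), (truth == 1).sum()) < 2:
        return {"skipped": "need at least 2 patients in each physiology class"}
    data = frame.copy()
    data["truth"] = truth
    candidates = list(config.screen.covariates) or [
        c for c in DEFAULT_CANDIDATES if c in data.columns]
    screened = univariate_screen(
        data, ScreenConfig(p_threshold=config.screen.p_threshold,
                           covariates=candidates,
                           p_source=config.screen.p_source))
    selected = [s.name for s in screened if s.selected]

    report: Dict = {
        "screening": [dataclasses.asdict(s) for s in screened],
        "selected": selected,
    }
    specs = {"combined (pattern + CAPP)": ["pattern", "capp_mmHg"],
             "average GLS alone": ["avg_gls"]}
    if "esc_risk_score" in data.columns:
        specs["ESC clinical likelihood"] = ["esc_risk_score"]
    if selected:
        usable = [s for s in selected
                  if not any(x.flag for x in screened if x.name == s)]
        if len(usable) >= 1:
            fitted = fit_multivariate(data, usable)
            report["multivariate"] = fitted.to_dict()
    report["model_comparison"] = compare_models(data, specs).reset_index().to_dict("records")
    return report


def run_pipeline(
    config: RunConfig | None = None,
    patients_path: str | Path | None = None,
    segments_path: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> Dict:
    """Run the full analysis and return (and optionally write) the reports.

    Without input paths a synthetic cohort is generated from
    ``config.cohort`` (seeded by ``config.seed`` when given).  Stages:
    classify → evaluate → screen → fit → compare.  Deterministic given the
    inputs, config and seed.
    """
    config = config or RunConfig()
    logging.basicConfig(level=config.log_level)
    try:
        if patients_path is not None:
            logger.info("reading cohort from %s / %s", patients_path, segments_path)
            frame = read_patient_table(patients_path, segments_path,
                                       convention=config.convention)
        else:
            logger.info("simulating cohort (n=%d)", config.cohort.n_patients)
            frame = generate_cohort(config.cohort, seed=config.seed)
    except Exception as err:
        raise RuntimeError(f"[input stage] {err}") from err

    try:
        frame = derive(frame, config)
    except Exception as err:
        raise RuntimeError(f"[classification stage] {err}") from err
    try:
        evaluation = _evaluate(frame, config)
    except Exception as err:
        raise RuntimeError(f"[evaluation stage] {err}") from err
    try:
        modeling = _screen_and_model(frame, config)
    except Exception as err:
        raise RuntimeError(f"[modeling stage] {err}") from err

    report = {
        "config": config.snapshot(),
        "seed": config.seed,
        "n_patients": int(len(frame)),
        "evaluation": evaluation,
        "modeling": modeling,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_report(evaluation, out / "evaluation.json")
        save_report(modeling, out / "model.json")
        save_report(report, out / "report.json")
        (out / "summary.md").write_text(render_summary(report), encoding="utf-8")
        logger.info("reports written to %s", out)
    return report


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def save_report(report: Dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, cls=_Encoder) + "\n",
                          encoding="utf-8")


def _fmt_est(e: Optional[Dict], pct: bool) -> str:
    if e is None:
        return "undefined"
    k = 100 if pct else 1
    unit = " %" if pct else ""
    return (f"{k * e['point']:.1f}{unit} "
            f"(95 % CI {k * e['lower']:.1f}–{k * e['upper']:.1f})")


def render_summary(report: Dict) -> str:
    """Human-readable markdown summary of a pipeline report."""
    ev = report["evaluation"]
    lines = [
        "# Ischemic bull's-eye pattern — diagnostic report",
        "",
        f"Patients: {report['n_patients']}; "
        f"physiology-positive prevalence {100 * ev['prevalence']:.1f} %.",
        "",
        "## Pattern vs invasive physiology",
        "",
        f"- confusion table (tp, fp, fn, tn): "
        f"{tuple(ev['confusion'][k] for k in ('tp', 'fp', 'fn', 'tn'))}",
    ]
    m = ev["metrics"]
    for name, pct in (("sensitivity", True), ("specificity", True),
                      ("ppv", True), ("npv", True), ("dor", False)):
        lines.append(f"- {name}: {_fmt_est(m[name], pct)}")
    if "auc" in ev:
        lines += ["", "## In-sample AUCs", ""]
        lines += [f"- {k}: {v:.3f}" for k, v in ev["auc"].items()]
    md = report["modeling"]
    if "selected" in md:
        lines += ["", "## Modeling", "",
                  f"- screened in (p < threshold): {', '.join(md['selected']) or 'none'}"]
        if "multivariate" in md:
            lines.append("- adjusted odds ratios:")
            for name, row in md["multivariate"]["odds_ratios"].items():
                lines.append(f"    - {name}: OR {row['or']:.2f} "
                             f"(95 % CI {row['ci_lower']:.2f}–{row['ci_upper']:.2f}, "
                             f"p={row['p']:.3g})")
        if "model_comparison" in md:
            lines.append("- model AUCs:")
            for row in md["model_comparison"]:
                lines.append(f"    - {row['model']}: {row['auc']:.3f}")
    elif "skipped" in md:
        lines += ["", f"Modeling skipped: {md['skipped']}"]
    return "\n".join(lines) + "\n"
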