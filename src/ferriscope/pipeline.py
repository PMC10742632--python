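"""End-to-end orchestration: images -> metrics -> classification -> statistics.

`run_image_pipeline` walks a set of patient image studies (multi-echo
stacks with ROI masks or myocardial contours), runs the relaxometry and
mapping chain on each, and collects one metrics row per patient.  Failures
are logged per patient and the run continues; a failure manifest is
attached to the result.  `run_cohort_analysis` takes a cohort table and an
analysis plan and emits the full statistical report (descriptives,
three-group comparisons with Bonferroni pairs, odds-ratio panel,
univariate + stepwise multivariate regression, ROC/Youden), as a plain
dict that serializes to JSON byte-identically for a fixed input, plus a
markdown rendering whose every number is taken from that dict.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ferriscope import io as fio
from ferriscope.cardiac_mapping import build_heart_map, segment_masks
from ferriscope.classification import Thresholds, classify_cohort
from ferriscope.cohort_stats import (
    ContingencyTable2x2,
    compare_groups,
    odds_ratio_2x2,
    roc_youden,
    stepwise_t2star_model,
)
from ferriscope.relaxometry import (
    lic_from_liver_t2star,
    pancreas_global,
    roi_mean_decay,
    select_fit,
)

__all__ = ["RunConfig", "AnalysisPlan", "run_image_pipeline", "run_cohort_analysis",
           "measure_patient", "report_to_markdown"]

log = logging.getLogger("ferriscope")


@dataclass(frozen=True)
class AnalysisPlan:
    """Which statistics to run on a cohort table."""

    group_var: str = "vitd_category"
    group_order: tuple[str, ...] = ("sufficient", "insufficient", "deficient")
    compare_vars: tuple[str, ...] = (
        "age", "bmi", "hb", "ferritin", "alt", "ast", "ggt", "lic",
        "pancreas_t2star", "heart_t2star", "n_low_segments",
        "edvi", "mass_index", "lv_ef", "rv_edvi", "rv_ef",
    )
    regression_outcome: str = "heart_t2star"
    regression_candidates: tuple[str, ...] = (
        "sex_f", "age", "hb", "ferritin", "vitamin_d", "pth", "lic",
        "pancreas_t2star",
    )
    roc_predictor: str = "vitamin_d"
    roc_outcome: str = "myocardial_overload"
    roc_direction: str = "low"


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for a measurement + analysis run."""

    patients: tuple[dict, ...] = ()          # per-patient file manifest dicts
    cohort_csv: str | None = None
    output_dir: str = "."
    thresholds: Thresholds = field(default_factory=Thresholds)
    lic_calibration: dict | None = None
    plan: AnalysisPlan = field(default_factory=AnalysisPlan)
    seed: int = 0


# ---------------------------------------------------------------------------
# image pipeline


def measure_patient(liver=None, pancreas=None, cardiac=None,
                    thresholds: Thresholds = Thresholds(),
                    lic_calibration: dict | None = None) -> dict:
    """Run the measurement chain on one patient's in-memory image studies.

    ``liver``: (stack, mask, echo_times, noise_sd);
    ``pancreas``: (stack, [head, body, tail masks], echo_times, noise_sd);
    ``cardiac``: list of (stack, MyocardialContours, echo_times, noise_sd)
    for the basal, mid and apical slices.  Returns a flat metrics dict;
    missing studies simply leave their metrics out.
    """
    row: dict = {}
    if liver is not None:
        stack, mask, te, sd = liver
        fit = select_fit(roi_mean_decay(stack, mask, te, sd))
        iron = lic_from_liver_t2star(fit.t2star, lic_calibration)
        row.update(liver_t2star=fit.t2star, lic=iron.lic,
                   lic_calibration=iron.calibration_id, liver_model=fit.model)
    if pancreas is not None:
        stack, masks, te, sd = pancreas
        fits = [select_fit(roi_mean_decay(stack, m, te, sd)) for m in masks]
        panc = pancreas_global(*fits)
        row.update(pancreas_head=panc.head, pancreas_body=panc.body,
                   pancreas_tail=panc.tail, pancreas_t2star=panc.global_value)
    if cardiac is not None:
        series = []
        for stack, contours, te, sd in cardiac:
            for m in segment_masks(contours, stack.shape[1:]):
                series.append(roi_mean_decay(stack, m, te, sd))
        heart = build_heart_map(series)
        row.update(heart_t2star=heart.global_value,
                   n_low_segments=heart.n_low_segments,
                   segment_t2star=[float(v) for v in heart.segment_values],
                   segment_models=[f.model for f in heart.fits],
                   segment_echoes_used=[f.n_echoes_used for f in heart.fits])
    return row


def _load_patient_inputs(manifest: dict) -> dict:
    """Resolve a per-patient file manifest into in-memory study tuples."""
    out: dict = {}
    if "liver_stack" in manifest:
        stack, te, sd = fio.load_stack(manifest["liver_stack"])
        out["liver"] = (stack, fio.load_mask(manifest["liver_mask"]), te, sd)
    if "pancreas_stack" in manifest:
        stack, te, sd = fio.load_stack(manifest["pancreas_stack"])
        masks = [fio.load_mask(p) for p in manifest["pancreas_masks"]]
        out["pancreas"] = (stack, masks, te, sd)
    if "cardiac_stacks" in manifest:
        contours = fio.load_contours(manifest["cardiac_contours"])
        slices = []
        for level, path in manifest["cardiac_stacks"].items():
            stack, te, sd = fio.load_stack(path)
            slices.append((stack, contours[level], te, sd))
        out["cardiac"] = slices
    return out


def run_image_pipeline(config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Measure every patient in the config; continue past per-patient errors.

    Returns (metrics table, failure manifest).  Each failure records the
    patient id and the error message; successful rows carry the fitted
    model and echoes-retained diagnostics per segment.
    """
    rows, failures = [], []
    for manifest in config.patients:
        pid = manifest.get("patient_id", "?")
        try:
            studies = _load_patient_inputs(manifest)
            row = measure_patient(thresholds=config.thresholds,
                                  lic_calibration=config.lic_calibration, **studies)
            row["patient_id"] = pid
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - batch realism: log and continue
            log.warning("patient %s failed: %s", pid, exc)
            failures.append({"patient_id": pid, "error": str(exc)})
    if not rows:
        log.warning("image pipeline produced an empty table (%d failures)", len(failures))
        return pd.DataFrame(), failures
    table = pd.DataFrame(rows)
    cols = ["patient_id"] + [c for c in table.columns if c != "patient_id"]
    return table[cols], failures


# ---------------------------------------------------------------------------
# cohort analysis


def _descriptives(df: pd.DataFrame, variables: Sequence[str]) -> dict:
    out = {}
    for v in variables:
        if v in df.columns:
            x = pd.to_numeric(df[v], errors="coerce").dropna()
            out[v] = {"mean": float(x.mean()), "sd": float(x.std(ddof=1)),
                      "n": int(x.size)}
    return out


def _or_panel(df: pd.DataFrame) -> dict:
    """Odds-ratio panel mirroring the study's risk comparisons."""
    panel = {}

    def mio_table(exposed: str, reference: str) -> ContingencyTable2x2:
        e = df[df["vitd_category"] == exposed]["myocardial_overload"]
        r = df[df["vitd_category"] == reference]["myocardial_overload"]
        return ContingencyTable2x2(int(e.sum()), int((~e).sum()),
                                   int(r.sum()), int((~r).sum()))

    for name, exp_, ref in (("mio_deficient_vs_insufficient", "deficient", "insufficient"),
                            ("mio_deficient_vs_sufficient", "deficient", "sufficient")):
        try:
            t = mio_table(exp_, ref)
            panel[name] = {"table": [t.a, t.b, t.c, t.d],
                           **odds_ratio_2x2(t).to_dict()}
        except ValueError as exc:
            panel[name] = {"error": str(exc)}
    # hepatic overload as a risk factor for inadequate (<30 ng/mL) vitamin D
    inadequate = df["vitd_category"].isin(["deficient", "insufficient"])
    t = ContingencyTable2x2(
        int((df["hepatic_overload"] & inadequate).sum()),
        int((~df["hepatic_overload"] & inadequate).sum()),
        int((df["hepatic_overload"] & ~inadequate).sum()),
        int((~df["hepatic_overload"] & ~inadequate).sum()),
    )
    panel["inadequate_vitd_given_hepatic_overload"] = {
        "table": [t.a, t.b, t.c, t.d], **odds_ratio_2x2(t).to_dict()}
    return panel


def run_cohort_analysis(cohort: pd.DataFrame,
                        plan: AnalysisPlan = AnalysisPlan(),
                        thresholds: Thresholds = Thresholds()) -> dict:
    """Full statistical report for a cohort table.

    The cohort is classified first (categories + overload flags appended),
    then: per-variable descriptives, three-group comparisons with
    Bonferroni post-hoc pairs, the odds-ratio panel, the univariate +
    stepwise multivariate regression for the configured outcome, and the
    ROC/Youden panel.  Pure function of its inputs.
    """
    df = classify_cohort(cohort, thresholds)
    if "sex_f" not in df.columns and "sex" in df.columns:
        df["sex_f"] = (df["sex"] == "F").astype(float)

    groups = df[plan.group_var]
    if groups.nunique() < 2:
        raise ValueError(f"grouping variable {plan.group_var!r} is constant")

    comparisons = {}
    for v in plan.compare_vars:
        if v not in df.columns:
            raise ValueError(f"plan variable {v!r} missing from cohort")
        c = compare_groups(df[v].to_numpy(float), groups.to_numpy())
        comparisons[v] = {
            "test": c.test, "statistic": c.statistic, "p_value": c.p_value,
            "pairwise_bonferroni": {f"{a}|{b}": p for (a, b), p
                                    in sorted(c.pairwise_bonferroni.items())},
            "group_means": {g: float(df.loc[groups == g, v].mean())
                            for g in plan.group_order},
            "group_sds": {g: float(df.loc[groups == g, v].std(ddof=1))
                          for g in plan.group_order},
        }

    missing = [v for v in plan.regression_candidates if v not in df.columns]
    if missing:
        raise ValueError(f"plan variables missing from cohort: {missing}")
    regression = stepwise_t2star_model(df, plan.regression_outcome,
                                       plan.regression_candidates)
    roc = roc_youden(df[plan.roc_predictor].to_numpy(float),
                     df[plan.roc_outcome].to_numpy(), direction=plan.roc_direction)

    return {
        "n": int(len(df)),
        "group_sizes": {g: int((groups == g).sum()) for g in plan.group_order},
        "descriptives": _descriptives(df, plan.compare_vars + ("vitamin_d", "pth")),
        "group_comparisons": comparisons,
        "odds_ratios": _or_panel(df),
        "regression": regression.to_dict(),
        "roc": roc.to_dict(),
    }


def report_to_markdown(report: dict) -> str:
    """Render the JSON report as markdown tables (no new numbers)."""
    lines = [f"# Cohort analysis report (n = {report['n']})", ""]
    gs = report["group_sizes"]
    lines += ["## Groups", "", "| group | n |", "|---|---|"]
    lines += [f"| {g} | {n} |" for g, n in gs.items()]

    lines += ["", "## Three-group comparisons", "",
              "| variable | " + " | ".join(gs) + " | test | p |", "|" + "---|" * (len(gs) + 3)]
    for v, c in report["group_comparisons"].items():
        cells = [f"{c['group_means'][g]:.2f} ± {c['group_sds'][g]:.2f}" for g in gs]
        lines.append(f"| {v} | " + " | ".join(cells) + f" | {c['test']} | {c['p_value']:.4g} |")

    lines += ["", "## Odds ratios", "", "| comparison | OR | 95% CI | p |", "|---|---|---|---|"]
    for name, r in report["odds_ratios"].items():
        if "error" in r:
            lines.append(f"| {name} | — | — | {r['error']} |")
        else:
            lines.append(f"| {name} | {r['or_value']:.2f} | "
                         f"({r['ci_low']:.2f}, {r['ci_high']:.2f}) | {r['p_value']:.4g} |")

    reg = report["regression"]
    lines += ["", "## Heart-T2* regression", "",
              "| candidate | univariate β | p | multivariate β | p |", "|---|---|---|---|---|"]
    for v, u in reg["univariate"].items():
        m = reg["multivariate"].get(v)
        mb = f"{m['beta']:.3f}" if m else ""
        mp = f"{m['p_value']:.4g}" if m else ""
        lines.append(f"| {v} | {u['beta']:.3f} | {u['p_value']:.4g} | {mb} | {mp} |")
    lines.append(f"\nRetained: {', '.join(reg['retained']) or 'none'}; "
                 f"model F = {reg['model_f']:.2f}, p = {reg['model_p']:.4g}")

    roc = report["roc"]
    lines += ["", "## ROC / Youden", "",
              f"AUC {roc['auc']:.3f} (95% CI {roc['auc_ci_low']:.3f}–{roc['auc_ci_high']:.3f}); "
              f"optimal cutoff {roc['optimal_cutoff']:.2f} "
              f"(sensitivity {roc['sensitivity']:.1f}%, specificity {roc['specificity']:.1f}%)."]
    return "\n".join(lines) + "\n"


def save_report(report: dict, out_dir: str | Path, stem: str = "report") -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / f"{stem}.json"
    mpath = out / f"{stem}.md"
    jpath.write_text(json.dumps(report, indent=1, sort_keys=True))
    mpath.write_text(report_to_markdown(report))
    return jpath, mpath
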