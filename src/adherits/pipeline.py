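"""End-to-end orchestration: simulate/load -> score -> aggregate -> fit -> report.

Every number in the rendered reports is recomputable from the intermediate
CSVs written alongside them; the run log captures exclusion counts,
stability flags and convergence warnings.  Runs are reproducible: the same
config and seed produce byte-identical output bundles (no timestamps in any
artifact).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io
from .adherence import score_cohort
from .config import MED_CLASSES, RunConfig
from .errors import ValidationError
from .its import SegmentedFit, build_design, reml_fit_ar1, summarize_fit, trajectories
from .months import month_start_day
from .series import StabilityReport, aggregate_monthly, stability_check
from .simulate import TruthRecord, simulate_cohort, write_fixture

_CLASS_SHORT = {
    "statin": "Statins",
    "beta_blocker": "Beta blockers",
    "angiotensin_system_inhibitor": "Angiotensin system inhibitors",
    "secondary_antiplatelet": "Secondary antiplatelets",
}

_ROW_LABELS = {
    "intercept_baseline_pct": "Intercept (baseline percentage)",
    "pre_slope_pct_per_month": "Pre-intervention slope (secular trend, per month)",
    "level_change_pct": "Change in level post-intervention (immediate effect)",
    "trend_change_pct_per_month": "Change in trend post-intervention (gradual effect, per month)",
}


@dataclass
class PipelineResult:
    """Everything a run produced, with the paths it was written to."""

    config: RunConfig
    patients: pd.DataFrame
    dispensations: pd.DataFrame
    truth: TruthRecord | None
    results: pd.DataFrame
    exclusions: pd.DataFrame
    n_orphans: int
    series: pd.DataFrame
    stability: StabilityReport
    fits: dict[str, SegmentedFit]
    effects: dict[str, list]
    process_eval: pd.DataFrame
    paths: dict[str, str]


def fit_group_series(series: pd.DataFrame, group: str, t0: int) -> SegmentedFit:
    """Convenience: build the design for one group and fit it."""
    sub = series[series["group"] == group].sort_values("t")
    return reml_fit_ar1(build_design(sub, t0))


def process_eval_report(results: pd.DataFrame, patients: pd.DataFrame,
                        split_day: int) -> pd.DataFrame:
    """Prolonged-dispensation proportions at index fill by group and period.

    For each group and pre/post period (split on discharge day), reports the
    average-across-classes row (denominator: all retained patients) and one
    row per medication class (denominator: retained patients with that class
    at index fill), each as numerator, denominator, percent and a formatted
    ``n/N (pct%)`` cell.
    """
    merged = results.merge(patients[["patient_id", "group", "discharge_day"]],
                           on="patient_id", how="left")
    merged["period"] = np.where(merged["discharge_day"] < split_day, "pre", "post")
    rows = []
    for (group, period), sub in merged.groupby(["group", "period"]):
        specs = [("average_across_classes", sub["prolonged_avg"].astype(bool))]
        for c in MED_CLASSES:
            flag = sub[f"prolonged_{c}"]
            specs.append((c, flag.dropna().astype(bool)))
        for name, flag in specs:
            n, N = int(flag.sum()), int(flag.count())
            pct = 100.0 * n / N if N else float("nan")
            rows.append({
                "group": group, "period": period, "outcome": name,
                "numerator": n, "denominator": N, "proportion_pct": pct,
                "display": f"{n}/{N} ({pct:.1f}%)" if N else "0/0 (-)",
            })
    order = {"pre": 0, "post": 1}
    out = pd.DataFrame(rows)
    out = out.sort_values(["group", "outcome", "period"],
                          key=lambda s: s.map(order) if s.name == "period" else s)
    return out.reset_index(drop=True)


def render_effects_table(effects_by_group: dict[str, list], outcome: str,
                         horizon: int) -> str:
    """Publication-style text table: one block per group, five rows each."""
    lines = [f"Segmented regression estimates, outcome = {outcome} "
             f"(percent; 95% CI; overall effect at {horizon} months)", ""]
    for group, effects in effects_by_group.items():
        lines.append(f"{group}")
        for e in effects:
            label = _ROW_LABELS.get(
                e.name, f"Overall effect at {e.horizon} months post-intervention")
            lines.append(
                f"  {label}: {e.estimate:.2f} ({e.ci_low:.2f} to {e.ci_high:.2f}), "
                f"P = {e.p_value:.3f}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full pipeline and write the result bundle under ``config.outdir``.

    Outputs: ``patients.csv`` / ``dispensations.csv`` (if simulated),
    ``adherence_results.csv``, ``exclusions.csv``, ``monthly_series.csv``,
    ``fit_results.json``, ``trajectories.csv``, ``report_effects.csv``,
    ``report_effects.txt``, ``process_eval.csv``, ``log.txt``.
    """
    outdir = _io.ensure_outdir(config.outdir)
    paths: dict[str, str] = {}
    log: list[str] = [f"outcome: {config.outcome}", f"t0: {config.t0}",
                      f"horizon: {config.horizon}", f"seed: {config.seed}"]

    truth = None
    if config.sim is not None:
        sim = config.sim.with_seed(config.seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            patients, dispensations, truth = simulate_cohort(sim)
        for w in caught:
            log.append(f"simulate warning: {w.message}")
        paths.update(write_fixture(patients, dispensations, outdir))
        n_months = sim.n_months
        log.append(f"simulated {len(patients)} patients, "
                   f"{len(dispensations)} dispensations "
                   f"({truth.n_no_index_fill} without an index-window fill)")
    else:
        patients = _io.read_patients(config.patients_path)
        dispensations = _io.read_dispensations(config.dispensations_path)
        from .months import month_of_day
        n_months = int(patients["discharge_day"].map(month_of_day).max())
        log.append(f"loaded {len(patients)} patients, {len(dispensations)} dispensations")

    results, exclusions, n_orphans = score_cohort(patients, dispensations,
                                                  config.thresholds)
    log.append(f"scored {len(results)} patients; excluded {len(exclusions)} "
               f"(no index fill); ignored {n_orphans} orphan dispensation(s)")
    paths["adherence_results"] = os.path.join(outdir, "adherence_results.csv")
    results.to_csv(paths["adherence_results"], index=False)
    paths["exclusions"] = os.path.join(outdir, "exclusions.csv")
    exclusions.to_csv(paths["exclusions"], index=False)

    series = aggregate_monthly(results, patients, config.outcome, n_months)
    paths["monthly_series"] = os.path.join(outdir, "monthly_series.csv")
    _io.write_series(series, config.t0, paths["monthly_series"])

    stability = stability_check(series, floor=config.denominator_floor)
    log.append(stability.describe())

    fits: dict[str, SegmentedFit] = {}
    effects: dict[str, list] = {}
    fit_dicts: dict[str, dict] = {}
    traj_frames = []
    for group in sorted(series["group"].unique()):
        if group in stability.flagged_groups and not config.force_fit:
            log.append(f"fit skipped for {group}: unstable series")
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = fit_group_series(series, group, config.t0)
        for w in caught:
            log.append(f"fit warning ({group}): {w.message}")
        fits[group] = fit
        effects[group] = summarize_fit(fit, horizon=config.horizon,
                                       df_method=config.df_method)
        fit_dicts[group] = _io.fit_to_dict(fit, effects[group])
        traj = trajectories(fit)
        traj.insert(0, "group", group)
        traj_frames.append(traj)

    paths["fit_results"] = os.path.join(outdir, "fit_results.json")
    _io.write_fit_results(fit_dicts, paths["fit_results"])
    paths["trajectories"] = os.path.join(outdir, "trajectories.csv")
    traj_all = (pd.concat(traj_frames, ignore_index=True) if traj_frames
                else pd.DataFrame(columns=["group", "t", "post", "observed",
                                           "fitted", "counterfactual"]))
    traj_all.to_csv(paths["trajectories"], index=False)

    effect_rows = []
    for group, elist in effects.items():
        for e in elist:
            effect_rows.append({"group": group, **_io.effect_to_dict(e)})
    paths["report_effects_csv"] = os.path.join(outdir, "report_effects.csv")
    pd.DataFrame(effect_rows).to_csv(paths["report_effects_csv"], index=False)
    paths["report_effects_txt"] = os.path.join(outdir, "report_effects.txt")
    with open(paths["report_effects_txt"], "w", encoding="utf-8") as fh:
        fh.write(render_effects_table(effects, config.outcome, config.horizon))

    split_day = month_start_day(config.t0 + 1)
    process_eval = process_eval_report(results, patients, split_day)
    paths["process_eval"] = os.path.join(outdir, "process_eval.csv")
    process_eval.to_csv(paths["process_eval"], index=False)

    paths["log"] = os.path.join(outdir, "log.txt")
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(log) + "\n")

    return PipelineResult(
        config=config, patients=patients, dispensations=dispensations, truth=truth,
        results=results, exclusions=exclusions, n_orphans=n_orphans, series=series,
        stability=stability, fits=fits, effects=effects, process_eval=process_eval,
        paths=paths)
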