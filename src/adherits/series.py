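"""Group x calendar-month aggregation of patient-level outcome flags.

Patients are binned by their month of *discharge* (the cohort is defined by
discharge date ranges, not by index-fill dates).  Months with no retained
patients are kept as rows with a missing proportion — they are flagged by
:func:`stability_check` and dropped from the regression design, never
imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .months import month_of_day

SERIES_COLUMNS = ["group", "t", "numerator", "denominator", "proportion_pct"]


@dataclass(frozen=True)
class MonthlySeriesPoint:
    """One group-month aggregate: numerator / denominator as a percent."""

    group: str
    t: int
    numerator: int
    denominator: int

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.numerator / self.denominator


@dataclass
class StabilityReport:
    """Per-group series diagnostics ahead of modeling.

    A group's series is flagged (excluded from modeling unless forced) when
    any month has zero retained patients or a denominator under the floor —
    the situation that precluded modeling of the per-class initial-duration
    outcomes in sparse groups.
    """

    floor: int
    groups: pd.DataFrame  # group, min_denominator, n_missing_months, flagged

    @property
    def flagged_groups(self) -> list[str]:
        return list(self.groups.loc[self.groups["flagged"], "group"])

    def describe(self) -> str:
        lines = [f"series stability check (denominator floor = {self.floor}):"]
        for _, row in self.groups.iterrows():
            status = "FLAGGED" if row["flagged"] else "ok"
            lines.append(
                f"  {row['group']}: min denominator {row['min_denominator']}, "
                f"{row['n_missing_months']} missing month(s) -> {status}")
        return "\n".join(lines)


def aggregate_monthly(results: pd.DataFrame, patients: pd.DataFrame,
                      outcome: str, n_months: int) -> pd.DataFrame:
    """Aggregate a boolean outcome flag to group-month proportions.

    Parameters
    ----------
    results:
        Scored cohort from :func:`adherits.adherence.score_cohort`; must
        contain ``patient_id`` and the ``outcome`` column.
    patients:
        Cohort table supplying ``group`` and ``discharge_day`` per patient.
    outcome:
        Name of a boolean column of ``results`` (e.g. ``"adherent"``,
        ``"prolonged_avg"``, ``"adherent_statin"``).
    n_months:
        Calendar length of the series; every month 1..n_months appears for
        every group, with missing months carrying a NaN proportion.

    Per-class outcomes are aggregated over the patients who have that class
    at their index fill (rows with NA for the flag are not counted in either
    the numerator or the denominator).
    """
    if outcome not in results.columns:
        raise ValidationError(f"unknown outcome flag {outcome!r}")
    merged = results.merge(
        patients[["patient_id", "group", "discharge_day"]], on="patient_id",
        how="left", validate="one_to_one")
    if merged["group"].isna().any():
        raise ValidationError("scored patients missing from the cohort table")
    merged["t"] = merged["discharge_day"].map(month_of_day)
    if (merged["t"] < 1).any() or (merged["t"] > n_months).any():
        raise ValidationError("discharge day outside calendar months 1..n_months")

    flag = merged[outcome]
    counted = merged[flag.notna()].copy()
    counted["_flag"] = counted[outcome].astype(bool)

    grouped = counted.groupby(["group", "t"])["_flag"].agg(["sum", "count"])
    full_index = pd.MultiIndex.from_product(
        [sorted(merged["group"].unique()), range(1, n_months + 1)], names=["group", "t"])
    grouped = grouped.reindex(full_index, fill_value=0).reset_index()
    grouped.columns = ["group", "t", "numerator", "denominator"]
    grouped["numerator"] = grouped["numerator"].astype(int)
    grouped["denominator"] = grouped["denominator"].astype(int)
    grouped["proportion_pct"] = np.where(
        grouped["denominator"] > 0,
        100.0 * grouped["numerator"] / grouped["denominator"], np.nan)
    return grouped[SERIES_COLUMNS]


def stability_check(series: pd.DataFrame, floor: int = 10) -> StabilityReport:
    """Flag group series too unstable to model.

    A series is flagged if any month is missing (zero denominator) or any
    monthly denominator falls below ``floor``.
    """
    rows = []
    for group, sub in series.groupby("group"):
        n_missing = int((sub["denominator"] == 0).sum())
        min_den = int(sub["denominator"].min())
        rows.append({
            "group": group,
            "min_denominator": min_den,
            "n_missing_months": n_missing,
            "flagged": bool(n_missing > 0 or min_den < floor),
        })
    return StabilityReport(floor=floor, groups=pd.DataFrame(rows))
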