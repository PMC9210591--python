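"""Patient-level adherence scoring from dispensation claims.

Scoring pipeline for one patient:

1. :func:`find_index_fill` — earliest fill within the 7-day post-discharge
   window; its medication classes define the patient's class set.
2. :func:`class_coverage` — covered-day intervals per class under
   *sequential stacking*: an early refill's supply is consumed only after
   the previous supply runs out, so overlapping fills push coverage forward.
3. :func:`compute_pdc` — per-class proportion of days covered over the year
   after discharge (censored at death), average PDC across index classes,
   and the adherence / persistence / prolonged-dispensation flags.

Conventions: day 0 of a patient's window is the discharge day; intervals
are half-open at day granularity, so a fill on day d with s days supplied
covers days d .. d+s-1.  All thresholds are inclusive and configurable via
:class:`adherits.config.Thresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MED_CLASSES, Thresholds
from .errors import CohortInvariantError, ValidationError

Interval = tuple[int, int]


@dataclass(frozen=True)
class IndexFill:
    """A patient's first dispensation event within the index window.

    ``supplies`` maps each medication class dispensed on the index day to
    its total days supplied that day (same-day fills of one class merged by
    summing — blister packs / split fills).
    """

    patient_id: str
    index_day: int  # offset from discharge, 0..index_window_days
    supplies: dict[str, int]

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.supplies))

    @property
    def average_duration(self) -> float:
        return float(np.mean(list(self.supplies.values())))


@dataclass(frozen=True)
class AdherenceResult:
    """Scored outcomes for one retained patient.

    ``window_days`` is min(365, days from discharge to death).  Per-class
    entries exist only for classes dispensed at the index fill; the average
    PDC is their plain mean.
    """

    patient_id: str
    window_days: int
    index_day: int
    pdc: dict[str, float]
    average_pdc: float
    adherent: bool
    class_adherent: dict[str, bool]
    class_persistent: dict[str, bool]
    class_prolonged: dict[str, bool]
    average_initial_duration: float
    prolonged_avg: bool

    @property
    def n_classes(self) -> int:
        return len(self.pdc)


def merge_same_day(fills) -> list[Interval]:
    """Sort fills by day and merge same-day fills by summing supply.

    ``fills`` is an iterable of ``(day, days_supplied)``.
    """
    merged: dict[int, int] = {}
    for day, supply in fills:
        if supply < 1:
            raise ValidationError(f"days_supplied must be >= 1, got {supply} on day {day}")
        merged[day] = merged.get(day, 0) + supply
    return sorted(merged.items())


def class_coverage(fills, window_start: int, window_end: int) -> list[Interval]:
    """Covered-day intervals for one medication class under sequential stacking.

    Maintains a running coverage end ``e``: a fill on day ``d`` with supply
    ``s`` contributes the half-open segment ``[max(d, e), max(d, e) + s)``
    and advances ``e`` to the segment end.  The union of segments is then
    intersected with ``[window_start, window_end)``.  Disjoint, sorted
    intervals are returned; an empty fill list yields empty coverage.
    """
    if window_start >= window_end:
        raise ValidationError("window_start must be < window_end")
    segments: list[Interval] = []
    end = None
    for day, supply in merge_same_day(fills):
        start = day if end is None else max(day, end)
        end = start + supply
        if segments and start <= segments[-1][1]:
            segments[-1] = (segments[-1][0], end)  # abuts or is pushed to abut
        else:
            segments.append((start, end))
    out = []
    for lo, hi in segments:
        lo, hi = max(lo, window_start), min(hi, window_end)
        if lo < hi:
            out.append((lo, hi))
    return out


def covered_days(intervals: list[Interval]) -> int:
    return sum(hi - lo for lo, hi in intervals)


def max_uncovered_run(intervals: list[Interval], window_start: int, window_end: int) -> int:
    """Longest uncovered run inside the window, including leading/trailing runs."""
    gaps = []
    prev = window_start
    for lo, hi in intervals:
        gaps.append(lo - prev)
        prev = hi
    gaps.append(window_end - prev)
    return max(gaps)


def _index_from_arrays(patient_id: str, discharge: int, days, classes, supplies,
                       thresholds: Thresholds) -> IndexFill | None:
    """Array core of :func:`find_index_fill` (days/classes/supplies aligned)."""
    index_abs_day = None
    for d in days:
        if discharge <= d <= discharge + thresholds.index_window_days:
            if index_abs_day is None or d < index_abs_day:
                index_abs_day = int(d)
    if index_abs_day is None:
        return None
    merged: dict[str, int] = {}
    for d, c, s in zip(days, classes, supplies):
        if d == index_abs_day:
            s = int(s)
            if s < 1:
                raise ValidationError(
                    f"patient {patient_id}: days_supplied must be >= 1")
            merged[c] = merged.get(c, 0) + s
    return IndexFill(patient_id=patient_id, index_day=index_abs_day - discharge,
                     supplies=merged)


def find_index_fill(patient: pd.Series, fills: pd.DataFrame,
                    thresholds: Thresholds = Thresholds()) -> IndexFill | None:
    """Identify the index fill, or ``None`` if the patient is excluded.

    The index fill is the earliest fill day ``d`` with
    ``discharge_day <= d <= discharge_day + index_window_days``; the
    patient's class set is every class with a fill on exactly day ``d``.
    A class first dispensed on a later day does not join the class set.
    """
    if len(fills) == 0:
        return None
    return _index_from_arrays(
        str(patient["patient_id"]), int(patient["discharge_day"]),
        fills["fill_day"].to_numpy(), fills["med_class"].to_numpy(),
        fills["days_supplied"].to_numpy(), thresholds)


def prolonged_flags(index: IndexFill,
                    thresholds: Thresholds = Thresholds()) -> tuple[dict[str, bool], bool]:
    """Per-class and average prolonged-dispensation flags at the index fill.

    A class is a prolonged dispensation if its index days supplied is at
    least 90 (inclusive); the average flag requires the mean days supplied
    across index classes to reach 90.
    """
    per_class = {c: s >= thresholds.prolonged_days for c, s in index.supplies.items()}
    return per_class, index.average_duration >= thresholds.prolonged_days


def _score_from_arrays(patient_id: str, discharge: int, W: int, index: IndexFill,
                       days, classes, supplies,
                       thresholds: Thresholds) -> AdherenceResult:
    """Array core of :func:`compute_pdc`."""
    if W <= 0:
        raise CohortInvariantError(
            f"patient {patient_id}: death on or before discharge day "
            "(empty observation window)")
    by_class: dict[str, list[tuple[int, int]]] = {c: [] for c in index.classes}
    for d, c, s in zip(days, classes, supplies):
        if d >= discharge and c in by_class:  # fills before discharge ignored
            by_class[c].append((int(d) - discharge, int(s)))

    pdc: dict[str, float] = {}
    persistent: dict[str, bool] = {}
    for med_class in index.classes:
        intervals = class_coverage(by_class[med_class], 0, W)
        pdc[med_class] = covered_days(intervals) / W
        persistent[med_class] = max_uncovered_run(intervals, 0, W) < thresholds.max_gap_days

    average_pdc = float(np.mean(list(pdc.values())))
    per_class_prolonged, avg_prolonged = prolonged_flags(index, thresholds)
    return AdherenceResult(
        patient_id=index.patient_id,
        window_days=W,
        index_day=index.index_day,
        pdc=pdc,
        average_pdc=average_pdc,
        adherent=average_pdc >= thresholds.pdc_adherent,
        class_adherent={c: v >= thresholds.pdc_adherent for c, v in pdc.items()},
        class_persistent=persistent,
        class_prolonged=per_class_prolonged,
        average_initial_duration=index.average_duration,
        prolonged_avg=avg_prolonged,
    )


def _window_days(patient_id: str, discharge: int, death, thresholds: Thresholds) -> int:
    W = thresholds.followup_days
    if death is not None and not pd.isna(death):
        W = min(W, int(death) - discharge)
    return W


def compute_pdc(patient: pd.Series, index: IndexFill, fills: pd.DataFrame,
                thresholds: Thresholds = Thresholds()) -> AdherenceResult:
    """Score one patient's PDC, adherence, persistence and prolonged flags.

    The observation window is ``[discharge, discharge + W)`` with
    ``W = min(followup_days, death_day - discharge)``.  Per index class the
    PDC uses *all* of that class's fills from discharge onward (fills before
    discharge are ignored entirely; supply running past the window is
    truncated).  Persistence fails if any uncovered run of at least
    ``max_gap_days`` exists in the window — a trailing run counts.

    Raises :class:`CohortInvariantError` if death falls on or before the
    discharge day (the observation window would be empty).
    """
    pid = str(patient["patient_id"])
    discharge = int(patient["discharge_day"])
    W = _window_days(pid, discharge, patient.get("death_day"), thresholds)
    return _score_from_arrays(
        pid, discharge, W, index, fills["fill_day"].to_numpy(),
        fills["med_class"].to_numpy(), fills["days_supplied"].to_numpy(), thresholds)


def _result_row(r: AdherenceResult) -> dict:
    row = {
        "patient_id": r.patient_id,
        "window_days": r.window_days,
        "index_day": r.index_day,
        "n_classes": r.n_classes,
        "average_pdc": r.average_pdc,
        "adherent": r.adherent,
        "average_initial_duration": r.average_initial_duration,
        "prolonged_avg": r.prolonged_avg,
    }
    for c in MED_CLASSES:
        row[f"pdc_{c}"] = r.pdc.get(c, np.nan)
        row[f"adherent_{c}"] = r.class_adherent.get(c, pd.NA)
        row[f"persistent_{c}"] = r.class_persistent.get(c, pd.NA)
        row[f"prolonged_{c}"] = r.class_prolonged.get(c, pd.NA)
    return row


def score_cohort(patients: pd.DataFrame, dispensations: pd.DataFrame,
                 thresholds: Thresholds = Thresholds(),
                 ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Score every patient; return (results, exclusions, orphan fill count).

    Patients without a fill inside the index window are excluded with reason
    ``"no index fill"``.  Dispensations whose patient id does not appear in
    the cohort table are counted as orphans and ignored.  A death on or
    before discharge raises :class:`CohortInvariantError` (cohort invariant:
    patients are alive at discharge).

    The results frame has one row per retained patient with the
    :class:`AdherenceResult` fields; per-class columns are ``NA`` for
    classes outside the patient's index class set.
    """
    if patients["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in cohort table")
    if (dispensations["days_supplied"] < 1).any():
        raise ValidationError("days_supplied must be >= 1 for every dispensation")

    known = set(patients["patient_id"])
    orphan_mask = ~dispensations["patient_id"].isin(known)
    n_orphans = int(orphan_mask.sum())

    # group fills per patient as plain arrays (much faster than per-patient frames)
    fills = dispensations[~orphan_mask]
    order = np.argsort(fills["patient_id"].to_numpy(), kind="stable")
    f_pid = fills["patient_id"].to_numpy()[order]
    f_day = fills["fill_day"].to_numpy()[order]
    f_cls = fills["med_class"].to_numpy()[order]
    f_sup = fills["days_supplied"].to_numpy()[order]
    uniq, starts = np.unique(f_pid, return_index=True)
    bounds = np.append(starts, len(f_pid))
    slices = {pid: (int(bounds[i]), int(bounds[i + 1])) for i, pid in enumerate(uniq)}

    p_pid = patients["patient_id"].to_numpy()
    p_discharge = patients["discharge_day"].to_numpy()
    p_death = patients["death_day"].to_numpy(dtype=object)

    rows: list[dict] = []
    exclusions: list[tuple[str, str]] = []
    for i in range(len(patients)):
        pid = p_pid[i]
        lo, hi = slices.get(pid, (0, 0))
        discharge = int(p_discharge[i])
        index = _index_from_arrays(pid, discharge, f_day[lo:hi], f_cls[lo:hi],
                                   f_sup[lo:hi], thresholds)
        if index is None:
            exclusions.append((pid, "no index fill"))
            continue
        W = _window_days(pid, discharge, p_death[i], thresholds)
        rows.append(_result_row(_score_from_arrays(
            pid, discharge, W, index, f_day[lo:hi], f_cls[lo:hi], f_sup[lo:hi],
            thresholds)))

    results = pd.DataFrame(rows, columns=list(_result_row(_DUMMY).keys()))
    for c in MED_CLASSES:
        for prefix in ("adherent", "persistent", "prolonged"):
            col = f"{prefix}_{c}"
            if col in results.columns:
                results[col] = results[col].astype("boolean")
    exclusions_df = pd.DataFrame(exclusions, columns=["patient_id", "reason"])
    return results, exclusions_df, n_orphans


# template result used only to fix the column order of an empty results frame
_DUMMY = AdherenceResult(
    patient_id="", window_days=365, index_day=0, pdc={}, average_pdc=0.0,
    adherent=False, class_adherent={}, class_persistent={}, class_prolonged={},
    average_initial_duration=0.0, prolonged_avg=False)
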