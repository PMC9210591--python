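"""Synthetic cohort and dispensation-claims generator with known-truth effects.

The generator is *constructive*: each discharged patient is first drawn
adherent or non-adherent from the latent month-level adherence probability,
and a refill trajectory is then built that is guaranteed (up to rare early
deaths, measured by the label-fidelity tests) to score on the matching side
of the 80% average-PDC threshold.  This makes the latent group-month
proportion the exact estimand of the downstream segmented regression, so
parameter recovery can be tested cleanly — refill mechanics are emulated
only as far as the scoring rules can see them (sequential stacking, variable
durations, overlaps, gaps, early deaths).

All randomness flows through one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; identical configs produce byte-identical tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MED_CLASSES, GroupSpec, SimConfig
from .errors import ValidationError
from .months import month_start_day

#: Column order of the patients table.
PATIENT_COLUMNS = ["patient_id", "discharge_day", "death_day", "group", "site_id",
                   "age", "sex", "stemi", "prior_mi", "prior_med_use"]
#: Column order of the dispensations table.
DISPENSATION_COLUMNS = ["patient_id", "med_class", "fill_day", "days_supplied"]

# Constructive-generation margins around the 80% adherence threshold.
# Adherent patients get total uncovered time <= 19% of the window (PDC >= 0.81);
# non-adherent patients get a covered-days budget <= 70% of the window.
_ADHERENT_MAX_UNCOVERED_FRAC = 0.19
_NONADHERENT_TARGET_LOW = 0.15
_NONADHERENT_TARGET_HIGH = 0.70


class _Categorical:
    """Fast scalar sampling from a finite distribution via inverse CDF."""

    def __init__(self, mapping):
        items = list(mapping.items())
        self.values = [v for v, _ in items]
        self.cum = np.cumsum([p for _, p in items])
        self.cum[-1] = 1.0  # guard against float round-off

    def draw(self, rng: np.random.Generator):
        return self.values[int(np.searchsorted(self.cum, rng.random(), side="right"))]


@dataclass
class TruthRecord:
    """Generating parameters and latent state saved alongside a simulation.

    Attributes
    ----------
    config:
        The :class:`SimConfig` used.
    latent:
        One row per group-month: ``group, month, p_trend`` (noiseless
        percent), ``p_latent`` (with AR(1) noise, clipped to [0, 100]).
    labels:
        One row per patient: ``patient_id, group, site_id, month,
        adherent_label, has_index_fill``.
    n_clipped_months:
        Number of group-months where the noisy latent percent hit 0 or 100.
    """

    config: SimConfig
    latent: pd.DataFrame
    labels: pd.DataFrame
    n_clipped_months: int = 0

    @property
    def n_no_index_fill(self) -> int:
        """Patients generated without any fill inside the index window."""
        return int((~self.labels["has_index_fill"]).sum())


def ar1_noise(rng: np.random.Generator, n: int, rho: float, innovation_sd: float) -> np.ndarray:
    """Stationary AR(1) sequence: e_t = rho * e_{t-1} + u_t, sd(u_t) = innovation_sd."""
    if innovation_sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, innovation_sd / math.sqrt(1.0 - rho * rho))
    shocks = rng.normal(0.0, innovation_sd, size=n - 1)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + shocks[i - 1]
    return e


def segmented_mean(t: np.ndarray, t0: int, beta: np.ndarray) -> np.ndarray:
    """Segmented-regression mean: b0 + b1*t + I(t>t0)*(b2 + b3*(t-t0))."""
    t = np.asarray(t, dtype=float)
    post = (t > t0).astype(float)
    return beta[0] + beta[1] * t + post * (beta[2] + beta[3] * (t - t0))


def simulate_series(
    rng: np.random.Generator,
    beta: np.ndarray | tuple = (75.0, 0.0, -1.0, 0.5),
    n_months: int = 36,
    t0: int = 24,
    rho: float = 0.3,
    innovation_sd: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one group-month proportion series directly at the series level.

    Used for estimator calibration studies (bias, CI coverage, type-I error)
    where simulating individual patients adds nothing: the series is the
    segmented mean plus stationary AR(1) noise with the given innovation
    standard deviation (percentage points).

    Returns ``(t, y)`` with ``t = 1..n_months``.
    """
    t = np.arange(1, n_months + 1)
    y = segmented_mean(t, t0, np.asarray(beta, dtype=float))
    y = y + ar1_noise(rng, n_months, rho, innovation_sd)
    return t, y


def _latent_percents(cfg: SimConfig, group: GroupSpec, rng: np.random.Generator):
    """(noiseless trend, clipped noisy latent) percent series for one group."""
    m = np.arange(1, cfg.n_months + 1)
    lvl, trd = cfg.group_effects(group)
    trend = segmented_mean(m, cfg.t0, np.array(
        [cfg.baseline_adherence_pct, cfg.pre_slope_pct_per_month, lvl, trd]))
    if trend.min() <= 0 or trend.max() >= 100:
        raise ValidationError(
            f"group {group.label!r}: noiseless latent adherence leaves (0, 100) "
            f"(range {trend.min():.1f}..{trend.max():.1f}); clipping would bias recovery")
    noisy = trend + ar1_noise(rng, cfg.n_months, cfg.ar_rho, cfg.innovation_sd_pct)
    clipped = np.clip(noisy, 0.0, 100.0)
    n_clipped = int((noisy != clipped).sum())
    return trend, clipped, n_clipped


def _adherent_fills(rng, W, delay, durations, gaps, prolonged):
    """Near-continuous refills for one class; total uncovered days (initial
    delay plus positive inter-fill gaps) capped at 19% of the window."""
    max_uncovered = int(_ADHERENT_MAX_UNCOVERED_FRAC * W)
    uncovered = delay
    fills = []
    day = delay
    end = delay  # coverage end under sequential stacking
    while day < W:
        s = 90 if prolonged else durations.draw(rng)
        fills.append((day, s))
        end = max(day, end) + s
        if end >= W:
            break
        g = gaps.draw(rng)
        if g > 0 and uncovered + g > max_uncovered:
            g = 0
        uncovered += max(g, 0)
        day = max(end + g, day + 1)
    return fills


def _nonadherent_fills(rng, W, delay, durations, gaps, prolonged):
    """Truncated/gapped refills targeting a covered fraction well below 80%."""
    target = _NONADHERENT_TARGET_LOW + (
        _NONADHERENT_TARGET_HIGH - _NONADHERENT_TARGET_LOW) * rng.random()
    budget = int(target * W)
    covered = 0
    fills = []
    day = delay
    end = delay
    while day < W:
        s = 90 if prolonged else durations.draw(rng)
        if fills and covered + s > budget:
            break
        fills.append((day, s))  # index fill is mandatory even over budget
        covered += s
        end = max(day, end) + s
        if covered >= budget:
            break
        day = max(end + max(0, gaps.draw(rng)), day + 1)
    return fills


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate a full synthetic cohort: patients, dispensations, truth.

    Returns ``(patients, dispensations, truth)`` where the two data frames
    follow :data:`PATIENT_COLUMNS` / :data:`DISPENSATION_COLUMNS` and
    ``truth`` records the latent group-month adherence series and each
    patient's latent label for parameter-recovery testing.

    Raises
    ------
    ValidationError
        If the noiseless latent trajectory leaves (0, 100) for any group —
        systematic clipping would bias every downstream estimate.

    Warns
    -----
    UserWarning
        If AR(1) noise pushes more than 1% of group-months onto the [0, 100]
        bounds (occasional clipping biases recovery).
    """
    rng = np.random.default_rng(config.seed)
    durations = _Categorical(config.duration_mix)
    gaps = _Categorical(config.refill_gap_mix)
    class_mix = _Categorical(config.resolved_class_mix())
    hazard_per_day = config.death_rate_per_year / 365.25

    patient_rows: list[tuple] = []
    fill_rows: list[tuple] = []
    latent_rows: list[tuple] = []
    label_rows: list[tuple] = []
    n_clipped_total = 0
    patient_counter = 0
    followup = 365

    for group in config.groups:
        trend, latent, n_clipped = _latent_percents(config, group, rng)
        n_clipped_total += n_clipped
        for m in range(1, config.n_months + 1):
            latent_rows.append((group.label, m, trend[m - 1], latent[m - 1]))
        site_ids = [f"{group.label}_s{j + 1}" for j in range(group.n_sites)]
        site_effects = rng.normal(0.0, config.site_sd_pct, size=group.n_sites)

        for m in range(1, config.n_months + 1):
            start = month_start_day(m)
            width = month_start_day(m + 1) - start
            n_pat = int(rng.poisson(group.mean_monthly_discharges))
            if n_pat == 0:
                continue
            discharge_days = start + rng.integers(0, width, size=n_pat)
            sites = rng.integers(0, group.n_sites, size=n_pat)
            ages = np.clip(np.rint(rng.normal(76.0, 7.0, size=n_pat)), 65, 104).astype(int)
            sexes = (rng.random(n_pat) < 0.35).astype(int)
            stemis = (rng.random(n_pat) < 0.35).astype(int)
            prior_mis = (rng.random(n_pat) < 0.20).astype(int)
            prior_meds = (rng.random(n_pat) < 0.60).astype(int)

            for i in range(n_pat):
                patient_counter += 1
                pid = f"P{patient_counter:06d}"
                discharge = int(discharge_days[i])
                site = site_ids[int(sites[i])]

                if hazard_per_day > 0:
                    days_to_death = max(1, math.ceil(rng.exponential(1.0 / hazard_per_day)))
                else:
                    days_to_death = None
                death_day = (discharge + days_to_death
                             if days_to_death is not None and days_to_death <= followup
                             else None)
                W = followup if death_day is None else death_day - discharge

                p_pat = float(np.clip(latent[m - 1] + site_effects[int(sites[i])], 0.0, 100.0))
                adherent = rng.random() < p_pat / 100.0
                prolonged = rng.random() < config.prolonged_patient_prob
                classes = class_mix.draw(rng)

                delay = int(rng.integers(0, 8))
                if adherent:
                    delay = min(delay, int(_ADHERENT_MAX_UNCOVERED_FRAC * W))
                has_index = delay < W
                if has_index:
                    build = _adherent_fills if adherent else _nonadherent_fills
                    for med_class in classes:
                        for rel_day, supply in build(rng, W, delay, durations, gaps, prolonged):
                            fill_rows.append((pid, med_class, discharge + rel_day, supply))

                patient_rows.append((pid, discharge, death_day, group.label, site,
                                     int(ages[i]), int(sexes[i]), bool(stemis[i]),
                                     bool(prior_mis[i]), bool(prior_meds[i])))
                label_rows.append((pid, group.label, site, m, adherent, has_index))

    patients = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    patients["death_day"] = patients["death_day"].astype("Int64")
    dispensations = pd.DataFrame(fill_rows, columns=DISPENSATION_COLUMNS)
    latent_df = pd.DataFrame(latent_rows, columns=["group", "month", "p_trend", "p_latent"])
    labels_df = pd.DataFrame(
        label_rows, columns=["patient_id", "group", "site_id", "month",
                             "adherent_label", "has_index_fill"])
    truth = TruthRecord(config=config, latent=latent_df, labels=labels_df,
                        n_clipped_months=n_clipped_total)

    n_group_months = config.n_months * len(config.groups)
    if n_clipped_total > 0.01 * n_group_months:
        warnings.warn(
            f"{n_clipped_total}/{n_group_months} group-months hit the [0, 100] "
            "bounds; clipping will bias parameter recovery", UserWarning, stacklevel=2)
    return patients, dispensations, truth


def write_fixture(patients: pd.DataFrame, dispensations: pd.DataFrame, outdir) -> dict:
    """Write ``patients.csv`` and ``dispensations.csv`` under ``outdir``.

    Empty cohorts produce header-only files; ``death_day`` is blank for
    patients alive through follow-up.  Round-trips losslessly through
    :func:`adherits.io.read_patients` / :func:`adherits.io.read_dispensations`.
    """
    from . import io as _io  # local import to avoid a cycle

    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "patients": os.path.join(outdir, "patients.csv"),
        "dispensations": os.path.join(outdir, "dispensations.csv"),
    }
    _io.write_patients(patients, paths["patients"])
    _io.write_dispensations(dispensations, paths["dispensations"])
    return paths
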