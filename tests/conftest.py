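"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import adherits

# derandomised hypothesis profile so the suite is reproducible everywhere
settings.register_profile("ci", derandomize=True, max_examples=200, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles


def grid_coverage(fills, window_start: int, window_end: int) -> np.ndarray:
    """Day-by-day supply-bank oracle for sequential stacking.

    Each day, newly filled supply is added to a bank; if the bank is
    non-empty the day is covered and one day of supply is consumed.  This is
    the defining mechanism of sequential stacking, implemented without
    intervals, and is compared exactly against the interval implementation.
    Returns a boolean array over [window_start, window_end).
    """
    out = np.zeros(window_end - window_start, dtype=bool)
    if not fills:
        return out
    add: dict[int, int] = {}
    for day, supply in fills:
        add[day] = add.get(day, 0) + supply
    horizon = max(window_end, max(add) + sum(s for _, s in fills) + 1)
    bank = 0
    for day in range(min(add), horizon):
        bank += add.get(day, 0)
        if bank > 0:
            if window_start <= day < window_end:
                out[day - window_start] = True
            bank -= 1
        if day >= window_end and bank == 0:
            break
    return out


def intervals_to_grid(intervals, window_start: int, window_end: int) -> np.ndarray:
    out = np.zeros(window_end - window_start, dtype=bool)
    for lo, hi in intervals:
        out[max(lo, window_start) - window_start: hi - window_start] = True
    return out


def brute_force_reml(t, y, X, rho):
    """Dense-matrix GLS/REML pieces, independent of the package's whitening.

    Builds the AR(1) covariance V explicitly and inverts it with dense
    linear algebra.  Returns (minus-two REML log-likelihood at the profiled
    sigma^2, beta_hat, sigma2_hat).
    """
    t = np.asarray(t, float)
    n, p = X.shape
    lag = np.abs(np.subtract.outer(t, t))
    V = rho ** lag / (1.0 - rho ** 2)
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    resid = y - X @ beta
    rss = float(resid @ Vi @ resid)
    sigma2 = rss / (n - p)
    m2ll = ((n - p) * np.log(2 * np.pi * sigma2) + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtVX)[1] + (n - p))
    return m2ll, beta, sigma2


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_config() -> adherits.SimConfig:
    """A cohort small enough to score in well under a second."""
    return adherits.SimConfig(
        n_months=12, t0=8,
        groups=(adherits.GroupSpec("g1", n_sites=2, mean_monthly_discharges=25.0),
                adherits.GroupSpec("ctrl", n_sites=3, mean_monthly_discharges=40.0,
                                   level_change_pct=0.0, trend_change_pct_per_month=0.0)),
        seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return adherits.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    patients, dispensations, truth = small_cohort
    results, exclusions, n_orphans = adherits.score_cohort(patients, dispensations)
    return results, exclusions, n_orphans


@pytest.fixture(scope="session")
def fitted_series():
    """A fixed simulated series (n=36, t0=24) and its REML fit."""
    rng = np.random.default_rng(42)
    t, y = adherits.simulate_series(rng, beta=(75.0, 0.05, -1.0, 0.5),
                                    rho=0.3, innovation_sd=5.0)
    design = adherits.build_design(None, 24, t=t, y=y)
    return design, adherits.reml_fit_ar1(design)


def make_patient(patient_id="P1", discharge_day=0, death_day=None, group="g1",
                 site_id="s1") -> pd.Series:
    return pd.Series({
        "patient_id": patient_id, "discharge_day": discharge_day,
        "death_day": death_day, "group": group, "site_id": site_id,
        "age": 70, "sex": 0, "stemi": False, "prior_mi": False,
        "prior_med_use": False})


def make_fills(rows) -> pd.DataFrame:
    """rows: iterable of (patient_id, med_class, fill_day, days_supplied)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "med_class", "fill_day", "days_supplied"])
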