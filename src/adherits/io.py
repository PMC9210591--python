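"""CSV / JSON readers and writers for the pipeline's tabular interfaces.

All tables are UTF-8, comma-separated with a header row.  Day values are
integer offsets on the global calendar (no dates); ``death_day`` is blank
for patients alive through follow-up.  Writers are deterministic: rerunning
the pipeline with the same inputs produces byte-identical files.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .config import MED_CLASSES
from .errors import ValidationError
from .its import EffectEstimate, SegmentedFit
from .simulate import DISPENSATION_COLUMNS, PATIENT_COLUMNS

_PATIENT_DTYPES = {
    "patient_id": str, "discharge_day": int, "group": str, "site_id": str,
    "age": int, "sex": int, "stemi": bool, "prior_mi": bool, "prior_med_use": bool,
}


def _wrap_io(path: str, exc: Exception) -> ValidationError:
    return ValidationError(f"{path}: {exc}")


def read_patients(path: str) -> pd.DataFrame:
    """Read a patients table; validates columns and the alive-at-discharge rule."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "group": str, "site_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise _wrap_io(path, exc) from exc
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df["death_day"] = df["death_day"].astype("Int64")
    for col in ("stemi", "prior_mi", "prior_med_use"):
        df[col] = df[col].astype(bool)
    bad = df["death_day"].notna() & (df["death_day"] <= df["discharge_day"])
    if bad.any():
        raise ValidationError(
            f"{path}: {int(bad.sum())} patient(s) with death on/before discharge")
    return df[PATIENT_COLUMNS]


def read_dispensations(path: str) -> pd.DataFrame:
    """Read a dispensations table; validates classes and positive supply."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "med_class": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise _wrap_io(path, exc) from exc
    missing = set(DISPENSATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(df["med_class"].unique()) - set(MED_CLASSES)
    if unknown:
        raise ValidationError(f"{path}: unknown medication classes {sorted(unknown)}")
    if len(df) and (df["days_supplied"] < 1).any():
        first = df.index[df["days_supplied"] < 1][0]
        raise ValidationError(f"{path}: line {first + 2}: days_supplied < 1")
    return df[DISPENSATION_COLUMNS]


def write_patients(patients: pd.DataFrame, path: str) -> None:
    patients.to_csv(path, index=False)


def write_dispensations(dispensations: pd.DataFrame, path: str) -> None:
    dispensations.to_csv(path, index=False)


def write_series(series: pd.DataFrame, t0: int, path: str) -> None:
    """Write a monthly series with the post indicator / time-after columns."""
    out = series.copy()
    out["post_indicator"] = (out["t"] > t0).astype(int)
    out["time_after"] = np.where(out["t"] > t0, out["t"] - t0, 0)
    out.to_csv(path, index=False)


def read_series(path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype={"group": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise _wrap_io(path, exc) from exc


def effect_to_dict(effect: EffectEstimate) -> dict:
    d = {
        "name": effect.name,
        "estimate": effect.estimate,
        "se": effect.se,
        "ci_low": effect.ci_low,
        "ci_high": effect.ci_high,
        "p_value": effect.p_value,
        "df": effect.df,
        "level": effect.level,
    }
    if effect.horizon is not None:
        d["horizon"] = effect.horizon
    return d


def fit_to_dict(fit: SegmentedFit, effects: list[EffectEstimate]) -> dict:
    return {
        "beta": [float(b) for b in fit.beta],
        "se_beta": [float(s) for s in fit.se],
        "rho": float(fit.rho),
        "sigma2": float(fit.sigma2),
        "mse": float(fit.mse),
        "reml_loglik": float(fit.reml_loglik),
        "n": fit.n,
        "t0": int(fit.design.t0),
        "converged_at_boundary": fit.converged_at_boundary,
        "effects": [effect_to_dict(e) for e in effects],
    }


def write_fit_results(fits: dict[str, dict], path: str) -> None:
    """Write per-group fit summaries as deterministic, sorted-key JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)
        fh.write("\n")


def ensure_outdir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
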