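"""Configuration objects: simulation parameters, scoring thresholds, run config.

All thresholds used by the scoring rules (7-day index window, 80% PDC cut,
30-day permissible gap, 90-day prolonged dispensation, 365-day follow-up)
live in :class:`Thresholds` with the study defaults, so sensitivity analyses
can move them without touching scoring code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import yaml

from .errors import ValidationError

#: The four secondary-prevention medication classes tracked in dispensation
#: claims.  Aspirin is excluded: it is available over the counter and is not
#: reliably captured in prescription claims.
MED_CLASSES: tuple[str, ...] = (
    "statin",
    "beta_blocker",
    "angiotensin_system_inhibitor",
    "secondary_antiplatelet",
)

GROUP_INTERVENTION_1 = "intervention_1"
GROUP_INTERVENTION_2 = "intervention_2"
GROUP_CONTROL = "control"

#: Outcome flags that can be aggregated into group-month series.
OUTCOME_COLUMNS: tuple[str, ...] = (
    "adherent",
    "prolonged_avg",
    *[f"adherent_{c}" for c in MED_CLASSES],
    *[f"persistent_{c}" for c in MED_CLASSES],
    *[f"prolonged_{c}" for c in MED_CLASSES],
)


@dataclass(frozen=True)
class Thresholds:
    """Scoring thresholds, all inclusive (``>=``).

    Attributes
    ----------
    pdc_adherent:
        Average PDC at or above this fraction means long-term adherent.
    max_gap_days:
        An uncovered run of at least this many days breaks persistence.
    prolonged_days:
        Index days-supplied at or above this is a prolonged dispensation.
    index_window_days:
        A patient enters the cohort only with a fill within this many days
        of discharge (inclusive).
    followup_days:
        Length of the adherence observation window after discharge.
    """

    pdc_adherent: float = 0.80
    max_gap_days: int = 30
    prolonged_days: int = 90
    index_window_days: int = 7
    followup_days: int = 365

    def __post_init__(self) -> None:
        if not 0 < self.pdc_adherent <= 1:
            raise ValidationError("pdc_adherent must be in (0, 1]")
        for name in ("max_gap_days", "prolonged_days", "index_window_days", "followup_days"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.followup_days < 1:
            raise ValidationError("followup_days must be >= 1")


@dataclass(frozen=True)
class GroupSpec:
    """One hospital group in the simulated three-group design.

    ``level_change_pct`` / ``trend_change_pct_per_month`` override the
    config-wide intervention effects; the control group pins both to zero
    because no intervention is implemented there.
    """

    label: str
    n_sites: int
    mean_monthly_discharges: float
    level_change_pct: float | None = None
    trend_change_pct_per_month: float | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if self.mean_monthly_discharges <= 0:
            raise ValidationError("mean_monthly_discharges must be > 0")


def default_groups() -> tuple[GroupSpec, ...]:
    """Three-group structure matching the study's observed monthly cohorts.

    Two small intervention groups (about 39 and 26 discharges per month at 2
    and 4 sites) and one large external control (about 515 per month across
    143 sites).  Intervention effects are inherited from the config; the
    control group receives none.
    """
    return (
        GroupSpec(GROUP_INTERVENTION_1, n_sites=2, mean_monthly_discharges=39.0),
        GroupSpec(GROUP_INTERVENTION_2, n_sites=4, mean_monthly_discharges=26.0),
        GroupSpec(GROUP_CONTROL, n_sites=143, mean_monthly_discharges=515.0,
                  level_change_pct=0.0, trend_change_pct_per_month=0.0),
    )


def default_class_mix(
    n_class_probs: Mapping[int, float] | None = None,
) -> dict[tuple[str, ...], float]:
    """Distribution over medication-class subsets at the index fill.

    Built from a distribution over the *number* of classes (1-4), spread
    uniformly over the subsets of each size.  The default count mix gives a
    mean of about 2.7 classes per patient, consistent with the per-class
    denominators observed in elderly post-MI claims cohorts.
    """
    probs = dict(n_class_probs) if n_class_probs else {1: 0.10, 2: 0.30, 3: 0.40, 4: 0.20}
    mix: dict[tuple[str, ...], float] = {}
    for k, pk in probs.items():
        subsets = list(combinations(MED_CLASSES, k))
        for s in subsets:
            mix[s] = pk / len(subsets)
    return mix


def _check_distribution(name: str, dist: Mapping) -> None:
    total = 0.0
    for key, p in dist.items():
        if p < 0:
            raise ValidationError(f"{name}[{key!r}] is negative")
        total += p
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{name} probabilities sum to {total}, expected 1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic claims generator.

    The latent month-level adherence percent in group g at month m is

        p_m = baseline + pre_slope * m
              + [m > t0] * (level_change + trend_change * (m - t0))
              + site effect + AR(1) noise,

    clipped to [0, 100].  Patients discharged in month m are drawn adherent
    with probability p_m / 100 and their refill trajectories are built
    constructively so that scored average PDC lands on the correct side of
    the 80% threshold (see :mod:`adherits.simulate`).

    Units: all adherence quantities are percentages; slopes are percent per
    month; ``death_rate_per_year`` is an exponential hazard.
    """

    n_months: int = 36
    t0: int = 24
    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    baseline_adherence_pct: float = 75.0
    pre_slope_pct_per_month: float = 0.0
    level_change_pct: float = -1.0
    trend_change_pct_per_month: float = 0.5
    ar_rho: float = 0.3
    innovation_sd_pct: float = 2.0
    site_sd_pct: float = 0.0
    class_mix: Mapping[tuple[str, ...], float] | None = None
    duration_mix: Mapping[int, float] = field(
        default_factory=lambda: {30: 0.80, 60: 0.15, 90: 0.05})
    prolonged_patient_prob: float = 0.06
    refill_gap_mix: Mapping[int, float] = field(
        default_factory=lambda: {-7: 0.10, -3: 0.10, 0: 0.45, 2: 0.15, 5: 0.10, 10: 0.10})
    death_rate_per_year: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.t0 < self.n_months:
            raise ValidationError("t0 must satisfy 1 <= t0 < n_months")
        if not 0 < self.baseline_adherence_pct < 100:
            raise ValidationError("baseline_adherence_pct must be in (0, 100)")
        if not -1 < self.ar_rho < 1:
            raise ValidationError("ar_rho must be in (-1, 1)")
        if self.innovation_sd_pct < 0 or self.site_sd_pct < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0 <= self.prolonged_patient_prob <= 1:
            raise ValidationError("prolonged_patient_prob must be in [0, 1]")
        if self.death_rate_per_year < 0:
            raise ValidationError("death_rate_per_year must be >= 0")
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValidationError("group labels must be unique")
        _check_distribution("duration_mix", self.duration_mix)
        _check_distribution("refill_gap_mix", self.refill_gap_mix)
        if any(d < 1 for d in self.duration_mix):
            raise ValidationError("duration_mix days-supplied values must be >= 1")
        if self.class_mix is not None:
            _check_distribution("class_mix", self.class_mix)
            for subset in self.class_mix:
                if not subset or any(c not in MED_CLASSES for c in subset):
                    raise ValidationError(f"invalid class subset {subset!r}")

    def resolved_class_mix(self) -> dict[tuple[str, ...], float]:
        return dict(self.class_mix) if self.class_mix is not None else default_class_mix()

    def group_effects(self, group: GroupSpec) -> tuple[float, float]:
        """(level change, trend change) applying to one group, in percent."""
        lvl = group.level_change_pct
        trd = group.trend_change_pct_per_month
        return (
            self.level_change_pct if lvl is None else lvl,
            self.trend_change_pct_per_month if trd is None else trd,
        )

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``sim`` is given (the cohort is simulated) or ``patients_path`` and
    ``dispensations_path`` point at existing claims tables.
    """

    outdir: str = "adherits_out"
    sim: SimConfig | None = None
    patients_path: str | None = None
    dispensations_path: str | None = None
    outcome: str = "adherent"
    t0: int = 24
    horizon: int = 12
    thresholds: Thresholds = field(default_factory=Thresholds)
    df_method: str = "satterthwaite"
    denominator_floor: int = 10
    force_fit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValidationError(
                f"unknown outcome {self.outcome!r}; expected one of {OUTCOME_COLUMNS}")
        if self.horizon < 0:
            raise ValidationError("horizon must be >= 0")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValidationError("df_method must be 'satterthwaite' or 'residual'")
        if self.sim is None and (self.patients_path is None or self.dispensations_path is None):
            raise ValidationError("either sim or both input paths must be provided")


def load_run_config(path: str) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``sim`` and ``thresholds``
    are nested mappings.  ``sim.groups`` is a list of mappings with the
    :class:`GroupSpec` fields.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    kwargs = dict(raw)
    if "sim" in kwargs and kwargs["sim"] is not None:
        sim_raw = dict(kwargs["sim"])
        if "groups" in sim_raw and sim_raw["groups"] is not None:
            sim_raw["groups"] = tuple(GroupSpec(**g) for g in sim_raw["groups"])
        if "class_mix" in sim_raw and sim_raw["class_mix"] is not None:
            sim_raw["class_mix"] = {
                tuple(k.split("+")): v for k, v in sim_raw["class_mix"].items()}
        for key in ("duration_mix", "refill_gap_mix"):
            if key in sim_raw and sim_raw[key] is not None:
                sim_raw[key] = {int(k): v for k, v in sim_raw[key].items()}
        kwargs["sim"] = SimConfig(**sim_raw)
    if "thresholds" in kwargs and kwargs["thresholds"] is not None:
        kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"bad config file {path}: {exc}") from exc
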