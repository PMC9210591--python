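# Methods

## The problem

Hospital- and policy-level interventions on discharge prescribing (for
example, defaulting discharge prescriptions for secondary-prevention cardiac
medications to a 90-day supply) are typically evaluated on routinely
collected pharmacy-dispensation claims with a non-randomized interrupted
time series (ITS) design. This package implements that analytic chain as a
library: patient-level adherence scoring from claims, aggregation to
group-month proportion series, and segmented regression with autocorrelated
errors — plus a synthetic claims generator with known ground truth, since
real dispensation registries are access-restricted and no public fixture can
exercise the pipeline end to end.

## Adherence scoring

**Index fill and cohort entry.** A patient enters the scored cohort only if
they fill a prescription for at least one of the four tracked medication
classes (statin, beta blocker, angiotensin system inhibitor, secondary
antiplatelet; aspirin is excluded as an over-the-counter product) within 7
days of hospital discharge, inclusive. The patient's *class set* is the set
of classes dispensed on that earliest fill day. A class first dispensed on a
later day never joins the class set — a deliberately literal reading of
"classes dispensed at the index fill"; some real-world analyses instead
admit late starters. Same-day fills of one class are merged by summing
supply (blister packs, split fills).

**Coverage with sequential stacking.** Within one class, each fill of `s`
days supplied covers `s` days starting at its fill day *or* at the end of
the previous supply, whichever is later: early refills are assumed to be
consumed in sequence, never in parallel. Coverage is computed at day
granularity with half-open intervals (a fill on day `d` covers days
`d … d+s−1`), which compose without off-by-one ambiguity. The test suite
checks the interval implementation exactly against an independent day-by-day
"supply bank" simulation (each day, newly filled supply is banked; a
non-empty bank covers the day and is decremented) on tens of thousands of
random fill configurations — the two formulations are provably the same
mechanism, so any disagreement is a bug.

**PDC, adherence, persistence, prolonged dispensation.** The observation
window is `[discharge, discharge + W)` with `W = min(365, death − discharge)`
— deaths censor the window, and a death on or before discharge is a cohort
invariant violation, not a scoreable record. Per class in the class set, PDC
= covered days within the window / `W`, using all of that class's fills from
discharge onward; fills before discharge are ignored entirely, and supply
running past the window (or past death) is truncated, not redistributed.
The patient's average PDC is the unweighted mean over their class set, and
*long-term adherence* is average PDC ≥ 0.80. *Persistence* per class means
no uncovered run of ≥ 30 days anywhere in the window — including a trailing
run, so a patient who stops 40 days before window end is non-persistent, and
persistence shares the death-censored window with PDC. A *prolonged
dispensation* is ≥ 90 days supplied at the index fill, per class and as the
average across the class set. All thresholds (7, 0.80, 30, 90, 365) are
inclusive — the convention matching how such cutoffs are stated in adherence
research — and are configuration values.

## Aggregation

Patients are binned by calendar month of **discharge** (the cohort is
defined by discharge date ranges, not fill dates). The calendar is a global
integer day axis; month *m* is the equal-width bin
`[round(30.4375·(m−1)), round(30.4375·m))` — nothing downstream needs real
calendar months, only an integer month index. Each group-month point is
`100 · (patients with the outcome flag) / (retained patients discharged that
month)`. A month with no retained patients is *missing*, never zero; missing
months are dropped from the regression design while keeping true calendar
spacing for the remaining rows. Before modeling, a stability check flags any
group whose series has a missing month or a monthly denominator below a
floor (default 10; the floor is a judgment call, exposed in config, since
there is no principled universal cutoff). Flagged series are excluded from
modeling unless forced — sparse per-class outcome series at small sites are
the typical casualty.

## Segmented regression with AR(1) errors

For a group's monthly percent series `y_t`, with `t0` the last
pre-intervention month:

```
y_t = β₀ + β₁·t + β₂·I(t > t0) + β₃·(t − t0)·I(t > t0) + ε_t
ε_t = ρ·ε_{t−1} + u_t,   u_t ~ iid N(0, σ²)
```

β₀ is the baseline percentage, β₁ the secular pre-intervention slope, β₂ the
immediate (level) effect, β₃ the gradual (trend) effect. The *counterfactual*
is the pre-trend line β₀ + β₁·t extrapolated past t0, and the *overall effect
at horizon h* is the fitted-minus-counterfactual difference at month t0+h,
algebraically `β₂ + h·β₃`. The first post-implementation discharge month is
the first treated month (`I = 1` from `t0 + 1`).

**Estimation.** REML, profiled over ρ: for fixed ρ, β̂ is the GLS estimate
and σ̂² the REML residual variance; the profiled criterion (including the
log-determinants of the AR(1) covariance and of the whitened cross-product)
is minimized over ρ ∈ (−0.99, 0.99) by bounded scalar optimization with
tolerance 1e-8. Whitening uses the AR(1) prediction decomposition at
*calendar* lags — observation covariance `σ²·ρ^|tᵢ−tⱼ|/(1−ρ²)` — so gaps
from missing months are handled by the exact covariance, not re-indexing.
Convergence onto the ρ bound is recorded on the fit and warned about.
Proportions are modeled on the linear (absolute percent) scale, not logit:
the estimand of interest is the absolute change in adherent patients per
100, and effects stay directly interpretable on that scale. Monthly points
are unweighted by denominator (the unit of analysis is the group-month);
denominator-weighted GLS is offered as a non-default option since the
group-month design deliberately treats each month as one observation.

**Inference.** Contrast CIs and p-values use a t reference distribution.
Denominator degrees of freedom default to a Satterthwaite approximation:
the contrast variance `g(θ) = σ²·c'(X'V(ρ)⁻¹X)⁻¹c` is a function of
θ = (ρ, log σ²); with `A` the inverse observed REML information (numeric
central-difference Hessian of −2·l_R, steps 1e-4), `df = 2g²/(∇g'A∇g)`. When
ρ is held fixed the expression collapses analytically to the residual df
n − 4, and the code returns that value directly on the fixed-ρ path; the
same limit is exercised as a test. Any numerical failure of the
approximation (singular information, non-positive variance sensitivity)
falls back to n − 4, also selectable explicitly. Fits require at least three
observed months on each side of t0; with fewer the design is refused rather
than fit badly. Each group is modeled independently, two-sided tests, 95%
CIs, no multiplicity adjustment.

Calibration at the study's scale (n = 36, t0 = 24, AR(1) innovation SD 5
percentage points) is verified by the acceptance suite: level- and
trend-change estimates unbiased within Monte-Carlo error over 500
replicates, 95% CI coverage for the 12-month overall effect inside
[93.5%, 96.5%] over 2000 replicates at ρ ∈ {0, 0.3}, and type-I error of the
overall-effect test within binomial error of 5% under the null.

## Synthetic claims generator

**What it emulates.** A three-group hospital structure (two small
intervention groups of about 39 and 26 discharges/month at 2 and 4 sites,
one large control of about 515/month across 143 sites — monthly cohort
sizes typical of a province-wide elderly post-MI claims population), 36
monthly discharge cohorts with the intervention
after month 24, Poisson month-to-month cohort size variation, index fills
within 7 days of discharge across 1–4 classes, refill sequences with 30/60/90
day supplies, early refills (overlaps), gaps, early deaths (exponential
hazard 0.10/year, matching elderly post-MI 1-year mortality), and AR(1)
month-level noise on the latent adherence percent.

**Constructive generation.** The latent adherence percent of group g in
month m is the segmented mean above plus stationary AR(1) noise, clipped to
[0, 100]. Each patient is drawn adherent with that probability, and the
refill trajectory is then built to *guarantee* the scored label: adherent
patients get near-continuous supply with total uncovered time capped at 19%
of their window (PDC ≥ 0.81 per class); non-adherent patients get supply
truncated at a covered-days budget of at most 70% of the window. This makes
the latent group-month proportion the exact estimand of the downstream
regression — the generator exists to let parameter recovery be tested
cleanly, not to model pharmacy behavior mechanistically. The only mislabels
are patients who die within roughly the first five weeks, where a single
mandatory 30-day index fill can overshoot the 80% threshold; measured label
fidelity exceeds 99.7%, asserted at ≥ 99%.

**Defaults and why.** Baseline adherence 75% and AR(1) ρ = 0.3 with
month-level innovation SD 2 percentage points reflect the magnitudes seen in
aggregate adherence series of this kind (binomial sampling noise at the
observed monthly denominators contributes most of the remaining monthly
variance). Default intervention effects are a −1 percentage-point level
change and +0.5/month trend change — small effects of the size such
interventions plausibly produce — and the control group's effects are pinned
to zero. Days-supplied mix {30: 0.80, 60: 0.15, 90: 0.05} plus a
patient-level "prolonged prescriber" propensity of 0.06 (a patient whose
fills are all 90-day) put the pre-intervention prolonged-dispensation
proportions near observed claims values (about 5–7% on average across
classes, 7–19% per class); the patient-level propensity is needed because an
average duration ≥ 90 days across several classes is essentially
unreachable with independent per-fill draws. Inter-fill delays are drawn
from a small distribution over −7…+10 days (negative = early refill, which
exercises stacking). Site-level heterogeneity in adherence exists as a knob
(`site_sd_pct`) but defaults to 0 — within-group between-site variability is
not identified by any published quantity this generator targets.

**What it does not emulate** (so what passing tests do and do not show):
pharmacy reimbursement behavior, dose/strength semantics, switching between
classes, seasonal structure, utilization or clinical outcomes, and any
correlation between death and adherence. Passing recovery tests show the
*estimator chain* is correct under the model's assumptions; they say nothing
about confounding or fidelity in a real non-randomized rollout.

**Degenerate inputs and numerical choices.** Configs whose noiseless latent
trajectory leaves (0, 100) are rejected (systematic clipping would bias
every estimate); occasional noise-driven clipping above 1% of group-months
triggers a warning. Zero-noise series fit with σ̂² ≈ 0 and exact β recovery;
inference is meaningless there and the Satterthwaite path falls back to
residual df. Ties in same-day fills merge by summing before stacking.

## Problem sizes

The default test suite simulates cohorts of a few hundred to a few thousand
patients and runs about 3,500 REML fits (500 recovery + 2000 coverage + 500
type-I + unit fixtures), completing in well under a minute. The acceptance
script runs the full three-group, ~21,000-patient pipeline twice (for the
determinism check) plus the same calibration studies, in about half a
minute. These sizes were chosen to give Monte-Carlo error comfortably below
the tolerances being asserted.

## Known limitations

- The Satterthwaite df uses numeric differentiation of the REML criterion;
  it is accurate to the Monte-Carlo tolerances asserted, but is not a
  bit-for-bit reproduction of any particular mixed-model software's
  denominator-df machinery.
- The generator's adherent/non-adherent trajectories are stylized (margins
  at 81% / ≤ 70% of the window); per-patient PDC *distributions* are not
  calibrated to real claims, only the month-level proportions are.
- Persistence and per-class adherence flags are scored but no patient-level
  regression models are provided; the modeling surface is the group-month
  series only.
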