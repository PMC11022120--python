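# Methods

## Design problem

The package sizes a two-arm parallel trial comparing glucocorticoid
treatment alone (the "GC" or control arm) against glucocorticoids plus a
candidate neuroprotective drug, in first-episode AQP4-IgG seropositive
optic neuritis. The endpoint is an OCT summary measure of retinal
ganglion cell integrity in the affected eye: mGCIPL thickness (µm) or
mGCIPL volume (mm³), at 2 or 6 months after onset. Control-arm
parameters come from a pilot cohort of five affected eyes from four
patients, which ships with the package as a long-format CSV.

Eyes are the unit of analysis and are treated as independent, exactly as
in the pilot analysis, even though one patient contributes two eyes;
with five observations no within-patient correlation is estimable.
Units are fixed per metric and never converted.

## Pilot statistics

`summarize` and `summarize_change` report mean, sample SD (n−1
denominator), median, and range. All downstream arithmetic consumes the
**unrounded** statistics: the 6-month volume SD is 0.08355, and rounding
it to the displayed 0.084 changes the 6-month follow-up-value design
from 140 to a different total. The n−1 denominator is adopted because it
reproduces every published pilot SD; the n denominator does not.

One data quirk: the published follow-up medians accompanying the pilot
(60.00 µm / 0.44 mm³ at 2 months, 59.55 µm / 0.44 mm³ at 6 months) are
not the medians of the corresponding data columns (56.56 / 0.42 and
50.89 / 0.37); they coincide with one eye's raw values. This package
computes the correct order statistics, and its tests assert only the
baseline medians, which do reproduce.

## Effect-size model

"Protective effect of e" is defined as: the test drug prevents a
fraction e of the control arm's mean loss from baseline, so

    δ = e · (μ_baseline − μ_GC,followup)

This definition is not the only reading of "effect size"; it is fixed
here because it is the one under which the published worked example
(σ ≈ 0.0913 mm³, 131 per arm, 262 total at e = 0.20) reproduces, while
"e of the follow-up mean" and "e of the baseline mean" do not. Under
Method A the test-arm mean is μ_GC + δ (more tissue retained); under
Method B the test-arm mean change is (1 − e) times the control mean
loss. The two phrasings imply the same between-arm separation, which is
all the two-sample formulas consume. Loss is signed positive for a
deteriorating endpoint; an improving endpoint is allowed with a warning.

## Sample size and power

The closed-form test-arm size is

    n_test = (1 + 1/κ) (σ (z_{1−α/2} + z_{1−β}) / δ)²,  n_GC = κ·n_test

with normal quantiles at full double precision (z_{0.975} = 1.959964…;
using 1.96 shifts raw sizes in the third decimal). Defaults: α = 0.05
two-sided, power 0.80 (grid 0.80/0.90/0.95), κ = 1, effect grid
0.20–0.60. Both arms share a common σ, as the formula assumes; no
Welch-style unequal-variance sizing is offered.

Raw per-arm sizes are **ceiled per arm, each arm separately**. Ceiling
is the conservative standard — the analytic power at the integer sizes
is then never below target — and it reproduces the robust cells of the
published grid. The publication's own grid mixes rounding conventions
(some cells match round-to-nearest instead, e.g. a printed 350 where
ceiling gives 352), so whole-grid agreement is deliberately not asserted
anywhere.

The power function keeps both terms of

    1 − β = Φ(Z − z_{1−α/2}) + Φ(−Z − z_{1−α/2})

The second (far-tail) term is what makes power(δ=0) equal α exactly; in
every design regime this package targets it is below 1e−6, which is why
the one-term closed-form inversion and the two-term power function agree
— the inverse-consistency tests use exactly that tolerance. The
machinery is purely normal-approximation (σ treated as known); the
z-versus-t difference at the arm sizes involved (≥ 16) is far below the
Monte Carlo resolution used to validate it.

Method B is read as a **two-sample** comparison of change scores (the
closed form is a two-sample formula), not a paired analysis.

Dropout is handled only as a documented post-hoc multiplier
(`inflate_for_dropout`: divide total N by 1 − fraction and ceil); no
principled dropout model is claimed.

## Synthetic cohorts

`CohortModel` generates per-eye records per metric: baseline ~
N(baseline_mean, baseline_sd²), follow-up value = baseline·(1 −
loss_fraction·(1 − treatment_effect)) + residual. The reference
parameters emulate the pilot: volume baseline 0.534 ± 0.134 mm³ with
29.6% / 37.1% mean loss at 2 / 6 months, thickness 73.664 ± 18.497 µm
with 30.0% / 37.2% loss. Residual SDs default to measurement-noise scale
(0.03 mm³, 3 µm, the order of OCT repeatability); they cannot be chosen
to match the pilot's observed follow-up SDs exactly, because the shrunk
baseline SD alone already exceeds them.

Within-eye correlation is a shared eye-level standard-normal effect
scaled into each visit's residual (residual_t = sd_t(√ρ·u_eye +
√(1−ρ)·ε_t)), giving cross-visit residual correlation ρ. The default
ρ = 0.7 is a synthetic-data placeholder with **no empirical basis**; the
two-sample formulas consume only marginal moments and never see it.
Generated values are floored at 1e−6 to keep records strictly positive
(a ≈3–4σ left-tail event for volume at reference parameters); the floor
introduces a truncation bias in recovered SDs of order 1e−3, which the
parameter-recovery tests absorb in their standard-error-based
tolerances. The two metrics of a record are generated independently;
real thickness and volume are strongly coupled, so synthetic cohorts
must not be used to study cross-metric questions.

What passing the simulator-based tests shows: the closed-form sizes and
the two-term power function are mutually consistent and correctly
calibrated **under the normality, known-σ, independent-eyes model**.
What it does not show: robustness to skewed endpoints, measurement
floors, within-patient correlation, or dropout, none of which the
generator emulates.

## Monte Carlo engine

`simulate_trial_power` draws the two arms from normals with common σ and
applies the two-sided z-test at level α. Because the z statistic (σ
known) depends on the data only through the arm means, arm means are
simulated directly — an exact shortcut that makes 10⁵ replicates
instantaneous. An optional Welch-t analysis draws full samples instead,
as an off-by-default sensitivity check. A single integer seed controls
all randomness and is recorded in every report; grid-wide runs spawn
per-cell seeds from one `SeedSequence`. Reports flag a cell when
empirical and analytic power differ by more than 4 binomial standard
errors. Default validation runs use 10,000 replicates per cell (MC SE
≈ 0.004 at 80% power), which keeps a 120-cell grid validation around a
minute on one CPU; one-off checks in the tests use up to 50,000.

## Known limitations

- The pilot has five eyes; every σ and δ inherits that fragility. The
  package propagates the pilot uncertainty nowhere — the estimates are
  conditional on the pilot values, as is standard for this formula.
- The effect-size definition is reverse-engineered from the worked
  example (see above) and should be stated explicitly in any protocol
  that uses these numbers.
- No longitudinal modelling: effects apply to visit means only, and the
  simulator validates the two-sample machinery, not mixed-model analyses
  of trajectories.
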