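# Methods

## Model and assumptions

The package models blood HbA1c as the cell-weighted mean glycated
fraction of a population of erythrocyte cohorts. Within one cohort,
glycation is second-order in non-glycated hemoglobin and plasma
glucose, dHbA/dt = −k·HbA·BG, so after cumulative exposure
E = ∫BG dt the glycated fraction is exactly 1 − exp(−k_day·E) with
k_day = 86400·k. The population model assumes:

1. a constant erythrocyte life span LS (default 120 days);
2. constant turnover — one cohort enters and one leaves per day;
3. newly released reticulocytes carry no glycated hemoglobin;
4. in vivo elimination is strictly chronological (oldest first);
5. spleen-facilitated vesiculation is negligible.

Under these assumptions HbA1c at constant glucose converges to
`HbA1c(%) = 91.5·(1 − (1 − e⁻ˣ)/x) + 2.15` with x = k·LS·MBG (LS in
seconds); the package evaluates this with the configurable NGSP–IFCC
master-equation coefficients (0.09148, 2.152), of which 91.5/2.15 is
the rounded form.

## Numerical conventions

**Exact exponential updates.** Each daily step applies the closed-form
within-day solution (not an Euler step), so per-cohort fractions are
exact for daily-constant glucose, fractions can never leave [0, 1],
and the in vitro sub-daily sawtooth reduces exactly to the day's
cumulative exposure.

**Midpoint age convention.** Cells are released continuously through a
day, so the entering cohort is credited half of its birth-day
exposure; a cohort aged a days at steady state carries (a − ½) days of
exposure. This midpoint discretization makes the day-stepped
population mean agree with the continuous-age closed form to O((k_day·BG)²)
— about 10⁻⁵ % NGSP at physiological rates, versus ~0.1 % for a
full-birth-day convention at high glucose — while all scenario
benchmarks stay within the 0.1 % reporting precision. The steady-state
age profile is an exact fixed point of the daily update, so constant
profiles stay constant to machine precision.

**k estimation.** The terminal model HbA1c is strictly increasing in
k, so the fit uses bisection on k ∈ [10⁻¹⁰, 10⁻⁸] l·mmol⁻¹·s⁻¹ (the
population range is ~0.96–1.80 × 10⁻⁹), stopping when the modeled and
measured HbA1c agree within 0.05 mmol/mol on the IFCC scale; bisection
was chosen over secant/Newton for unconditional robustness on a
monotone objective, and convergence takes ≤ 60 (typically ~15)
iterations. The cohort history is supplied by the course itself: the
course (≥ LS days; shorter courses are cycled) is run once from an
unglycated population so the cohort aged a on the final day has lived
exactly the last a days. The analytic estimate inverts the closed form
by Brent root finding. Because k and LS enter only as a product, k and
LS are never estimated jointly; the life-span sweep re-fits k at LS ∈
{60…160} and k·LS stays nearly constant.

**Sub-daily data.** In vivo inputs are averaged to daily means before
simulation (HbA1c is insensitive to short-term variability); the in
vitro sawtooth uses 24 steps/day, which is exact for the linear
within-day interpolation.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| k | 1.296 × 10⁻⁹ | l·mmol⁻¹·s⁻¹ | population mean in adults with type 1/2 diabetes |
| k SD | 0.216 × 10⁻⁹ | l·mmol⁻¹·s⁻¹ | between-subject SD (CV ≈ 16.7 %) |
| LS | 120 | days | canonical erythrocyte life span |
| NGSP–IFCC | 0.09148, 2.152 | —, % | standard master equation; configurable |
| whole blood → plasma | × 1.11 | — | recommended plasma rescaling of whole-blood glucose |
| medium → plasma | ÷ 1.06 | — | water-content difference of culture medium |
| meter → reference | identity (warned) | — | device-specific coefficients must be supplied for real meter data |
| IFCC stopping rule | 0.05 | mmol/mol | fit tolerance of the iterative estimate |
| combined removal weight | 0.5 | — | chronological share of daily culture cell loss; a parameter, not a fitted value |

Scenario uncertainty bands rerun the model at k ± 1.96 SD. The
ADAG stand-in population defaults (HbA1c mean 7.5 %, SD 1.5 %,
truncation 4–12 %, residual SD 1.02 mmol/l giving r ≈ 0.92) are
placeholders — the source study's summary statistics are not printed —
and every quantity the tests rely on (noiseless line recovery,
regression algebra, the model line lying above the inverse ADAG line)
is insensitive to them. The model's regression line uses 25 evenly
spaced MBG values on [4, 20] mmol/l; the published 0.5547/2.4624
coefficients are matched with tolerance since the original grid is
unknown.

## Synthetic data: what it does and does not emulate

Generators (all bit-reproducible under seed) emulate the study-like
structure: per-subject k ~ Normal(1.296, 0.216) × 10⁻⁹ truncated
positive; diurnal glucose = basal + three Gaussian meal excursions,
with type 1 subjects ~1.2 mmol/l higher in mean and more variable than
type 2; whole-day glucose offsets (SD 0.8/0.6 mmol/l for type 1/2,
consistent with subjects under stable control); CGM as three six-day
sensor sessions with multi-week gaps, 5-min sampling and AR(1) sensor
noise; HbA1c as the mean of five replicates with 0.05 % NGSP assay SD
(an assumed, documented value); cultures at 5.2/10.5/15.7 mmol/l
plasma-equivalent glucose with exponentially decaying viability
(rate 0.05/day) and a daily sawtooth whose amplitude shrinks with
viability. The CGM sessions sample the same realized days the
subject's true course integrates, so end-to-end recovery error
reflects genuine subsampling (18 of 120 days), not generator
mismatch.

Not emulated: CGM drift/recalibration and sensor error spectra,
insulin–glucose physiology, non-constant erythropoiesis, life-span
heterogeneity between subjects, and real culture biochemistry
(GLUT1 transport changes, hemolysis). Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's
own assumptions, not robustness to the ways real CGM and assay data
violate them. Per-subject culture records use the generated truth as
reference, so removal-mode comparisons test orderings, not absolute
in vitro accuracy.

## Design choices where the design was open

- **Iteration scheme:** only the stopping rule is inherited; bisection
  is this package's choice.
- **WW tiling phase:** weeks start on a Monday (5 workdays + 2 weekend
  days); steady-state quantities are insensitive to phase.
- **ID ordering:** recorded days cycle in chronological order.
- **CGM gaps:** intra-day gaps ≤ 2 h are linearly interpolated, longer
  gaps drop the day.
- **Culture update order:** glycation first, then removal (affects
  results < 0.01 %); chronological truncation removes the boundary
  cohort fractionally so the measured viable fraction is met exactly.
- **Hypoglycemia interleaving** is deterministic (every Nth day), and
  the ordering-probability Monte Carlo truncates k at zero (untruncated
  sampling would produce k ≤ 0 with probability ~10⁻⁹).
- **Scenario evaluation grid:** every 10 days over [0, 120] for figure
  tables, configurable.

## Problem sizes

Tests and the acceptance script run at desk scale: 120-day courses,
30-subject cohorts for estimation-consistency and recovery checks
(1000 subjects for the CV check, via the fast analytic estimator),
100 000 draws for ordering probabilities, 10 000 pairs for ADAG
samples. These sizes keep Monte Carlo error comfortably inside the
stated tolerances.

## Known limitations

- k and LS are identified only through their product; any statement
  about one requires prior knowledge of the other.
- The constant-life-span assumption is the model's largest
  simplification; life-span heterogeneity (SD ~23 days in healthy
  subjects) can explain much of the apparent variability of k.
- The meter-to-reference recalibration defaults to identity and warns;
  real glucometer data need device coefficients.
- Printed NGSP↔IFCC pairs in source tables are not all consistent with
  a single master equation (rounding paths differ); conversions here
  are exact and never internally rounded.
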