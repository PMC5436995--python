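# Methods

This note documents the models, parameter choices and numerical decisions
behind `petdosim`, and what the synthetic cohort does and does not emulate.

## Biokinetic model and residence times

Organ activity is carried internally as the decay-corrected fraction of
injected activity (FIA) in the VOI; %IA/g is a presentation unit. With only
three samples per organ, each curve is described by a single exponential
`A(t) = A₀ exp(−λ_bio t)` extended to infinity beyond the last sample — the
standard recommendation for three-time-point studies. The residence time is
the closed-form integral against physical decay,

    τ = A₀ / (λ_bio + λ_phys),   λ_phys = ln2 / 1.1285 h⁻¹ (⁶⁸Ga),

integrated from t = 0: uptake before the first scan is represented by the
back-extrapolated exponential. Organs still accumulating tracer (negative
λ_bio, e.g. the choroid plexuses) are accepted as long as the effective
rate λ_bio + λ_phys stays positive; otherwise the integral diverges and the
fit is rejected rather than clamped.

Fitting is nonlinear least squares on the linear scale, started from the
log-linear closed form (exact for two points). R² is computed on the same
scale as the fit residuals (configurable to log scale; linear is the
default because the goodness-of-fit values are displayed alongside
linear-scale data). A constant curve is an exact fit with λ_bio = 0 and
R² = 1. Cohort statistics use the arithmetic mean and the sample SD (n−1);
a single subject reports SD = 0 by convention.

Special procedures:

* **Red marrow (two-region).** Per-gram TIACs of a femoral-head VOI and a
  lumbar-vertebrae (L3–L4) VOI are averaged and scaled by the reference
  phantom red-marrow mass (1120 g, adult male). Averaging two skeletal
  sites reduces bias from heterogeneous marrow uptake.
* **Colon partitioning.** The colon residence time is split between ULI and
  LLI wall proportionally to their phantom masses (220/160 g), conserving
  the sum exactly.
* **Whole body / remainder.** The whole-body VOI yields τ_WB; activity not
  assigned to an explicit organ becomes the remainder of body,
  τ_rob = τ_WB − Σ τ_organ (negative remainders are an input error).

## Dynamic voiding bladder

Urinary excretion is described by components (fraction fᵢ, biological
half-time T½ᵢ); cumulative decay-corrected delivery into the bladder is
B(t) = Σ fᵢ(1 − exp(−λᵢt)). Bladder contents decay physically and are
emptied instantaneously every T_v hours (to a configurable residual
fraction, default 0 — complete voiding). The residence time is evaluated
analytically per inter-void interval and summed until the remaining tail is
below 1e-9 MBq·h/MBq. Extrapolation between voiding schedules multiplies a
*measured* residence time by the model ratio of the two schedules, so the
measurement fixes the absolute scale and the model only supplies the
relative change.

**Calibrated default kinetics.** The published 30-min→1-h extrapolation
factor of ~1.74 equals the prompt-delivery closed form
(1−e^{−λ·1})/(1−e^{−λ·0.5}) for the ⁶⁸Ga decay constant, and no finite
single biological half-time reproduces it (the model ratio exceeds 1.9 for
any half-time in the minutes-to-hours range, approaching 1.74 only in the
prompt limit). The default kinetics are therefore **calibrated, not
derived**: a dominant effectively-prompt component (fraction 0.589,
T½ = 0.001 h) plus a small slow component (0.077, T½ = 1.5 h) that keeps
the bladder refilling between scans. This pair reproduces the 1.74 factor
(1.744) and anchors the synthetic whole-body residence time at 0.877 h.
The "doubling the voiding interval at most doubles τ" rule is approximate:
intermediate half-times can overshoot the factor-2 bound by a few percent
(numerically ≤ ~2.06 over realistic parameters).

## Unit-density sphere model

Structures absent from the phantoms (choroid plexuses) are dosed as
unit-density spheres of their estimated mass (supported range 0.01–6000 g):

    S = [Δ_np·φ_np(m) + Σᵢ yᵢEᵢ·φ_γ(m, Eᵢ)] / m.

φ_np is computed geometrically: positrons travel straight tracks of length
equal to their CSDA range in water, depositing energy uniformly along the
track, from uniformly distributed, isotropic emission points; the fraction
E[min(d, ℓ)]/ℓ is evaluated by 48×48 Gauss–Legendre quadrature over radius
and direction cosine, and averaged energy-weighted over the allowed β⁺
spectrum of each branch (Fermi correction omitted; the spectrum mean then
underestimates the compiled mean β⁺ energy by ≈4%, and the difference to
the frozen Δ_np = 0.7387 MeV is booked as locally absorbed Auger/conversion
energy). A Monte-Carlo chord-sampling oracle cross-checks the quadrature in
the test suite. φ_γ uses the mean escape path of a uniform spherical source
(3R/4) with water mass energy-absorption coefficients. With the measured
choroid residence time (3.08e-4 h) the model yields 0.0404/0.0595 mGy/MBq
for the 2.76/1.81 g male/female spheres, +2%/+5% against the published
0.0396/0.0566.

Choroid-plexus masses come from bilateral cylindrical segments (body,
atrial and temporal parts of the lateral ventricles); the shipped dimension
set is **synthetic**, calibrated to reproduce the published 2.76 g (male)
and 1.81 g (female) masses because the underlying MR morphometry is not
redistributable. Third/fourth-ventricle plexuses are excluded. Density is
fixed at 1.0 g/cm³ (configurable).

## Reference data and S-value fixtures

The ⁶⁸Ga decay data (T½ = 67.71 min, β⁺ branches 87.72%/1.19% with
endpoints 1.8992/0.8219 MeV, annihilation yield 1.7782, 1077-keV γ at
3.22%, Δ_np = 0.7387 MeV) are frozen from a published decay-data
compilation. Adult-male phantom masses follow the classic
Cristy–Eckerman-style adult reference phantom as commonly tabulated; the
adult-female masses are approximate stand-ins (documented in the fixture)
since only the male table is a quantitative reproduction surface here.

The shipped S tables are generated by `scripts/generate_svalue_fixtures.py`:
self-dose from the sphere model of the organ mass; cross-dose as a uniform
photon bath (body-absorbed annihilation/γ energy spread over the total-body
mass); the total-body source column as the activity-mass-weighted mixture
of the two, which makes the remainder-of-body correction exactly
self-consistent; and the urinary bladder wall dosed from its contents by
the standard hollow-organ convention (wall-surface dose = half the contents
equilibrium dose). These tables are deliberately approximate — they keep
the schema exact (linearity, remainder conservation, self ≥ cross) and give
realistic magnitudes for compact organs (e.g. kidney self-dose
1.55 mGy/(MBq·h)), but they are not a replacement for a validated kernel
set; the loader accepts user tables in the same dialect.

## Effective dose rules

Radiation weighting factor 1 (photons/positrons), so H_T = D_T. Colon is
the mass-weighted ULI/LLI wall combination. Surrogates: esophagus←thymus;
salivary glands and oral mucosa←brain (nearest available proxies, an
OLINDA-era convention). ICRP60 remainder: mass-weighted mean over
{adrenals, brain, small intestine, kidneys, muscle, pancreas, spleen,
thymus, uterus(female)}, with the splitting rule (a remainder tissue hotter
than every named tissue takes half the remainder weight alone). ICRP103
remainder: arithmetic mean over the remainder tissues available in the
phantom (extrathoracic region, lymphatic nodes and prostate have no
phantom representation and are excluded; the documented subset has 10
tissues for the male and 11 for the female phantom). Sex-specific ICRP103
EDs are reported for comparability but labelled non-standard; the reference
person averages equivalent doses per tissue across sexes (gonads:
testes/ovaries) before weighting, so it always lies between the sex-specific
values.

Reconstructing the published ICRP60 male 30-min ED from the published
organ-dose column with these rules gives 14.1 vs 15.7 μSv/MBq (−10%); the
gap is dominated by the mass-weighted remainder (muscle pulls it down) and
the unpublished remainder/surrogate treatment of the original analysis,
which is why that check carries a ±15% tolerance.

## Synthetic cohort

The generator emulates the study design: n = 5 subjects, scans at 10/60/120
min with uniform jitter matching the protocol tolerances (±2/±5/±5 min),
30-min voiding, multiplicative Gaussian noise truncated at zero with CV 5%
(PET VOI means are approximately proportional-error; the study reports no
noise model). Organ ground truths (A₀, λ_bio) are chosen so the true
residence times equal the published cohort means (kidneys 2.86e-2 h, liver
5.11e-2 h, colon 2.05e-2 h, ...), with clearance rates reflecting the
qualitative kinetics (slow kidney washout, choroid plexuses in uptake with
λ_bio = −0.3 h⁻¹). Mass balance holds exactly before noise: organs +
remainder + bladder + voided urine = 1 on the decay-corrected scale at all
times.

What it does **not** emulate: image formation (partial volume,
reconstruction bias, VOI delineation error), inter-subject kinetic
variability (all subjects share the truth; variability comes from jitter
and noise only), multi-exponential kinetics, and a realistic urinary
transit time (the calibrated prompt component front-loads the bladder, so
the synthetic bladder residence time, ~0.22 h, exceeds the published
0.073 h; end-to-end synthetic EDs are correspondingly higher than the
published ones). Passing the recovery tests therefore demonstrates that
the estimation chain is unbiased under its own assumptions, not that those
assumptions hold for any given patient. The whole-body curve is a step
function of the voiding cycle and is only approximately mono-exponential;
its fitted residence time is biased low by ~10%, which propagates into the
remainder term (the same limitation applies to the real protocol).

Problem sizes: the default analysis uses 5 subjects; the stochastic
parameter-recovery check runs 100 seeds × 5 subjects (median relative
residence-time error ≈0.9%, bound 10%).

## Numerical choices

* Bladder interval summation stops when the remaining tail bound is
  < 1e-9 h; the ODE cross-check agrees to 1e-6 relative.
* Sphere quadrature: 48-node Gauss–Legendre in radius and angle; β⁺
  spectra on 200-point grids; CSDA ranges and μ_en log-log interpolated
  from 15/10-point frozen tables.
* Fits: `scipy.optimize.curve_fit`, log-linear start values; exact
  interpolation when parameters equal samples; R² of a constant curve
  defined as 1 when residuals vanish.
* Ranking ties break lexicographically by organ name. Reports print
  3-significant-figure scientific notation; full precision is kept
  internally.
* The phantom-concentration worked value 42.3 MBq/9340 mL = 4.529 kBq/mL
  rounds to 4.53 at three significant figures; the published table prints
  4.52, and checks accept one unit in the last printed digit.

## Known limitations

* Fixture S tables are first-principles approximations (see above); organ
  cross-doses ignore geometry-specific photon transport entirely.
* The female phantom fixture is approximate; female extrapolations are
  structural (vocabulary, monotonicity) rather than quantitative.
* Hollow-organ wall/content geometry is modelled only for the urinary
  bladder; other walled organs use self-absorption at the wall mass.
* No patient-specific organ masses; no multi-exponential or compartmental
  fitting; no voxel phantoms or Monte-Carlo transport.
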