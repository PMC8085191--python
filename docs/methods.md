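# Methods

## Scope

`pbifpet` replicates, on synthetic data with full ground truth, the
workflow used to validate population-based input functions (PBIF) for a
reversible brain PET tracer quantified with Logan graphical analysis:
process each subject's arterial blood data into a patient-specific input
function (PSAIF), pool normalized PSAIFs leave-one-out into a PBIF,
rescale the PBIF to each individual, estimate regional V_T through both
routes, and judge the surrogate against the repeatability of the arterial
method itself.

## Input-function processing

The total-blood activity curve is modeled as a linear rise from zero at
injection to a peak, followed by a sum of three decaying exponentials
(amplitudes A1–A3 in kBq/mL, rates λ1 > λ2 > λ3 in 1/min, peak time in
min).  Fitting is multi-start nonlinear least squares (trust-region
reflective, bounds keeping rates positive) over a fixed, log-spaced grid
of 27 rate-triple starts; starting amplitudes come from non-negative
linear least squares at each rate triple.  Tri-exponential fits are
initialization-sensitive, and the deterministic start list keeps every
fit reproducible; the best residual sum of squares wins and all starts
are recorded in the fit report.

The parent (unmetabolized) fraction is fitted with a Hill-type curve
f(t) = a + (1−a)·c^b/(c^b + t^b), which is monotone non-increasing with
f(0) = 1 and plateau `a`.  The published analyses for this tracer class
use a proprietary metabolite model whose closed form is not printed; the
Hill form reproduces its qualitative behavior (unity at injection,
monotone fall, late plateau) and is exposed by name so an alternative can
be registered.

Metabolite correction multiplies the fitted total curve by the fitted
parent fraction — fit first, correct after, matching the order used in
practice.  The corrected curve is then sampled onto a uniform 1-s grid
over 0–90 min and rigidly time-shifted so its maximum sits at 30 s, the
point where most input functions peak; a right shift zero-pads the
origin, a left shift extends the right end by evaluating the analytic
model (or a mono-exponential fitted to the last 10 min when only samples
are available).  Rigid shifting trades a small area error for exact
shape preservation; the test suite bounds the area change at 0.5% for
the few-second shifts the generator actually produces.  All areas under
curves are trapezoidal on the stored grid.

## PBIF construction and rescaling

Each cohort PSAIF is normalized by one of three schemes before
averaging: weight × injected dose (kg·MBq), the curve's own 0–90 min AUC
(kBq·min/mL), or weight × AUC.  The AUC uses the metabolite-corrected
curve over the full span, consistent with the integrals entering the
Logan transform.  For every subject the PBIF is the pointwise mean of
the other subjects' normalized curves (sample SD, n−1, is carried as a
dispersion band).  Rescaling back to an individual multiplies by
weight × dose, or — for the AUC-based schemes — tail-scales the
population curve by the mean ratio of the subject's late blood values to
the population curve at the same times (60 and 90 min by default).
Single-sample scaling at each of 30/37.5/45/52.5/60/75/90 min can be
screened; the pseudo times are averages of two bracketing draws and are
matched against the same average of the population curve, so a subject
exactly proportional to the population shape is rescaled with zero area
error at every candidate.

## Kinetics

Ground-truth tissue curves solve the two-tissue-compartment system
analytically: the impulse response is a two-exponential function of
(K1, k2, k3, k4) and the tissue curve is its convolution with the plasma
input on the 1-s grid (FFT convolution with trapezoid end-point
correction).  The measured frame value averages
(1−vB)·(C1+C2) + vB·C_blood over each acquisition frame; vB defaults to
0.05 and the blood term uses the total-blood (uncorrected) curve, a
configurable choice since conventions differ.  Blood-volume correction
inverts that mixture and clips negatives (with a logged warning —
negative frames occur only under noise).

Logan coordinates are computed at frame mid-times; the tissue integral
anchors a straight segment at (0, 0) before the first mid-time, the
plasma integral is trapezoidal on the 1-s grid.  The linearity onset t*
is the earliest frame such that an ordinary least-squares line through
the remaining points leaves every relative deviation |y−ŷ|/|ŷ| at or
below the threshold (default 10%); measuring against the observed value
instead is available as a documented toggle.  If no start qualifies, the
last three points are used and the result is flagged.  V_T is the OLS
slope; diagnostics are R², AIC in the Gaussian-RSS form
n·ln(RSS/n) + 2k with k = 2, and the percent standard error of the
slope (unweighted OLS — no weighting scheme is assumed).

Logan analysis is asymptotically exact for reversible kinetics but needs
the slow eigenvalue of the system to have decayed.  With the generator's
default constants (k2 = 0.25, k3 = 0.06, k4 = 0.04 /min; equilibration
half-time ≈ 22 min) the 90-min schedule recovers V_T to about 1%
(frame-discretization residual only); a deliberately slow parameter set
(half-time ≈ 80 min) needs a several-hour simulated scan before the
slope converges, and the test suite demonstrates exactly that.

## Agreement statistics

Test-retest uses the symmetric percent difference (pair-mean
denominator); PBIF-vs-PSAIF uses the PSAIF-referenced difference, which
is deliberately not antisymmetric.  Bland-Altman bias and limits of
agreement use the sample SD with a configurable coverage factor (default
1.96; some published tables are consistent with 2.0, and both are
exercised in the tests).  The coefficient of repeatability is
implemented in the printed form CR = 1.96·√(σ²/(N−1)) — which divides
the variance by N−1 a second time and therefore behaves like a standard
error — with the conventional 1.96·SD available behind a flag.  ICC
defaults to the two-way mixed, single-measure, consistency form
ICC(3,1) (computed via pingouin; any of its forms can be requested),
since reliability tables in this literature rarely state the form.
Scheme comparisons run a one-way ANOVA over the per-region difference
vectors, all pairwise two-sided t-tests — paired, because the schemes
are applied to the same cohort — with Bonferroni correction (p×3 capped
at 1), and Shapiro-Wilk normality per group.  Gray-matter normalization
divides each regional V_T by the session's (volume-weighted) mean over
the designated gray-matter structures, removing any session-level
multiplicative factor.

## The synthetic cohort

The generator emulates the study conditions: 18 subjects (12 Parkinson
disease, 6 healthy volunteers), five healthy volunteers with same-day
test-retest sessions, genotype split between high- and mixed-affinity
binders (low-affinity binders excluded), automated arterial sampling
every 15 s for 10 min plus manual draws at 20/30/45/60/90 min, parent
fractions at 5/10/20/30/45/60/90 min, nine regions on the 32-frame
schedule (6×10, 4×30, 3×60, 2×120, 5×240, 12×300 s).

Defaults and the reasoning behind them:

| parameter | default | rationale |
| --- | --- | --- |
| weight | 75 kg × lognormal, CV 0.15 | typical adult cohort spread |
| injected dose | 526.4 MBq × lognormal, CV 0.14 | reported mean ± SD of the protocol |
| blood-curve base shape | A = (60, 8, 3) kBq/mL, λ = (4.0, 0.35, 0.012) /min | carbon-11 bolus: sharp peak ≈60 kBq/mL at ~500 MBq, slowly decaying tail ≈1 kBq/mL at 90 min |
| peak time | 0.5 min ± 0.05 (SD) | peaks cluster near the 30-s alignment target |
| AIF amplitude / rate CVs | 0.20 / 0.15 | assumption — the inter-subject variability of the source cohort is not published; these values reproduce a PBIF-vs-PSAIF spread of the magnitude reported for this tracer class |
| parent fraction | a = 0.15, b = 1.5, c = 15 min, CV 0.10 | falls to ~50% by 15 min, plateau ~15%, as metabolite profiles for this class show |
| regional V_T (HAB baseline) | 3.2–4.9 mL/cm³ across the nine regions | the reported healthy-volunteer range; K1 sets the level with k2 = 0.25, k3 = 0.06, k4 = 0.04 /min shared |
| genotype effect | MAB = 0.60 × HAB | the ~40% V_T reduction reported for mixed-affinity binders |
| disease effect | PD = 1.15 × HV | small, statistically fragile group difference |
| subject / region V_T CVs | 0.25 / 0.05 | global TSPO expression varies much more across subjects than across regions within a subject |
| retest effect | 1.25 × lognormal, CV 0.15 | same-day retest studies of this tracer class report a systematic 20–30% V_T increase with subject scatter |
| noise | additive Gaussian, SD = 0.1·√(C/Δ) | count-statistics-like heteroscedasticity: ~2–3% on 5-min frames, larger on 10-s frames and late blood draws; exactly zero at noise_scale = 0 |

Composition conventions: the tri-exponential parameterizes the *total*
blood curve (what gets fitted), the parent curve is total × f, whole
blood ≡ plasma, and all activities are decay-corrected by construction.
The measured total equals parent/f plus noise, so noise-free generation
and processing are exact inverses — the round-trip test requires <1%
recovery of the true corrected curve on [1, 90] min and achieves machine
precision.

What the generator does **not** emulate: image-domain effects (partial
volume, motion, reconstruction noise correlations between regions),
sampler dispersion/delay, plasma-to-whole-blood ratios and plasma free
fraction, genotype- or disease-dependent input-function shape, decay
physics, and left/right hemisphere duplicates.  Passing tests therefore
demonstrate the correctness and internal consistency of the estimation
chain under the stated statistical structure, not performance on real
scanner data.

## Problem sizes and runtime

The cohort-level checks run the full replica three ways: noise-free
(18 subjects + 5 retests, 9 regions), fully degenerate (all variability
zero — every rescaled population curve must reproduce the excluded
subject's curve to ~1e−9 and its V_T to <1e−6), and at the default
stochastic conditions.  Each run is a few tens of seconds on one CPU;
the whole test suite and the acceptance script each complete in about a
minute.

## Known limitations

* The weight × dose scheme inherits whatever correlation the generator
  imposes between plasma concentration, dose and weight; its relative
  ranking among schemes is assumption-dependent.
* The Fig-4-style tail screen's absolute error level scales directly
  with the assumed AIF-shape variability, which is a documented
  assumption, not a published value.
* With five test-retest pairs the limits of agreement are estimated from
  four degrees of freedom; region-to-region variation of those limits is
  dominated by the shared subject-level draws.
* Logan's multiplicative-noise bias (negative) is reproduced
  qualitatively and tested directionally, not calibrated to a scanner
  noise model.
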