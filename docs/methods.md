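# Methods

This note documents the models and procedures implemented in `hrvidh`, the
assumptions behind them, the synthetic-data generator that stands in for the
unavailable patient-level data, and the numerical choices made where the
design was genuinely open.

## Preprocessing

A tachogram is the sequence of RR intervals (ms) against beat time (s);
`rr[k]` is the interval ending at `time[k]`, so cumulative RR reproduces the
beat times of a recording started at t = 0 (the 10-minute pre-dialysis rest
is assumed to precede t = 0).

**Ectopic rule.** An interval deviating more than 20% from the reference is
removed. "Previous" is read as the most recent *retained* interval, not the
raw predecessor: under the raw-predecessor reading a single ectopic beat
also condemns the normal beat after it, and the filter would not be
idempotent. Idempotence (re-filtering a clean series removes nothing) is a
tested invariant and only holds under the retained-reference reading.
Removed beats are dropped outright — no interpolated replacements — from
both the time-domain statistics and the resampling input.

**Segment grid.** Segments are 300-s half-open windows on wall-clock beat
time, `[(k-1)·300, k·300)`, k = 1…48 for a 240-minute session; a beat at
exactly a boundary starts the next segment. A recording must reach the end
of the grid to within 5 s (a few beats of slack for heartbeat discreteness);
shorter recordings raise unless a partial grid is explicitly requested.
Phases: early = segments (1, 2), middle = (24, 25), late = (47, 48).

## HRV features

Per segment (≥ 3 beats required): mean RRI; mean HR defined as
60000 / mean RRI (one consistent definition, not the mean of instantaneous
rates); SDNN with the n−1 denominator; RMSSD.

Spectral analysis resamples the tachogram at 4 Hz by linear interpolation
(samples outside the beat span hold the nearest beat's value; a 300-s
segment gives exactly 1200 samples) and applies Welch's method: 256-sample
(64-s) windows, 75% overlap (15 windows per segment), per-window mean
removal, Hann taper with power correction, density scaling — the PSD
integrates to the variance of the mean-removed signal (Parseval is a tested
invariant, 10% tolerance on broadband input). The taper is a choice: Welch
alone does not name one, and Hann is the field default; band tests carry
15% tolerances to absorb its leakage.

Band powers integrate the PSD over bins whose *centre* frequency falls in
the half-open band [low, high) — VLF [0.003, 0.04), LF [0.04, 0.15),
HF [0.15, 0.40) Hz — so no bin is counted twice at the shared edges. TP is
defined as the integral over the union of the three bands, which makes
`vlf + lf + hf = tp` exact on the bin grid; the alternative convention
(everything below 0.4 Hz including < 0.003 Hz) differs negligibly at this
window length. Note two resolution effects of 64-s windows: only bins at
multiples of 1/64 Hz exist, so VLF content below ~0.016 Hz is unobservable;
and a tone riding on a ~1 Hz beat train is low-passed by beat sampling plus
linear interpolation (a 0.25 Hz, 50 ms tone at HR 60 loses roughly a third
of its power before the PSD sees it). The band-*fraction* contracts
(≥ 90% of power in the right band) are unaffected; the absolute a²/2 check
is asserted on evenly sampled input, where it holds to within leakage.

Phase values are the arithmetic mean of the phase's two segments; the LF/HF
ratio is averaged as a ratio (not recomputed from averaged LF and HF — the
two differ and the averaged-ratio reading is the documented choice). Delta
features are middle − early, signed so that a *rise* in a band power gives a
positive delta; protective (rate-ratio < 1) delta effects then mean "larger
early-to-middle increases predict fewer events". If HF power is exactly
zero the ratio (and its delta) is reported missing, never infinite.

## Count models

Monthly IDH counts from a small cohort are over-dispersed, so the model is
NB2 with log link: Var(y) = mu + alpha·mu², both beta and alpha estimated by
full maximum likelihood (the method-of-moments alternative for alpha is not
used). No exposure offset: every patient contributes the same 12 sessions
per month, so log-exposure is constant and absorbed by the intercept.
Inference is Wald throughout — Exp(B) = exp(beta) with
exp(beta ± 1.96·SE) intervals from the observed information — matching the
rate-ratio reporting convention. AIC = −2 logL + 2k and
BIC = −2 logL + k ln n count the dispersion in k.

Likelihood maximisation is delegated to statsmodels with a Poisson warm
start (clipped to ±10, since quasi-separated binary covariates push Poisson
coefficients toward infinity) and an optimiser cascade: BFGS, Newton, then
box-bounded L-BFGS (coefficients in ±15, alpha in [1e-6, 50]). The bounds
matter under quasi-separation — when, say, every carrier of a binary
covariate has zero events, the likelihood plateaus as that coefficient
diverges, and a bounded optimiser pins it on the plateau instead of
wandering to NaN. When the fitted dispersion sits on the Poisson boundary
the observed information is singular; the covariance then falls back to its
pseudo-inverse. Constant design columns (a small cohort drawing zero
carriers) are dropped with a warning before fitting.

**Screen and search.** Candidates enter the multivariate model when their
univariate Wald p < 0.10; a caller-supplied force-include list (by default
coronary disease and heart failure, clinically established risk factors a
small sample cannot confirm) is kept regardless. The delta search fits the
basic model plus every subset of (screened) delta columns up to 4 terms,
excludes candidates whose design has any VIF > 10 — VIF_j = 1/(1−R²) from
an intercept-included least-squares regression of column j on the rest — or
any pairwise |r| > 0.8 involving an added column, and ranks survivors by
the in-sample AUC of the linear predictor against "count ≥ 1". The basic
model is always reported and never excluded. The 0.8 correlation bound is a
configurable default; "mutually strong correlation" has no canonical
number.

**Reporting scales.** Age per 10 years, iPTH per 100 pg/mL, spectral deltas
per 100 ms². The RRI delta's published reporting unit is ambiguous (0.1 ms
as printed is physiologically implausible for the effect size it carries;
0.1 s is the likely intent), so the divisor is configuration
(`delta_rri_unit`, default 100 ms) rather than a hard-coded assertion.

## ROC and DeLong

AUC is the Mann–Whitney estimate with midrank ties:
(#concordant + ½·#tied) / (n₁·n₀) — ties are real here, because linear
predictors dominated by binary covariates coincide exactly. The ROC curve
(one point per distinct threshold plus endpoints) has trapezoidal area equal
to the midrank AUC to 1e-12, a tested identity. DeLong's paired test
computes per-subject placement values (with midranks), estimates the
covariance of the two AUCs across cases and across controls, and refers
z = ΔAUC/√Var to the standard normal, two-sided. Zero variance with equal
AUCs gives p = 1; zero variance with unequal AUCs is a degenerate pairing
and an error. Both components are checked against brute-force enumeration
oracles, and the test's type-I error is verified to sit in [0.03, 0.07] at
the nominal 5% level.

## Descriptive statistics

"As appropriate" is operationalised and logged: categorical contrasts use
Pearson chi-square *without* continuity correction when all expected counts
are ≥ 5, Fisher's exact test otherwise (the uncorrected chi-square is what
reproduces the published drug-use p-values 0.023 and 0.040 from their 2×2
counts; the corrected version does not). Two-group continuous contrasts use
Student's t when a Shapiro–Wilk check (alpha = 0.05) passes in both groups,
Mann–Whitney U otherwise; paired contrasts use the same rule on the
differences. Phase trends across early/middle/late use the Friedman test by
default (robust for skewed spectral powers; scipy's asymptotic p, which the
tests verify against a within-subject permutation oracle to 0.05), with
one-way repeated-measures ANOVA behind a flag. No multiplicity adjustment
is applied across descriptive rows.

## Synthetic-data generator

**Tachograms.** Beat times are iterated through an instantaneous RR
function (integral-pulse-frequency-modulation style):
`t_{k+1} = t_k + RR(t_k)/1000` with

    RR(t) = base_rr · traj_base(t)
            + Σ_band amp_band · traj_band(t) · sin(2π f_band t + φ_band)
            + N(0, noise_sd),

one sinusoid per band (VLF/LF/HF) plus white beat-scale noise. Per-phase
trajectory multipliers (early, middle, late) are interpolated
piecewise-linearly between anchors at the midpoints of the session thirds;
with the default anchors the three 10-minute measurement windows of a
240-minute session sit on the flat early region, the middle anchor, and the
flat late region, so a band's true phase delta has the closed form
`(amp·m_mid)²/2 − (amp·m_early)²/2`. Generation is fully deterministic
under the seed; a configuration whose RR trajectory falls to ≤ 50 ms (a
floor below any physiologic interval — without it a zero-crossing
trajectory stalls in ever-shorter beats) is rejected with an error.
Ectopic injection shifts a Bernoulli-chosen subset of intervals by a
fractional magnitude that must exceed 0.2 (otherwise the cleaning rule
could not remove them), leaving beat times untouched, and returns the
ground-truth index list.

**Cohorts.** Covariates are drawn per a declarative spec (normal /
Bernoulli / log-normal / constant, with optional physiologic clipping);
counts are NB2 via the gamma–Poisson mixture (exact Poisson below
alpha = 1e-8). Counts are *not* truncated at 12 sessions — the NB
likelihood the fitter assumes is the NB the generator draws — and a warning
is logged if a draw exceeds the month. Default study conditions emulate a
71-patient prevalent-hemodialysis cohort: age ~ N(54.8, 13) y, diabetes
0.62, coronary disease and heart failure 0.127 each, ultrafiltration
~ N(2.83, 1.10) kg, iPTH log-normal with median ≈ 230 pg/mL and the
published-style IQR spread, antihypertensive prevalences 0.69/0.58/0.49.
True clinical rate ratios follow published adjusted estimates (e.g.
UFR 1.67/kg, age 1.34/10 y, iPTH 0.81/100 pg/mL); the HRV link uses
protective delta effects (HF 0.87 and TP 0.89 per 100 ms²). The dispersion
default is alpha = 1.5, giving a realistic ~55–60% of patients with zero
events at the target rate. The intercept is not a free parameter: it is
calibrated by fixed-seed Monte Carlo so the marginal mean count is 1.2 per
patient-month (≈ 10% of 12 sessions). Because exp(eta) is right-skewed, a
typical 71-patient realisation lands somewhat below the 10% expectation —
the calibration fixes the mean, not the median.

Per-patient tachogram profiles draw base RR ~ N(850, 60) ms (clipped to
650–1150), band amplitudes log-normal around 18–22 ms (clipped to 2–60 ms),
band frequencies uniform within each band, middle-phase multipliers
log-normal around 1.25 and late multipliers around 1.0 (both clipped to
0.5–2.0), and beat noise of 15 ms. The clips are not cosmetic: amplitudes
large enough to swing successive RRs past 20% would be systematically
deleted by the ectopic filter, corrupting the delta ground truth (measured
deltas track the analytic truth with r > 0.95 under the defaults). Segment
SDNN under these defaults is ~25–35 ms and total power a few hundred ms² —
the low-HRV regime typical of dialysis patients.

**What the generator does not emulate.** No baroreflex or blood-pressure
dynamics (IDH counts are linked to HRV only through the regression), no
respiration or frequency drift within a band, no missing or truncated
recordings, no arrhythmias beyond the injected single-beat ectopics, and
covariates are drawn independently (no diabetes–age correlation, say).
Passing tests therefore certify the *pipeline arithmetic* under known
ground truth, not clinical performance on real recordings.

## Problem sizes in the test suite

Parameter recovery uses 200 simulated cohorts of n = 500 (bias within 3
Monte-Carlo SEs, 95% CI coverage required in [0.90, 0.99]); the
Poisson-limit check uses n = 2000 at 1e-3; DeLong calibration uses 2000
null replicates at n = 200; the end-to-end comparison runs 100 seeded
71-patient studies through tachogram generation, feature extraction and the
model search (two added terms), requiring the HRV-augmented model to beat
the basic model's AUC in a majority. Filter idempotence is checked on 1000
random series.

## Known limitations

- In-sample AUC is the ranking criterion, as in the emulated analysis; no
  cross-validation or optimism correction is attempted, so the absolute
  AUCs of the search winner are optimistic at n = 71.
- Wald inference near the alpha → 0 boundary is approximate; the
  pseudo-inverse fallback flags but does not repair a singular information.
- The Friedman p is asymptotic; at very small n an exact permutation test
  would differ.
- VLF at 64-s windows is resolution-limited (see above); VLF values should
  be compared only within this pipeline, not against long-window VLF.
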