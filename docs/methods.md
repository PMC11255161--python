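# Methods

This note documents the models, numerical choices and known limitations
of the package.  Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Dose model

Absorbed dose is self-dose only, in the sphere-model local-deposition
approximation: the mean electron energy emitted per decay of ¹⁷⁷Lu
(β⁻ + conversion + Auger, default Ē_e = 147.9 keV; ICRP 107) is absorbed
entirely within the source region, so

    S(m) = 3.6×10⁹ decays/(MBq·h) × Ē_e / m  →  85.31 mGy/(MBq·h) at m = 1 g,

scaling as 1/m.  For ¹⁷⁷Lu this is accurate to a few percent for
organ-sized masses because the electron range (≲2 mm) is small and the
photon yield is low.  An optional `(mass, fraction)` table adds photon
self-absorption as a multiplicative `1 + f(m)` term (log–log
interpolated); it is off by default since the electron term dominates and
no default table is bundled.  Cross-dose between regions, voxel dosimetry
and bone-marrow dosimetry are out of scope.

Kidneys are treated as one paired region of combined mass with the same
mass-scaled factor as spheres; salivary glands use ICRP reference masses
(parotid 25.0 g, submandibular 12.5 g); lesion masses come from volumes
and kind densities (1.06 kidney, 1.03 soft tissue, 1.92 bone, g/cm³).
Units package-wide: hours, MBq, MBq·h, grams, mGy, mGy/MBq; cumulative
doses in Gy.

## TAC fitting and TIA

The reference cascade mirrors standard dosimetry-suite behaviour:

1. If the first sample lies below the second and ≥4 points exist, try the
   uptake bi-exponential `A₀(e^(−λ_eff t) − e^(−λ_up t))`, initialised
   from a mono-exponential fit of the post-peak points and a 1 h uptake
   half-life; rejected if the rates fail to separate (λ_up/λ_eff < 1.05).
2. Otherwise fit `A₀e^(−λt)` to all points (monotone TACs) or from the
   peak onward; log-linear initialisation, nonlinear least squares on
   untransformed activities (log-linear exactly for 2 points).
3. If fitting fails or the residual RMS exceeds 20% of the peak activity,
   integrate by trapezoids — linear rise from (0, 0) to the first sample,
   trapezoid rule between samples, analytic tail `A_last/λ_tail` from a
   mono-exponential through the last 3 points (2 if the last three are
   not monotone decreasing).

λ is bounded to effective half-lives between 0.5 and 1000 h; a fit pinned
at a bound is flagged, not discarded.  Fits are unweighted; whether to
weight and whether to start integration at injection or at the first scan
are the two conventions most suites differ on, and both are fixed here
(unweighted; integration from t = 0 with the triangle rise) and exposed
in code.  Analytic TIA agrees with adaptive quadrature to <0.1% (tested
on 1000 random kinetics); at 5% measurement noise the fitted T_eff is
unbiased to <1% with ~5% median absolute error at the 4-point schedule.

## Synthetic cohort

The generator works backwards from population summary statistics, which
makes round-trip validation exact in expectation: per patient, cycle and
region it draws a target normalized dose and effective half-life, inverts
the forward map (TIA = D̃·A_inj/S(m), A₀ = TIA·λ) and simulates
measurements with i.i.d. multiplicative log-normal noise (mean 1, CV 5%
by default).

Default study conditions: 16 patients × 4 cycles; injected activity
truncated-normal 6200 ± 500 MBq on [5000, 6700]; scans at 2/24/48 h plus
a last time point in {72, 96, 120, 144, 168} h with weights
(0.125, 0.15, 0.2, 0.225, 0.3) → mean 130.2 h, drawn once per patient
and redrawn per cycle with probability 0.25 (the last scan varies mainly
between patients, only partly within).  Organ targets are per-cycle means
and between-patient CVs (kidneys 0.67/0.73/0.75/0.67 mGy/MBq, T_eff
39.3/38.0/36.3/36.7 h; parotid and submandibular analogous); lesions are
split into bone (70; 2.91 mGy/MBq, T_eff 55.5 h) and soft tissue (19
nodes + 1 local recurrence; 7.18 mGy/MBq, T_eff 52.2 h) whose weighted
cycle-1 mean is 3.86 mGy/MBq, with per-cycle uptake factors
1.00/0.61/0.53/0.52 and constant T_eff targets.  Lesion dropout removes
randomly chosen lesions to exact per-cycle counts 90/87/79/67 (scaled
proportionally for other totals), ≤10 lesions per patient.

Between-patient variability is realised through one standard-normal
effect per region and quantity, shared across cycles and scaled to each
cycle's log-normal CV, so per-cycle means and CVs match their configured
rows while a patient keeps a consistent rank.  Inter-cycle variability is
an additional mean-1 log-normal jitter (CV 0.10 by default) on amplitude,
clearance and — when the bi-exponential lesion model is enabled — uptake
rate.  The jitter CV is a free knob: only between-patient spread is
published, so the inter-cycle correlation cannot be inferred from the
tables.

Organs and (by default) lesions are mono-exponential: at the 2/24/48/last
schedule the uptake phase is essentially over by the first scan, and a
3-parameter bi-exponential is not identifiable from one pre-peak point —
enabling `lesion_model="uptake_biexp"` (uptake half-life default 1 h)
biases fitted lesion T_eff upward by ~15% at 5% noise, which is a
property of the schedule, not of the fitter.

What the generator does **not** emulate: image formation (partial volume,
segmentation, count statistics), variable uptake-phase kinetics between
cycles, activity-dependent noise, inter-lesion correlation within a
patient, and any tumor-sink coupling between tumor burden and organ
uptake.  Passing round-trip tests therefore demonstrate the correctness
and calibration of the analysis chain, not clinical performance on real
scans.

## Simplified methods

SM1 rescales the cycle-1 analytic TIA by `measured/Â₁(t*)` — equivalent
to rescaling the whole fitted curve, and equivalent for mono-exponentials
to re-fitting with the cycle-1 half-life.  For the 72–168 h label the
observation time is the cycle's own last scan.  A trapezoid-tail cycle-1
fit is evaluated through its tail mono-exponential with a logged warning.
SM2/SM3 are exact closed forms; they refuse lesion regions because
declining tumor uptake violates their constancy assumption, and when
totalling over 4 cycles the cycles they extrapolate *from* (1, or 1–2)
carry reference-method values.

A structural note on single-time-point error: for mono-exponential
kinetics the SM1-vs-RM relative error is ≈ x·(1 − λ₁t) with
x = ln(λ_i/λ₁), so it vanishes near t = 1/λ₁ (≈56 h for organs, ≈79 h
for lesions) and grows linearly on both sides.  In the synthetic cohort
this puts the best organ time point at 24–48 h — matching clinical
experience — and makes the 72–168 h point (mean 130 h) slightly *worse*
than 2–4 h for lesions, whereas real studies find late imaging best for
tumors.  The discrepancy is informative: the clinical early-time-point
penalty comes from variable uptake-phase kinetics that a terminal-phase
model cannot carry (see the limitation above), so late-TP superiority for
tumors should not be expected from this generator's defaults.

## Agreement statistics

Percent differences default to the reference-method denominator (the
Bland–Altman pair-mean denominator is available); bias is their mean,
limits of agreement bias ± 1.96 × sample SD (ddof 1); RMSE is computed in
dose units over the same pairs.  Lesions are compared both individually
and as per-patient means.  The between-cycle test is a permutation test:
statistic = variance of cycle means of per-patient values, null =
permuting cycle labels within patients (missing cells stay with their
patient), p with the +1 correction; it is a deliberately simple stand-in
for a repeated-measures mixed model and its p-values are its own.  Its
type-I error at nominal 0.05 is verified ≤0.07 over 500 null simulations.
Note that it will legitimately reject for organs whose configured
per-cycle targets differ (the default kidney rows do, slightly).

## Problem sizes and determinism

All randomness flows from a single seed (per-replicate seeds derived via
a seed sequence, kept below 2³¹).  Seed-replicated summaries use 60
replicates of the default cohort (~1–2 min on one CPU), which puts the
Monte-Carlo standard error of cohort-mean organ doses near 1.2–1.5% —
small against the ~±5% bands used in validation; ordering checks for
SM2/SM3 pool 100 organ-only replicates.  Re-running any stage with the
same inputs and seed reproduces outputs byte-identically.
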