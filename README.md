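# lutadose

Internal dosimetry for ¹⁷⁷Lu radioligand therapy (Lu-177 PSMA), built for
method research at desk scale: a reference multi-time-point dosimetry
pipeline, the simplified estimators used to shortcut it in later therapy
cycles, the agreement statistics that compare them, and a synthetic
virtual-patient cohort generator so that every result is reproducible
without patient data.

## The problem

Patients with metastatic castration-resistant prostate cancer receive
several cycles of a ¹⁷⁷Lu-labelled PSMA ligand (~6.2 GBq per cycle).
Safety depends on the absorbed dose to the kidneys and salivary glands
(proposed limits 28–40 Gy and 35 Gy cumulative), efficacy on the dose to
tumor lesions.  Full dosimetry needs four quantitative SPECT/CT scans per
cycle (≈2, 24, 48 and 72–168 h post-injection); the clinical question is
how much accuracy is lost when later cycles use only a single scan or no
scan at all.

## The methods

**Reference method (RM).**  For each source region *r* with measured
time–activity curve A(t), the time-integrated activity is the analytic
integral of a fitted model,

- mono-exponential  A(t) = A₀·e^(−λ_eff·t),  TIA = A₀/λ_eff,
- uptake bi-exponential  A(t) = A₀·(e^(−λ_eff·t) − e^(−λ_up·t)),
  TIA = A₀·(1/λ_eff − 1/λ_up),

with a trapezoid-plus-monoexponential-tail fallback when no exponential
fits.  Absorbed dose uses the sphere-model self-dose factor with local
electron deposition, D = TIA · S(m), S(m) = N·Ē_e/m (N decays per MBq·h,
Ē_e = 147.9 keV per decay for ¹⁷⁷Lu), and is reported normalized to the
injected activity, D̃ = D/A_inj in mGy/MBq, with T_eff = ln2/λ_eff.

**Simplified methods.**  For cycle i ≥ 2:

- SM1: assume cycle-1 kinetics, rescale the cycle-1 fitted curve through
  one measured point:  TIA_i = [A_i(t*)/Â₁(t*)] · TIA₁.
- SM2: D_i = (D₁/A₁)·A_i.
- SM3: D_i = ½(D₁/A₁ + D₂/A₂)·A_i  (organs only — tumor uptake declines
  with treatment response, so pure activity scaling is invalid for
  lesions).

**Agreement.**  Bland–Altman percent bias with 1.96·SD limits of
agreement, RMSE = √(Σ(d_SM − d_RM)²/n), per-cycle percent deviations, and
a within-patient permutation test for a between-cycle effect.

**Synthetic cohort.**  The generator inverts the forward dose map: it
draws per-patient/cycle targets (normalized dose, T_eff) from log-normal
distributions around published per-cycle population values — kidneys
≈0.71 mGy/MBq and T_eff ≈39 h, parotid ≈0.28, submandibular ≈0.22
mGy/MBq, 90 tumor lesions (70 bone / 19 node / 1 local recurrence) with
declining uptake 3.86→2.01 mGy/MBq and T_eff ≈55 h, dropout 90/87/79/67 —
solves for the true kinetics, and simulates noisy measurements at the
imaging schedule.  Running RM on the cohort therefore recovers the
configured statistics, which is the package's main validation loop.

## Worked example

```python
from lutadose import CohortConfig, generate_cohort, run_reference_dosimetry
from lutadose.dose import summarize_records

cohort = generate_cohort(CohortConfig(seed=42))
records = run_reference_dosimetry(cohort)
kid = records[records.kind == "kidney"]
print(f"kidney normalized dose: {kid.norm_dose_mGy_per_MBq.mean():.3f} "
      f"+/- {kid.norm_dose_mGy_per_MBq.std():.3f} mGy/MBq")
print(f"kidney T_eff, cycle 1: "
      f"{kid[kid.cycle == 1].t_eff_h.mean():.1f} h")
```

prints

```
kidney normalized dose: 0.755 +/- 0.344 mGy/MBq
kidney T_eff, cycle 1: 35.7 h
```

i.e. this single 16-patient realization recovers a cohort-mean kidney
dose per unit injected activity of ≈0.75 mGy/MBq (≈4.7 Gy per 6.2 GBq
cycle) and a cycle-1 effective half-life of ≈36 h — within one
between-patient standard error of the configured population values (0.71
mGy/MBq, 39.3 h), which seed-replicated runs recover to within a couple
of percent.  The `examples/` directory holds one short
script per capability (cohort simulation, reference dosimetry, simplified
methods, agreement statistics); a thin CLI (`lutadose simulate|run|
compare|report`) wraps the same functions for shell use.

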