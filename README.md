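# hrvidh — predicting intradialytic hypotension from heart-rate variability

Intradialytic hypotension (IDH) — a symptomatic blood-pressure drop during a
hemodialysis session — is a common, morbid complication driven in part by
autonomic dysfunction: patients whose sympathetic response to ultrafiltration
is blunted tolerate volume removal poorly. Heart-rate variability (HRV)
measured *during* a dialysis session is a non-invasive window on that
autonomic response, and the within-session *change* of HRV between the early
and middle phases of dialysis turns out to carry prognostic information about
how many IDH events a patient will suffer in the following month.

`hrvidh` is a tested, reusable implementation of that analysis chain for
biostatisticians and nephrology researchers:

1. **RR-interval preprocessing** — tachograms (beat time, RR interval) are
   cleaned with the 20% ectopic rule (an RR interval deviating more than 20%
   from the most recent retained interval is discarded), then cut into
   forty-eight 5-minute segments of a 240-minute session. Three analysis
   phases take two consecutive segments each: early (1–2), middle (24–25),
   late (47–48).
2. **HRV features** — per segment, the nine standard parameters: mean HR,
   mean RRI, SDNN, RMSSD and the Welch-periodogram band powers VLF
   (0.003–0.04 Hz), LF (0.04–0.15 Hz), HF (0.15–0.40 Hz), TP, and LF/HF
   (4 Hz linear-interpolation resampling, 64-s Hann windows, 75% overlap).
   Phase values average the two segments; **delta features** are
   middle − early.
3. **Count models** — monthly IDH counts `y_i` are over-dispersed, so they
   are modelled by NB2 negative-binomial regression with log link:
   `y_i ~ NB(mu_i, alpha)`, `mu_i = exp(x_i' beta)`, `Var = mu + alpha mu^2`,
   fitted by maximum likelihood. A univariate screen (Wald p < 0.10, with
   clinically established factors force-included) feeds a multivariate
   "basic" clinical model (diabetes, coronary disease, heart failure,
   age/10 y, ultrafiltration rate per kg, iPTH/100 pg/mL, antihypertensive
   use); delta features are then added exhaustively under VIF (> 10) and
   mutual-correlation (|r| > 0.8) exclusion.
4. **Model comparison** — each model's linear predictor `x' beta` is scored
   against the binary outcome "any IDH event" by the midrank Mann–Whitney
   AUC; the basic and best augmented models are compared with DeLong's
   paired AUC test.
5. **Synthetic data** — because no patient-level data are public, a
   first-class simulator generates tachograms with band-limited sinusoidal
   autonomic modulation (integral-pulse-frequency-modulation style),
   injectable ectopic beats, and cohorts whose IDH counts follow a known
   NB2 model linked to the patients' true HRV dynamics — so every stage is
   testable against ground truth.

## Worked example

```python
import hrvidh.pipeline as pl
from hrvidh import StudyConfig, simulate_study

study = simulate_study(StudyConfig(), seed=1)   # 71 patients, 12 sessions/mo
feats = pl.study_features(study)                # tachogram -> delta features
result = pl.analyze(study.cohort, feats)

print(f"events: {study.cohort.idh_count.sum()} "
      f"({100 * study.cohort.idh_count.sum() / (71 * 12):.1f}% of sessions)")
print(f"basic model AUC {result.basic_auc:.3f}, "
      f"best HRV-augmented AUC {result.best_auc:.3f} "
      f"(added {'+'.join(result.search.best.added)})")
print(f"DeLong p = {result.comparison.p:.3f}")
```

prints

```
events: 56 (6.6% of sessions)
basic model AUC 0.824, best HRV-augmented AUC 0.866 (added d_hr+d_tp)
DeLong p = 0.311
```

The simulated month produced 56 IDH events across 852 sessions; the clinical
covariates alone discriminate future IDH patients with AUC 0.824, and adding
the heart-rate and total-power deltas raises it to 0.866. At n = 71 a single
cohort rarely certifies the improvement (DeLong p = 0.311 here); across
repeated simulated cohorts the augmented model wins a clear majority of the
time, which is the property the test suite checks.

The same chain runs from the shell:

```sh
hrvidh run-all --seed 1 --out results/demo
```

writing tachograms, the cohort table, feature/univariate/model CSVs, ROC
coordinates and a DeLong comparison report.

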