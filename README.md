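# bdscreen

Automated screening of neurocritical-care patients for impending brain
death, together with the machinery to evaluate such a screen as a diagnostic
test and a synthetic cohort generator for end-to-end testing without patient
data.

## Who this is for

Intensive-care and organ-donation research groups evaluating clinical
decision-support rules over electronic medical record (EMR) data streams:
the package reimplements a cyclic screening rule used on neuro-ICUs, scores
its alerts against a reference-standard outcome, and reports the standard
diagnostic-accuracy estimates with the confidence-interval methods used for
screening tests of rare conditions.

## The rule and the statistics

Every 12 hours (wall-clock ticks at 06:00 and 18:00) the engine inspects a
patient's most recently charted observations and raises an alert when two
findings coincide:

* **coma** — latest Richmond Agitation Sedation Scale (RASS) score of −4 or
  −5, *or* latest Glasgow Coma Scale (GCS) score of 3–6, and
* **bilaterally absent pupillary light reflexes** — both eyes charted
  `absent`; an undocumented or `not_assessable` pupil on either side never
  fires.

Charted values count only within a staleness window (12 h for bedside neuro
checks, 24 h for labs and pressures). Each notification carries a
demographic snapshot and ancillary flags: controlled ventilation without
spontaneous breathing, ICP > 50 mmHg, CPP < 20 mmHg, serum sodium
> 160 mmol/L or a swing > 10 mmol/L within 24 h, and any CPR event.

Patient-level screening results against the reference standard give the
confusion matrix (TP, FP, FN, TN) and from it

* sensitivity TP/(TP+FN), specificity TN/(TN+FP), overall accuracy
  (TP+TN)/N — exact Clopper–Pearson or Wilson score intervals;
* PPV and NPV via Bayes' theorem at the cohort prevalence — delta-method
  intervals on the logit scale (Mercaldo-style), the appropriate method for
  prevalence-dependent predictive values;
* subgroup analyses (restricting the cohort, or redefining positivity, e.g.
  to repeatedly detected patients) and the 2×2 odds ratio with Wald CI for
  exposure–screening associations.

Degenerate estimates (zero denominators, boundary variances) are reported as
undefined, never as 0 or 1 with fabricated bounds.

## Worked example

Simulate a year of a 12-bed neuro-ICU (414 admissions), screen it, evaluate:

```sh
bdscreen simulate --n 414 --seed 7 --out-dir cohort
bdscreen screen   --events cohort/events.jsonl --patients cohort/patients.csv \
                  --out notifications.jsonl
bdscreen evaluate --notifications notifications.jsonl \
                  --patients cohort/patients.csv --out metrics.json
bdscreen report metrics.json
```

prints

```
Accuracy estimates, % (95% CI)
Sensitivity                 100.0 (47.8-100.0)
Specificity                 89.5 (86.1-92.3)
Positive predictive value   10.4 (8.1-13.4)
Negative predictive value   100.0
Overall accuracy            89.6 (86.3-92.4)
TP 5  FP 43  FN 0  TN 366  (N = 414)
```

Five of the 414 synthetic patients were designed to progress to brain death
and all five were detected (sensitivity 100%, but note the wide exact CI at
n = 5 — brain death is rare). Forty-three sedation-driven transient episodes
produced false alerts, giving a specificity near the generative value
1 − 46/406 ≈ 88.7%. The PPV of ~10% reflects the ~1.9% prevalence, not a
fault of the rule; NPV is 100% with no false negatives and is printed
without an interval because its logit variance is undefined at perfect
sensitivity. `metrics.json` additionally records the analgosedation odds
ratio (7.6, 95% CI 3.0–19.7 in this run — sedated patients mimic the
screening pattern) and notification bookkeeping (48 screen-positive
patients, 191 notifications of which 143 repeats, all gaps 12 h).

The same analyses are available as a library (`bdscreen.run_screening`,
`bdscreen.diagnostic_metrics`, `bdscreen.simulate_cohort`, ...); see
`docs/methods.md` for the model and its assumptions.

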