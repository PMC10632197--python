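# Methods

## Screening model

The engine models an EMR-integrated screen that runs at fixed wall-clock
anchor times (default 06:00 and 18:00, i.e. a 12-h cadence) over each
admission. A tick is *positive* iff the coma criterion and the pupil
criterion hold simultaneously:

* coma: latest RASS ∈ {−4, −5} **or** latest GCS ∈ [3, 6];
* pupils: latest pupillary light reflex charted `absent` in **both** eyes.

Design choices the deployed-system description leaves open, resolved here:

* **Fixed wall-clock ticks**, not admission-relative ones: screening systems
  poll the EMR on a site schedule, and alerts at "day 4, 6 a.m." style times
  imply anchored ticks. Ticks run strictly after admission up to discharge,
  and stop at the formal brain-death determination time when one exists, so
  post-mortem charting cannot generate alerts.
* **Staleness**: an observation counts at a tick if charted within 12 h
  (RASS, GCS, pupils — critical-care monitoring guidelines make bedside
  neuro checks at least this frequent) or 24 h (ventilation status, ICP,
  CPP, sodium). Both are configurable per kind; missing or expired data
  never fires the rule.
* **Missing-data asymmetry**: an undocumented or `not_assessable` pupil on
  either side fails the pupil criterion. A screen for a catastrophic
  condition must not alert on absence of documentation.
* **Boundary strictness** for ancillary flags: ICP *above* 50 mmHg and
  sodium *above* 160 mmol/L are strict `>`; CPP *below* 20 mmHg strict `<`;
  the GCS coma band is the closed interval [3, 6]. The 24-h sodium-swing
  flag uses max − min over the trailing window and requires ≥ 2 values —
  the most sensitive deterministic reading of an otherwise unspecified
  pairing rule.
* **Repeats**: every notification after a patient's first is a repeat; there
  is no episode concept. A patient is *screen-positive* iff they have ≥ 1
  notification during the admission.

## Accuracy statistics

Evaluation is patient-level: screen-positivity versus the reference-standard
outcome (confirmed brain death) gives TP/FP/FN/TN. Sensitivity, specificity
and overall accuracy are binomial proportions; both the exact
Clopper–Pearson interval (Beta quantiles; conservative coverage) and the
Wilson score interval are implemented, with Clopper–Pearson the default:
for screening evaluations of rare outcomes the exact method's conservatism
at small numerators (e.g. 8/8) is usually wanted, and it is what standard
clinical-statistics packages print for diagnostic-test tables. Every
estimate records the method that produced its bounds.

PPV/NPV are prevalence-dependent, so their intervals come from the
delta-method on the logit scale (Mercaldo-style):

    Var(logit PPV) = (1−se)/(se·n1) + sp/((1−sp)·n0)
    Var(logit NPV) = se/((1−se)·n1) + (1−sp)/(sp·n0)

with n1, n0 the condition-positive/-negative sample sizes. At boundary
operating points (se = 1 for NPV, se = 0 for PPV, sp ∈ {0, 1}) the variance
is undefined and the point is reported without bounds — never with
fabricated ones. Reported percentages use round-half-up at one decimal.

Subgroup analyses support two distinct semantics: a *patient filter*
restricts the cohort (e.g. mechanically ventilated patients), while a
*positivity override* keeps the full cohort but redefines who counts as
screen-positive (e.g. only repeat-detected patients). The
exposure–screening association is the 2×2 sample odds ratio (ad)/(bc) with
the Wald log-scale interval — identical to a bivariate logistic regression
with a single binary predictor; zero cells are flagged rather than
continuity-corrected.

## Synthetic cohort generator

The generator emulates a year of admissions to a 12-bed neurocritical-care
unit. Defaults (all configurable in `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `prevalence_bd` | 0.019 | probability an admission progresses to confirmed brain death |
| `p_false_positive_pattern` | 46/406 | probability a non-brain-death patient exhibits ≥ 1 alert-generating episode |
| `p_repeat_given_positive` | 34/54 | designed false positives with ≥ 2 alerts |
| notification→determination delay | 3.6 ± 3.2 d, truncated ≥ 0.5 d | truncated normal; family chosen for simplicity, only mean/SD being constrained |
| length of stay | 9.1 ± 8.6 d, truncated ≥ 1 d | truncated normal |
| age | 70.8 ± 14.8 y, truncated ≥ 18 | truncated normal; adults only |
| `p_female` | 0.459 | |
| `charting_interval_hours` | 4 ± 1 (jitter) | bedside neuro-check cadence |
| sedation | 0.891 / 0.567 / 7/8 | P(analgosedation) given FP / TN / brain-death class |
| ventilation | 0.87 / 0.35 / 1.0 | P(controlled ventilation) by class; brain-death patients are ventilated by necessity |
| diagnosis mix | 0.701 / 0.128 / 0.082 / 0.031 / rest | ischemic stroke / ICH / seizure / meningoencephalitis / other |

Trajectories by designed class:

* **brain_death** — baseline charting until a random onset 6–48 h after
  admission, then persistent RASS −5 / GCS 3 / bilaterally absent pupils
  until determination. The determination time is anchored at the first tick
  after onset plus the truncated-normal delay, so (a) the simulated
  alert-to-determination delay follows the configured distribution exactly
  and (b) the episode always covers ≥ 1 tick with fresh charting — designed
  sensitivity is 1 by construction.
* **false_positive** — one (or, for repeats, a run of k ≥ 2, k = 2 +
  Poisson(2.5), capped by the stay) consecutive ticks covered by a
  sedation-style episode starting 3 h before the first covered tick, with a
  recovery chart 30 min after the last, so the designed alert count is
  exact: positive findings never linger into the next tick because newer
  baseline charts override them.
* **true_negative** — never bilaterally absent pupils. Sedated true
  negatives chart coma-level RASS/GCS and may have one blunted pupil; since
  both pupils are charted at every neuro check, the latest left/right values
  always come from the same chart and can never combine into a false
  bilateral absence across charts.
* **fn_pattern** (stress mode, off by default, matching a study that
  observed zero false negatives) — a condition-positive patient whose
  positive findings flicker strictly between ticks and are re-charted as
  recovered before the next tick.

Ancillary channels (ventilation, sodium random walk around 140 mmol/L,
occasional ICP/CPP extremes, CPR markers) are generated consistently with
the flag frequencies observed among screen positives; they influence
notification flags only, never positivity.

What the generator does **not** emulate: charting irregularities (real
repeat-notification gaps average above the cadence because charting lapses
break staleness windows; synthetic gaps are exact 12-h multiples), clinical
fluctuation of real sedation episodes (the per-patient notification-count
distribution is not matched beyond its designed structure), competing risks
such as withdrawal of life-sustaining therapy, and any physiology beyond
what the rule reads. Passing end-to-end tests therefore demonstrates that
the engine implements the rule and its bookkeeping exactly and that the
statistics recover generative parameters — not that the screen would attain
these operating characteristics on real EMR data.

## Numerical and testing choices

* Timestamps are timezone-naive at minute resolution (ICU flowsheet
  granularity); event ordering ties break by observation kind.
* Determinism: a cohort is a pure function of `SimulationConfig` and its
  seed (single `numpy` Generator, sequential per patient); the engine log is
  a pure function of records and engine config.
* Problem sizes in the test suite: cohort fixtures of 414 (the study scale)
  and 2000 patients (parameter recovery at 3σ binomial tolerance);
  interval-coverage checks use 3000–4000 Monte-Carlo replicates per (n, p)
  grid point; report-vs-brute-force equivalence uses 100 random cohorts of
  ≤ 200 patients.
* Statistical cross-checks in tests run against independent implementations
  (statsmodels `proportion_confint`, `Table2x2`) and closed forms
  (lower bound (α/2)^(1/n) at x = n); the engine is checked against a
  linear-scan brute-force evaluation of the rule at every tick.
* Known limitation: one published bound (overall-accuracy upper limit)
  differs in the last printed digit from the exact Clopper–Pearson value
  (91.7496% prints as 91.7 directly but 91.8 after intermediate two-decimal
  rounding); the tests accept the half-rounding ambiguity and assert the
  underlying interval.
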