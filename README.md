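# hemolift

**Which intraoperative fluid–norepinephrine regime gives each patient the
best chance of a kidney-injury-free recovery?**

`hemolift` is an observational uplift-modeling pipeline for anesthesia /
perioperative-medicine researchers. It targets the setting of a cystectomy
registry in which two continuous exposures — total intraoperative fluid
balance (TIFB, mL·kg⁻¹·h⁻¹) and norepinephrine rate (NE, µg·kg⁻¹·min⁻¹) —
are dichotomized into a *high-TIFB / low-NE* treatment regime (T = 1)
versus a *low-TIFB / high-NE* control regime (T = 0), and the question is
not "who is at risk of postoperative acute kidney injury (PO-AKI)?" but
"who would benefit from the alternative regime?".

## The method

With the beneficial outcome coded Y = 1 (no PO-AKI), the per-patient
**uplift** is the conditional average treatment effect

u(x) = P(Y = 1 | T = 1, x) − P(Y = 1 | T = 0, x),

estimated with the **two-model (T-learner)** approach: one
outcome-probability model per arm (logistic regression or random forest),
differenced. Because the data are observational, the arms are first
balanced by **inverse probability of treatment weighting** (IPTW): a
logistic propensity model e(x) on a configured adjustment set gives
weights w = T/e + (1 − T)/(1 − e), a super-population replicates each
patient round(w · 10,000) times, and per-arm samples of the original
cohort size form a confounder-balanced pseudo-population of size 2n on
which all models are fit. The Hájek-weighted outcome contrast estimates
the average treatment effect (ATE).

Because individual effects are unobservable, sorting rules are scored on
aggregates: with patients sorted by descending predicted uplift, the
**Qini curve** q(p) = Y_T(p) − Y_C(p)·N_T(p)/N_C(p) accumulates the
incremental benefit over the top fraction p, and its normalized area
(**AUQC**) is compared against a random-sorting benchmark and an
idealized outcome-based ordering. Everything is wrapped in a nested
bootstrap × pseudo-sample × cross-validation scheme (reference layout
500 × 5 × 2 with a 60/40 split; desk-scale default 20 × 2 × 2) reporting
means with percentile 95% intervals.

The clinical registry itself is not public, so the package ships a
synthetic cohort generator with the same statistical structure —
confounded regime assignment (including a calendar-year practice shift),
inversely coupled exposures, and a known ground-truth heterogeneous
effect — making every stage testable end to end. See
[docs/methods.md](docs/methods.md) for the model details and design
choices.

## Worked example

The analysis is organised as numbered drivers over the library:

```bash
python analysis/01_generate_cohort.py     # synthetic registry + baseline table
python analysis/02_treatment_effect.py    # dichotomization, balance, IPTW ATE
python analysis/03_uplift_evaluation.py   # nested bootstrap model evaluation
python analysis/04_offset_sensitivity.py  # sweep of the dichotomization line
```

Step 01 draws the 1,482-patient cohort and prints

```
adverse-outcome incidence 21.7% (95%-CI 19.6-23.8%), mean true uplift 0.035
```

— an adverse-outcome (PO-AKI) rate of 21.7% with its Wald interval, and
the generator's ground-truth mean effect (+3.5 percentage points in favor
of the high-TIFB / low-NE regime). Step 02 dichotomizes at the primary
line (slope 0.02, offset −0.04), yielding arms of 647 (treatment) and 835
(control), and shows that weighting removes the confounding (worst
covariate |SMD| 0.92 → 0.05) while the IPTW ATE estimate of 1.8%
(95%-CI −2.5 to 6.2%) brackets the 3.5% truth that the unadjusted
contrast (7.4%) overstates. Step 03 runs the desk-scale nested
evaluation (80 replicates) and prints

```
AUQC (mean [95%-CI] across replicates):
  idealized benchmark        0.419 [0.390; 0.447]
  uplift random forest       0.055 [0.018; 0.091]
  uplift logistic            0.032 [-0.018; 0.073]
  prediction random forest   0.015 [-0.025; 0.049]
  prediction logistic        -0.001 [-0.033; 0.035]
  random benchmark           0.012 [-0.015; 0.036]
response types (uplift RF): SureThing 83.2%, Persuadable 7.6%,
                            LostCause 1.0%, DoNotDisturb 8.2%
```

— the uplift models sort patients by expected treatment benefit better
than random sorting or a conventional PO-AKI risk model, the forest-based
uplift model leading; most patients are predicted to do well under either
regime (SureThings), with a minority of Persuadables who specifically
benefit from the liberal-fluid regime. Step 04 sweeps the line offset
from −0.12 to 0.08 and reports arm sizes, propensity-overlap support and
the ATE per offset (the near-degenerate top offset leaves 6 control
patients and a uselessly wide interval — visible, not hidden).

A one-command CLI mirrors the drivers:
`hemolift generate`, `hemolift run` (`--full` for the 500 × 5 × 2
reference layout), `hemolift sensitivity`, configured by a single YAML
(`analysis/config/study.yaml`).

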