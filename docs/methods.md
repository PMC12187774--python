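# Methods

`hemolift` implements an observational uplift-modeling workflow for a joint
continuous exposure: which of two hemodynamic regimes — a high total
intraoperative fluid balance (TIFB) with little norepinephrine (NE), or the
converse — gives a given patient the better chance of a recovery free of
postoperative acute kidney injury (PO-AKI). The outcome is coded
benefit-side throughout: `outcome_beneficial = 1` means *no* PO-AKI.

## Exposure dichotomization

TIFB (mL·kg⁻¹·h⁻¹) and NE rate (µg·kg⁻¹·min⁻¹) are inversely related in
practice, so the joint exposure is dichotomized by a line in the (TIFB, NE)
plane,

    T = 1  ⇔  NE < offset + slope · TIFB,

with slope 0.02 µg·kg⁻¹·min⁻¹ per mL·kg⁻¹·h⁻¹ and primary offset
−0.04 µg·kg⁻¹·min⁻¹; offsets −0.12 … 0.08 (step 0.04) form the sensitivity
grid. Patients exactly on the line go to control: "high TIFB / low NE" is
read as strict dominance, and the boundary set has measure zero. The test
is monotone in NE and in the offset, which the sensitivity sweep exploits
(treatment-arm size is non-decreasing in the offset).

## Confounding adjustment

Arm assignment is confounded (notably by a calendar-year practice shift
toward restrictive fluids with pre-emptive NE). A main-effects logistic
regression of the arm on a configured adjustment set — default
`year, ckd_stage, heart_disease, hypertension`, a plausible stand-in for a
causal-graph-derived set and deliberately *configuration*, not computation —
yields propensity scores e(x), clipped to [ε, 1−ε] with ε = 0.01 so the
IPTW weights

    w = T/e(x) + (1−T)/(1−e(x))

stay finite. Weight diagnostics use the standardized mean difference with
the unweighted pooled SD in the denominator (|SMD| < 0.1 as the usual
balance yardstick). No truncation or stabilization beyond clipping.

A confounder-balanced pseudo-population of size 2n is built by replicating
each patient `round(w · 10,000)` times (half away from zero) into a per-arm
super-population and drawing n records per arm with replacement. The draw
is implemented as a weighted choice with probabilities proportional to the
integer counts, which is mathematically identical to materializing the
replicated rows and sampling uniformly.

The average treatment effect uses the Hájek estimator (per-arm normalized
weighted outcome means), bounded in [−1, 1] for binary outcomes, with a
percentile bootstrap over patients in which the propensity model is refit
per replicate.

## Uplift models and evaluation

The two-model (T-learner) estimator fits one outcome-probability learner
per arm and scores u(x) = P(Y=1|T=1,x) − P(Y=1|T=0,x). Learners: logistic
regression (standardized features, light L2, C = 100 — a numerical guard on
quasi-separated resamples, never the estimand) and a random forest
(vote-fraction probabilities, √p feature subsampling, unlimited depth;
500 trees by design default, 100 in the desk-scale experiment profile).
The traditional comparator is a single pooled outcome model *without* the
arm indicator, sorting patients purely by predicted beneficial-outcome
probability. Dichotomizing (p_treat, p_control) strictly at 0.5 yields the
four response types (SureThing, LostCause, Persuadable, DoNotDisturb).

Sorting rules are scored on aggregates. For the head of the first
⌈p·N⌉ patients sorted by descending score,

    q(p) = Y_T(p) − Y_C(p) · N_T(p)/N_C(p),

with the control term set to 0 when the head contains no controls (the only
finite continuous completion at small p). The curve is normalized by the
total treated count N_T — the source analysis does not state its
normalization constant, and this
choice leaves cross-model comparisons on identical data unaffected — and
integrated by trapezoid from the origin over the dense grid
p = 0.01 … 1.00 to give the AUQC. Ties are broken once per evaluation by a
seeded random permutation.

Two benchmarks bracket any model: the random-sorting AUQC (expectation
q_norm(1)/2, estimated over seeded random orderings with a percentile CI)
and an idealized ordering built from observed outcomes — treated successes,
then control failures, then treated failures, then control successes.
Within the first conceptual block, treated successes precede control
failures deliberately: any ordering with all treated successes first and
all control successes last attains the exhaustive maximum of the AUQC under
the zero-control-head convention, whereas interleaving does not (verified
against an 8!-ordering search in the tests). A stricter reading in which
only treated successes lead is available via
`optimal_ordering(mode="treated_successes_first")`. Note the idealized
benchmark chases observed Bernoulli noise, so it sits far above what any
covariate-based sorter — including an oracle scoring by the true uplift —
can reach.

The uplift-by-decile summary bins patients by deciles of the pooled score
distribution (bin 1 = top 0–10%) and reports the observed treated-minus-
control outcome difference per bin; bins missing an arm are NaN, never
zero. AUROC is the Mann–Whitney rank statistic (ties ½); proportion CIs are
Wald, which reproduces the published 19.6–23.8% interval for 321/1,482
exactly at one decimal.

## Nested evaluation scheme

The reference layout: 500 bootstrap resamples of the cohort (propensity and
weights refit per resample) × 5 pseudo-population samples × 2
cross-validation splits, training on 60% and evaluating AUQC / AUROC /
response types on the held-out 40%, with random and idealized benchmarks on
the same evaluation sets; metrics are aggregated as the mean with
percentile 2.5/97.5 intervals across all replicates (the per-bootstrap
Hájek ATE is aggregated the same way). Every replicate (b, s, c) derives
its random state as a pure function of the master seed and its coordinates,
so results are independent of execution order and byte-reproducible.

Cross-validation folds are stratified by (arm, outcome) **and grouped by
source patient**: the bootstrap and the pseudo-population both replicate
patients, and a record-level split would place copies of one patient on
both sides of the train/evaluation boundary. That leakage lets a
high-capacity learner score its own training patients — on a zero-effect
cohort it inflates the forest uplift AUQC from ≈ random to ≈ 0.23 — so all
copies of a patient stay in one fold. This is the package's own design
choice where the scheme's description says only "random cross-validation".

The default profile is desk-scale, 20 × 2 × 2 with 100-tree forests
(≈ 1 minute per run on one CPU); `ExperimentConfig.full()` (CLI `--full`)
restores 500 × 5 × 2 with 500 trees. Replicates that cannot complete (a
single-class arm in a fold, a separated propensity fit) are skipped and
logged with their coordinates; a run aborts if more than 5% fail.

## Synthetic cohort generator

The clinical registry behind the analysis is not public, so the generator
emulates its structure with a known ground truth: 1,482 patients;
covariates matching the published marginal summaries (age, BMI, ASA class,
Charlson index, CKD stage, COPD, heart disease, hypertension, statins,
procedure year uniform over 2000–2020.5); a latent regime propensity
logistic in standardized covariates (intercept −0.28 reproducing the
published 647/835 arm split; year −0.9 encoding the practice shift; CKD,
heart disease and hypertension loading negatively so sicker patients
receive the restrictive regime); exposures drawn on the corresponding side
of the primary line (treatment: shifted log-normal TIFB with median
≈ 5.2 mL·kg⁻¹·h⁻¹ and 60% exact-zero NE; control: log-normal TIFB with
median ≈ 1.74, NE above the line with a negative within-arm coupling of
−0.02 to TIFB plus noise, SD 0.015). Potential outcomes are Bernoulli with
logistic models on standardized covariates; a shared per-patient uniform
couples y₀ and y₁ (rank preserving), so a zero effect yields identical
potential outcomes. The outcome intercept α is calibrated by bisection
(tolerance 0.005, hard failure beyond 0.02) so the marginal beneficial rate
hits its target, 0.783 by default.

Coefficient maps accept an `intercept` key and interaction keys `"a:b"`
(products of standardized covariates). The default heterogeneous-effect
profile places most of the CATE variance in two such interactions
(heart disease × hypertension 2.6, CKD stage × COPD 1.6, intercept 1.9,
moderate main effects). Two considerations fix this shape. First,
standardized-product interactions of independent covariates are orthogonal
to the main effects, so a main-effects logistic T-learner cannot represent
that component while a forest can — the structural reason a forest-based
uplift model can outperform a linear one, as observed in the source
setting. Second, pushing the effect intercept high enough to force a mean
uplift near 0.12 saturates p₁ toward 1, and the uplift then collapses onto
(one minus) baseline risk, which the linear learner captures perfectly;
the default therefore settles at a true ATE ≈ 0.04, inside the 2.5–12.4%
range the source analysis itself reports across dichotomization choices.
An additive profile (`effect="linear"`, mean uplift ≈ 0.12) serves the
well-specified recovery checks, and `effect="null"` zeroes the effect.

What the generator does **not** emulate: the real joint covariate
distribution (marginals only, independent draws), intraoperative time
courses and sequential fluid decisions, KDIGO staging from creatinine
trajectories, and unmeasured confounding (the propensity model is correctly
specified by construction). Passing tests therefore demonstrate that the
pipeline recovers known truths under its own assumptions — not that those
assumptions hold in registry data.

## Numerical and degenerate-input choices

- Propensity clipping ε = 0.01; separation or non-convergence raises with
  advice rather than returning degenerate scores.
- Replication rounding half away from zero (deterministic,
  platform-stable).
- Bisection for α over [−20, 20], 200 iterations.
- Sorting ties: one seeded random permutation per evaluation.
- Empty-arm deciles and single-class AUROC folds are NaN/skipped, never
  silently zero; an offset producing an empty arm is flagged in the
  sensitivity table, not fatal.
- Complete-case file reads drop incomplete rows and report the count.

## Problem sizes in tests and scripts

The test-suite and acceptance-script runs use the desk-scale layout
(20 × 2 × 2, 100-tree forests) on the 1,482-patient fixture, n = 5,000
cohorts for recovery/balance checks (10–100 seeds), 2,000 random orderings
for the random-benchmark limit, and exhaustive 8!-ordering search for the
Qini oracle. These sizes were chosen so a full validation pass completes
on a single CPU in well under half an hour while keeping Monte-Carlo error
far below every asserted margin.

## Known limitations

- Only the two-model estimator; no X-/R-/DR-learners, no calibration
  post-processing.
- The adjustment set is user configuration; no causal-graph search.
- No variance-reduced Qini estimators and no decision-curve analysis.
- The idealized benchmark is outcome-noise-chasing by construction and
  should be read as an upper bound, not an attainable target.
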