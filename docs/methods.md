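# Methods

## Scope and design

`runinmeta` treats trials as the units of analysis and asks how a design
feature — the run-in period — relates to the magnitude of pooled
drug-versus-placebo effects. The pipeline has four stages: per-trial effect
construction from aggregate data, inverse-variance pooling with
heterogeneity-driven model choice, stratification of pooled effects by
run-in covariates, and meta-regression of total dropout. A patient-level
generator supplies outcome-bearing trial sets, because per-trial outcome
data for the real trial literature were never published; only the design
characteristics of those 35 trials ship with the package.

## Effect sizes

Efficacy uses the standardized mean difference of change scores,

    d = (Δ̄_drug − Δ̄_placebo) / s_pooled,
    Var(d) = (n1 + n2)/(n1 n2) + d² / [2 (n1 + n2)],

with s_pooled the usual two-group pooled SD. Negative d favors the drug.
Cohen's d is the default; Hedges' correction J = 1 − 3/(4(n1+n2−2)−1) is a
flag (`SmdConfig.hedges_correction`) because analyses of this literature do
not consistently state which flavor they used. Binary outcomes use the log
odds ratio with Woolf variance. If any cell of the 2×2 table is zero, 0.5
is added to all four cells and the estimate flagged `continuity_0.5`;
trials with zero events in both arms carry no information about the odds
ratio and are excluded from pooling with a logged reason
(`both_arms_zero_events`).

### SD reconstruction

When a trial reports no SD of change, the SD is recovered in this order of
preference, each route recorded in the estimate's `sd_source`:

1. **from_p** — invert the two-sample test: t* at 1 − p/2 with
   df = n1+n2−2, SE = |Δ̄₁−Δ̄₂|/t*, SD = SE/√(1/n1+1/n2).
2. **from_ci** — SE = (upper − lower)/(2 q), same back-transformation.
3. **from_range** — SD = range/4. The range rule is the only route with a
   heuristic constant; the quarter-range approximation is the common
   choice for samples of the sizes seen here.
4. **imputed** — the unweighted mean of reported SDs from trials with the
   same symptom indication and instrument, per arm role. If that stratum
   is empty the donor pool falls back to instrument-only matching with a
   logged warning; if no instrument match exists at all, the estimate
   fails with an explicit error rather than guessing.

The p/CI routes identify only the *pooled* SD, so that single value is
used for both arms; the reconstruction is then exactly self-consistent
with the SMD's pooled denominator. The t family (df = n1+n2−2) is the
default reference distribution, with a normal option
(`sd_recovery_quantile`), since the software used for the original
analyses is not documented at that level of detail.

Multi-dose or multi-drug arms are pre-combined by
`combine_arms`: n-weighted mean, and a variance that pools within- and
between-arm components exactly as the sample variance of the concatenated
patient-level data — so combining is lossless at the level of first and
second moments.

## Pooling and model selection

Fixed-effect pooling weights by 1/v; random-effects pooling by
1/(v + τ²) with the DerSimonian–Laird moment estimator
τ² = max(0, (Q − df)/C), C = Σw − Σw²/Σw. Heterogeneity is reported as
Cochran's Q and I² = max(0, (Q − df)/Q)·100.

`pool_auto` chooses fixed-effect when I² < 40% and random-effects
otherwise, applied **per analysis cell** (each stratum of each outcome
separately), with the chosen model recorded and flagged in renderings. A
single-trial cell is its own estimate under the fixed model. CIs use
normal quantiles on the pooling scale (no Knapp–Hartung); odds-ratio
pooling is inverse-variance on the log scale rather than Mantel–Haenszel.
These are the classic defaults of general-purpose meta-analysis software;
alternative estimators (REML, Hartung–Knapp, MH) are deliberately out of
scope.

## Stratification and contrasts

Covariates: run-in presence; replacement type among run-in trials, merged
to washout-only versus placebo-or-active-drug (active-drug run-ins are too
rare to stand alone); and duration dichotomized at 7 days, with
missing-duration trials excluded from that covariate only. Class subsets
include combined-class trials in both the conventional and the atypical
analysis, since their haloperidol and atypical arms are informative for
each.

`compare_strata` adds a z-test on the difference of two pooled estimates
(SE = √(SE_a² + SE_b²)). Stratified tables in this literature are usually
presented without a formal between-strata test, so contrast records carry
`in_source_tables=False` and renderers treat them as an extension.

## Dropout meta-regression

The outcome is total dropout in percent of randomized patients,
y = 100·(dropouts_drug + dropouts_placebo)/n. The within-trial variance is
the binomial approximation on the percent scale, v = 100²·p(1−p)/n, with p
clamped away from 0 and 1 by half an event to keep degenerate trials
finite. A residual between-trial variance is estimated by the method of
moments — E[Q_E] = df + τ²·(tr W − tr[(XᵀWX)⁻¹XᵀW²X]), truncated at zero —
and the slope refit by WLS with weights 1/(v + τ²). CIs are normal. The
covariate is the 0/1 stratum indicator with the no-run-in / washout-only /
≤1-week level as reference.

## The synthetic cohort generator

Each patient i carries a latent placebo response r_i ~ N(μ_r, σ_r²) (the
change they would show without active drug; negative = improvement) and an
intolerance indicator with probability π. Observed changes add fresh
N(0, σ_e²) measurement noise; drug assignment adds a constant
`drug_effect`. During a run-in, all patients receive placebo-equivalent
exposure regardless of the replacement label (the label affects metadata
only — a documented simplification, since nothing in aggregate data
distinguishes washout from placebo run-in outcomes mechanistically).
Patients whose run-in improvement, −(r_i + noise), meets the
`placebo_responder_cut` threshold are deselected, as are intolerant
patients when `exclude_intolerant` is set. Survivors are randomized 1:1.

Because the trial-phase change reuses r_i, deselection truncates the
response distribution the arms inherit: the placebo arm's apparent
improvement shrinks toward zero and, more importantly for the SMD, the
change-score SD contracts, so an unchanged additive drug effect divides by
a smaller denominator. Intolerant patients on drug have their odds of
somnolence, EPS, and dropout multiplied by a single factor
(`intolerance_or_multiplier`); mortality odds are left unmultiplied, as
deaths in these short trials are not primarily tolerability-driven.
Dropout odds are equal in both arms at baseline, so the selective-dropout
odds ratio is null by construction except through intolerance.

Default parameters describe a generic dementia-NPS trial on an NPI/CMAI-like
scale: baseline 60 ± 15 points, placebo response −8 ± 10, drug effect −2.5,
noise SD 8 (total change SD ≈ 12.8, SMD ≈ −0.2, matching the small pooled
efficacy this literature reports); placebo-arm risks 7% somnolence / 6% EPS
/ 3% death with odds ratios 3 / 2 / 1.5; 28% base dropout; 10% intolerance
with odds multiplier 5. The default run-in applies mild selection — a
20-point improvement cut (≈ the most responsive sixth) plus intolerance
screening — so post-run-in exclusion fractions fall inside the 0–29% range
the real trials report. Trial sets default to 35 trials of 220 enrolled
patients with a 29/35 run-in share, run-in durations drawn from 2–42 days,
and class/replacement mixes matching the real literature (11:21:3
conventional:atypical:both; 14:13:2 washout:placebo:active among run-in
trials).

Two presets pin down study conditions for calibration experiments:

- `null_scenario` — no drug effect, no run-in anywhere; 20 trials of 200
  patients. Used for CI-coverage checks (observed coverage ≈ 95%).
- `runin_bias_scenario` — a deliberately strong selection scenario: 24
  trials of 400 patients, half with run-in; response heterogeneity
  dominates noise (σ_r = 13, σ_e = 3.5), the improvement cut (11.4 points)
  removes roughly the most responsive 40% of patients, and 25% of patients
  are intolerant with an ×8 odds multiplier. Truncated-normal arithmetic
  gives expected stratum SMDs near −0.34 (run-in) versus −0.24
  (no-run-in) and a roughly halved somnolence OR, large enough that the
  bias direction is detected in ≥95% of modest Monte-Carlo replicates.
  The exclusion fractions here (~55%) exceed anything in the real
  literature; the preset demonstrates the mechanism, it does not claim to
  match history.

Determinism: a trial set is a pure function of its `SimConfig`. The seed
feeds a root `SeedSequence`; per-trial generators are spawned by counter,
so extending a set never perturbs earlier trials. The run-in noise draw is
made on the same stream position whether or not filters are active, so a
run-in design with inactive filters reproduces the no-run-in trial
byte-for-byte at the same seed.

`degrade_reporting` emulates incomplete reporting: selected trials lose
their SDs and gain exactly one surrogate (p, CI, or per-arm range = 4·SD)
computed from the true aggregates with the t reference distribution, or
lose the SD outright to force imputation. Surrogates are exact inverses of
the corresponding recovery routes, which is what makes the round-trip
tests sharp (≈1e-14 observed error).

### What the generator does not emulate

Between-trial heterogeneity of true effects (τ² = 0 by construction unless
parameters are varied externally); informative dropout (changes are
"observed" for all randomized patients, an ITT idealization); washout
rebound or pharmacokinetic carry-over; correlation between placebo
response and intolerance; non-normal symptom scales and floor effects;
multi-dose arms (the generator emits exactly two arms). Passing tests
therefore show that the pipeline recovers the truth *of this model* and
responds to run-in selection in the expected direction — not that the
magnitude of bias in the real literature equals the simulated one.

## Numerical choices and degenerate inputs

- I² clamps to 0 when Q ≤ df or df = 0; τ² truncates at 0.
- p = 1 or a zero mean difference makes SD recovery undefined → explicit
  error rather than an infinite/zero SD.
- Zero pooled SD, empty arm lists, empty effect lists, and constant
  meta-regression covariates all raise typed errors.
- Rounding happens only in renderers (SMD to 3 decimals, OR to 1);
  serialized CSV/JSON values are full precision, and CSV round-trips are
  exact (floats written with `repr`).
- Estimator implementations are plain float arithmetic; they agree with a
  60-digit decimal re-evaluation of the same formulas to ~1e-13 on random
  small instances (see `tests/oracles.py`).

## Test problem sizes

The calibration experiments use 500 replicates of 20-trial null sets and
200 replicates of 24-trial bias sets (a few million simulated patients in
total), sizes chosen to put Monte-Carlo error comfortably inside the
asserted bands while keeping the default suite fast on one CPU.
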