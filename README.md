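# runinmeta

A meta-epidemiological toolkit for studying how **run-in periods** — the
pre-randomization phase in which eligible patients are washed out, given
placebo, or given the study drug, and then some are deselected before
randomization — relate to the estimated efficacy and harms of
antipsychotics for neuropsychiatric symptoms (NPS) in dementia.

It is written for meta-analysts and pharmacoepidemiologists who work from
published aggregate trial data: per-arm sample sizes, mean change on a
symptom instrument (NPI, BEHAVE-AD, CMAI, …) with its SD, and counts of
somnolence, extrapyramidal symptoms (EPS), deaths, and dropouts.

## What it computes

**Per-trial effect sizes.** Efficacy as the standardized mean difference of
change scores, *d* = (Δ̄₁ − Δ̄₂)/s_pooled with
Var(*d*) = (n₁+n₂)/(n₁n₂) + *d*²/2(n₁+n₂) (Hedges' *g* by flag); binary
outcomes as log odds ratios with Woolf variance 1/a + 1/b + 1/c + 1/d and a
0.5 continuity correction for zero cells. When a trial reports no SD it is
reconstructed from the between-group *p*-value or CI (inverting the
two-sample *t* statistic) or from the range (range/4), or imputed as the
mean SD of trials with the same indication and instrument — in that order,
with provenance flags.

**Pooling.** Inverse-variance fixed-effect and DerSimonian–Laird
random-effects models, with Cochran's *Q*, *I*² = max(0, (Q−df)/Q)·100, and
τ² by the moment estimator. The model is chosen per analysis cell:
fixed-effect when *I*² < 40%, otherwise random-effects.

**The meta-epidemiological layer.** Pooled drug-vs-placebo effects
stratified by run-in presence, by what patients received during run-in
(washout only vs placebo/active drug), and by run-in duration (≤ 1 week vs
longer); class subsets (conventional / atypical antipsychotics, with
combined-class trials counting toward both) and a sensitivity exclusion of
combined-class trials; selective-dropout odds ratios; and random-effects
meta-regression of total dropout (percent) on run-in covariates.

**A patient-level trial simulator.** Each simulated patient has a latent
placebo response and an intolerance indicator; a run-in phase deselects
strong placebo responders and (optionally) intolerant patients before 1:1
randomization. Because the trial-phase change score reuses the same latent
response, run-in deselection truncates the response distribution the
randomized arms inherit — inflating |SMD| — and removing intolerant
patients deflates the drug arm's adverse-event odds ratios. This generator
supplies outcome-bearing trial sets for testing and calibration; a packaged
table of the design characteristics of the 35 real trials in this
literature (`runinmeta.load_table1()`) supplies the design side.

## Worked example

```python
import runinmeta as rm

# a 24-trial set under strong run-in selection (half the trials use run-in)
trials = rm.simulate_trial_set(rm.runin_bias_scenario(seed=1))

for outcome in ("efficacy", "somnolence"):
    table = rm.stratified_pool(trials, outcome, "run_in_presence")
    for label in ("no_run_in", "with_run_in"):
        r = table.strata[label]
        print(f"{outcome:10s} {label:12s} k={r.k:2d}  {rm.format_pooled(r)}")
    c = table.contrast
    print(f"{outcome:10s} contrast     z={c.z:+.2f}  p={c.p:.3f}")
```

prints

```
efficacy   no_run_in    k=12  -0.235 (-0.291 to -0.178)
efficacy   with_run_in  k=12  -0.363 (-0.448 to -0.278)
efficacy   contrast     z=-2.46  p=0.014
somnolence no_run_in    k=12  5.8 (4.9-6.9)
somnolence with_run_in  k=12  2.9 (2.2-3.8)
somnolence contrast     z=-4.30  p=0.000
```

Both trial strata share one patient-level model; only the run-in design
differs. The run-in stratum shows a visibly larger standardized efficacy
(−0.363 vs −0.235; negative favors drug) and a roughly halved somnolence
odds ratio (2.9 vs 5.8) — the two faces of run-in selection bias. SMDs are
printed to 3 decimals, odds ratios exponentiated to 1 decimal; a trailing
`*` would mark cells pooled with a random-effects model.

The same pipeline is scriptable from the shell:

```bash
runinmeta simulate --out trials.csv --seed 3 --n-trials 35
runinmeta validate --input trials.csv
runinmeta analyze  --input trials.csv --out analysis_out/
runinmeta report   --input trials.csv
```

## Layout

- `src/runinmeta/trial_data.py` — data model, CSV I/O, filters, fixture
- `src/runinmeta/effect_sizes.py` — SMD/OR construction, SD recovery
- `src/runinmeta/pooling.py` — fixed/DL pooling, Q, I², τ², model choice
- `src/runinmeta/metaepi.py` — stratification, contrasts, meta-regression
- `src/runinmeta/synthetic_cohort.py` — patient-level trial generator
- `src/runinmeta/cli_report.py` — `runinmeta` command-line interface
- `docs/methods.md` — modeling assumptions, defaults, and limitations
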