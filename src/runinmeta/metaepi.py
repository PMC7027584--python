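"""The meta-epidemiological layer: design features versus trial outcomes.

Here trials are the units of analysis.  Pooled antipsychotic-versus-placebo
effects are computed within strata of a run-in design covariate — presence
of a run-in phase, what patients received during it (washout only versus
placebo or active drug), and its duration (up to one week versus longer) —
and contrasted across strata.  The same machinery runs within drug-class
subsets (conventional / atypical; trials testing both classes count toward
both) and under the sensitivity exclusion of combined-class trials.

Total dropout (both arms combined, in percent of randomized patients) is
related to run-in covariates by random-effects meta-regression with a
method-of-moments residual variance, mirroring how design-feature effects
on attrition are usually quantified.

The between-strata z-test in :func:`compare_strata` is an added
convenience: stratified tables in this literature are usually presented
side by side without a formal test, so contrast records are flagged
``in_source_tables=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .effect_sizes import EffectSet, SmdConfig, build_effects
from .pooling import PooledResult, PoolingConfig, format_pooled, pool_auto
from .trial_data import TrialRecord, TrialSet, filter_trials

COVARIATES = ("run_in_presence", "replacement_type", "duration_dichotomy")

#: canonical stratum order per covariate; the first level is the reference
STRATA = {
    "run_in_presence": ("no_run_in", "with_run_in"),
    "replacement_type": ("washout_only", "placebo_or_drug"),
    "duration_dichotomy": ("le_1_week", "gt_1_week"),
}

DURATION_CUT_DAYS = 7


class AnalysisError(ValueError):
    """Stratified analysis not possible for the given inputs."""


def stratum_of(trial: TrialRecord, covariate: str) -> Optional[str]:
    """Assign a trial to a stratum of a design covariate, or None.

    Replacement and duration strata are defined only for run-in trials
    (and, for duration, only when the duration is known); other trials
    return None and are excluded from that covariate's table.
    """
    if covariate == "run_in_presence":
        return "with_run_in" if trial.run_in.present else "no_run_in"
    if not trial.run_in.present:
        return None
    if covariate == "replacement_type":
        return ("washout_only" if trial.run_in.replacement == "washout_only"
                else "placebo_or_drug")
    if covariate == "duration_dichotomy":
        d = trial.run_in.duration_days
        if d is None:
            return None
        return "le_1_week" if d <= DURATION_CUT_DAYS else "gt_1_week"
    raise ValueError(f"unknown covariate {covariate!r}; valid: {COVARIATES}")


@dataclass
class StratumContrast:
    """Difference between two pooled estimates on the pooling scale."""

    diff: float
    se: float
    z: float
    p: float
    labels: tuple[str, str] = ("", "")
    in_source_tables: bool = False


@dataclass
class StratifiedTable:
    """Per-stratum pooled results for one outcome and design covariate."""

    outcome: str
    covariate: str
    strata: dict[str, PooledResult] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)
    contrast: Optional[StratumContrast] = None

    def k_total(self) -> int:
        return sum(r.k for r in self.strata.values())


def compare_strata(a: PooledResult, b: PooledResult,
                   labels: tuple[str, str] = ("a", "b")) -> StratumContrast:
    """z-test for the difference of two pooled estimates (a minus b)."""
    if a.scale != b.scale:
        raise AnalysisError(f"scale mismatch: {a.scale} vs {b.scale}")
    diff = a.estimate - b.estimate
    se = math.sqrt(a.se ** 2 + b.se ** 2)
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return StratumContrast(diff=diff, se=se, z=z, p=p, labels=labels)


def stratified_pool(trials: TrialSet, outcome: str, covariate: str,
                    smd_cfg: Optional[SmdConfig] = None,
                    pool_cfg: Optional[PoolingConfig] = None,
                    effects: Optional[EffectSet] = None) -> StratifiedTable:
    """Pool one outcome within each stratum of a design covariate.

    Effects are constructed once over the whole set (so SD imputation can
    draw donors from every comparable trial) and then pooled per stratum
    with the I^2 model-selection rule applied per cell.  Strata with no
    contributing trials are omitted; when exactly the two canonical strata
    are present, the table carries their contrast (first minus reference).
    """
    if covariate not in COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}; valid: {COVARIATES}")
    eff = effects if effects is not None \
        else build_effects(trials, outcome, smd_cfg)
    table = StratifiedTable(outcome=outcome, covariate=covariate)
    table.excluded.extend(eff.skipped)
    by_id = {e.trial_id: e for e in eff}
    groups: dict[str, list] = {label: [] for label in STRATA[covariate]}
    for t in trials:
        if t.trial_id not in by_id:
            continue
        label = stratum_of(t, covariate)
        if label is None:
            table.excluded.append((t.trial_id, f"no_{covariate}_stratum"))
            continue
        groups[label].append(by_id[t.trial_id])
    for label, effs in groups.items():
        if effs:
            table.strata[label] = pool_auto(effs, pool_cfg)
    ref, other = STRATA[covariate]
    if ref in table.strata and other in table.strata:
        table.contrast = compare_strata(
            table.strata[other], table.strata[ref], labels=(other, ref))
    return table


def class_subset_analysis(trials: TrialSet, outcome: str,
                          smd_cfg: Optional[SmdConfig] = None,
                          pool_cfg: Optional[PoolingConfig] = None,
                          ) -> dict[str, StratifiedTable]:
    """Run-in presence stratification within each drug-class subset.

    Trials testing both a conventional and an atypical drug contribute to
    both class subsets.
    """
    out = {}
    for cls in ("conventional", "atypical"):
        subset = filter_trials(trials, "by_class", cls=cls)
        out[cls] = stratified_pool(subset, outcome, "run_in_presence",
                                   smd_cfg, pool_cfg)
    return out


def sensitivity_exclude_combined(trials: TrialSet, outcome: str,
                                 covariate: str = "run_in_presence",
                                 smd_cfg: Optional[SmdConfig] = None,
                                 pool_cfg: Optional[PoolingConfig] = None,
                                 ) -> StratifiedTable:
    """Stratified pooling after excluding combined-class trials.

    Removes trials that tested both an atypical drug and a conventional
    comparator in separate arms before stratifying.
    """
    subset = filter_trials(trials, "exclude_combined_class")
    return stratified_pool(subset, outcome, covariate, smd_cfg, pool_cfg)


def selective_dropout_table(trials: TrialSet, covariate: str = "run_in_presence",
                            smd_cfg: Optional[SmdConfig] = None,
                            pool_cfg: Optional[PoolingConfig] = None,
                            ) -> StratifiedTable:
    """Selective dropout (drug-vs-placebo dropout OR) by design covariate."""
    return stratified_pool(trials, "dropout", covariate, smd_cfg, pool_cfg)


# ---------------------------------------------------------------------------
# Meta-regression of total dropout

@dataclass
class MetaRegressionResult:
    """Slope of total dropout (percentage points) on a design covariate.

    ``beta`` is the change in total dropout percent for the non-reference
    stratum relative to the reference (the first canonical stratum);
    ``tau2`` is the method-of-moments residual between-trial variance.
    """

    covariate: str
    reference: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    k: int


def _total_dropout_percent(t: TrialRecord) -> Optional[tuple[float, float]]:
    """Total dropout percent and its binomial variance, or None."""
    d, p = t.drug.dropouts, t.placebo.dropouts
    if d is None or p is None:
        return None
    frac = (d + p) / t.n_randomized
    # binomial approximation on the percent scale; guard degenerate 0/100%
    eps = 0.5 / t.n_randomized
    fv = min(max(frac, eps), 1.0 - eps)
    var = 1e4 * fv * (1.0 - fv) / t.n_randomized
    return 100.0 * frac, var


def weighted_metareg(x, y, v) -> tuple[float, float, float]:
    """Random-effects WLS of y on x with within-unit variances v.

    Fits by inverse-variance weighted least squares, estimates the residual
    between-unit variance tau^2 by the method of moments
    (E[Q_E] = df + tau^2 * [tr(W) - tr((X'WX)^-1 X'W^2 X)], truncated at
    zero), refits with weights 1/(v + tau^2), and returns
    ``(beta, se, tau2)`` for the slope.
    """
    x, y, v = (np.asarray(a, dtype=float) for a in (x, y, v))
    k = x.shape[0]
    if k < 3:
        raise AnalysisError(f"meta-regression needs >= 3 units, got {k}")
    if x.min() == x.max():
        raise AnalysisError("covariate is constant; no contrast")
    X = np.column_stack([np.ones(k), x])

    def wls(weights):
        xtw = X.T * weights
        cov = np.linalg.inv(xtw @ X)
        return cov @ (xtw @ y), cov

    w = 1.0 / v
    beta_f, _ = wls(w)
    resid = y - X @ beta_f
    q_e = float(np.sum(w * resid ** 2))
    df = k - 2
    xtwx_inv = np.linalg.inv((X.T * w) @ X)
    trace_term = float(np.sum(w) - np.trace(xtwx_inv @ ((X.T * w * w) @ X)))
    tau2 = max(0.0, (q_e - df) / trace_term)
    beta, cov = wls(1.0 / (v + tau2))
    return float(beta[1]), math.sqrt(cov[1, 1]), tau2


def meta_regress_dropout(trials: TrialSet, covariate: str = "run_in_presence",
                         ci_level: float = 0.95) -> MetaRegressionResult:
    """Random-effects meta-regression of total dropout on a run-in covariate.

    The outcome is each trial's total dropout in percent of randomized
    patients, with within-trial binomial variance; the covariate is the
    0/1 stratum indicator (reference = first canonical stratum).  A
    method-of-moments residual tau^2 is added to the weights and the slope
    re-estimated by weighted least squares; the CI uses normal quantiles.
    """
    if covariate not in COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}; valid: {COVARIATES}")
    ref, other = STRATA[covariate]
    xs, ys, vs = [], [], []
    for t in trials:
        label = stratum_of(t, covariate)
        yv = _total_dropout_percent(t)
        if label is None or yv is None:
            continue
        xs.append(1.0 if label == other else 0.0)
        ys.append(yv[0])
        vs.append(yv[1])
    k = len(xs)
    beta, se, tau2 = weighted_metareg(xs, ys, vs)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return MetaRegressionResult(
        covariate=covariate, reference=ref, beta=beta, se=se,
        ci_low=beta - z * se, ci_high=beta + z * se, tau2=tau2, k=k)


# ---------------------------------------------------------------------------
# Report tables

CLINICAL_OUTCOMES = ("efficacy", "somnolence", "eps", "mortality")


def build_report_tables(trials: TrialSet,
                        smd_cfg: Optional[SmdConfig] = None,
                        pool_cfg: Optional[PoolingConfig] = None,
                        ) -> dict[str, pd.DataFrame]:
    """Assemble the two summary tables of the analysis.

    ``clinical``: pooled effect per (class grouping x stratum x clinical
    outcome) cell, with trial count, model used, and a formatted rendering.
    The all-classes grouping carries all three covariates' strata; class
    subsets carry run-in presence only.  ``dropout``: selective-dropout
    odds ratios per stratum plus total-dropout meta-regression slopes per
    covariate and grouping.
    """
    groupings = {
        "all": trials,
        "conventional": filter_trials(trials, "by_class", cls="conventional"),
        "atypical": filter_trials(trials, "by_class", cls="atypical"),
    }
    clin_rows, drop_rows = [], []
    for gname, subset in groupings.items():
        covs = COVARIATES if gname == "all" else ("run_in_presence",)
        for outcome in CLINICAL_OUTCOMES + ("dropout",):
            eff = build_effects(subset, outcome, smd_cfg)
            for cov in covs:
                table = stratified_pool(subset, outcome, cov,
                                        smd_cfg, pool_cfg, effects=eff)
                rows = clin_rows if outcome != "dropout" else drop_rows
                for label in STRATA[cov]:
                    r = table.strata.get(label)
                    if r is None:
                        continue
                    rows.append({
                        "grouping": gname, "covariate": cov, "stratum": label,
                        "outcome": outcome, "scale": r.scale,
                        "estimate": r.estimate, "se": r.se,
                        "ci_low": r.ci_low, "ci_high": r.ci_high,
                        "k": r.k, "i2": r.i2, "model": r.model,
                        "formatted": format_pooled(r),
                    })
        for cov in covs:
            try:
                mr = meta_regress_dropout(subset, cov)
            except AnalysisError:
                continue
            drop_rows.append({
                "grouping": gname, "covariate": cov,
                "stratum": STRATA[cov][1], "outcome": "total_dropout",
                "scale": "percent", "estimate": mr.beta, "se": mr.se,
                "ci_low": mr.ci_low, "ci_high": mr.ci_high, "k": mr.k,
                "i2": float("nan"), "model": "meta_regression",
                "formatted": (f"{mr.beta:.1f} ({mr.ci_low:.1f} to "
                              f"{mr.ci_high:.1f}) vs {mr.reference}"),
            })
    return {
        "clinical": pd.DataFrame(clin_rows),
        "dropout": pd.DataFrame(drop_rows),
    }


def render_report_text(tables: dict[str, pd.DataFrame]) -> str:
    """Plain-text rendering of the two report tables."""
    lines = []
    for name, df in tables.items():
        lines.append(f"== {name} ==")
        if df.empty:
            lines.append("(no analyzable cells)")
            continue
        pivot = df.pivot_table(index=["grouping", "covariate", "stratum"],
                               columns="outcome", values="formatted",
                               aggfunc="first", sort=False)
        lines.append(pivot.to_string())
        lines.append("")
    return "\n".join(lines)
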