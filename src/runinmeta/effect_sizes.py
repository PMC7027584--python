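"""Per-trial effect estimates: standardized mean differences and odds ratios.

Efficacy is expressed as the standardized mean difference (SMD) of change
scores between the antipsychotic and placebo arms: Cohen's d on change from
baseline, with Hedges' small-sample correction available by flag.  Negative
SMDs favor the drug (greater symptom reduction).  Binary outcomes
(somnolence, extrapyramidal symptoms, mortality, dropout) are expressed as
log odds ratios with Woolf variances and a 0.5 continuity correction when
any cell of the 2x2 table is empty.

Many older trials report no SD of the change score.  The SD is then
reconstructed, in order of preference, from the between-group p-value, the
confidence interval of the between-group difference, or the range of
changes (range/4); as a last resort it is imputed as the mean reported SD
of trials with the same target symptom and instrument.  Every estimate
carries provenance flags recording which route produced its SD and which
corrections were applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .trial_data import ArmOutcome, TrialRecord, TrialSet

logger = logging.getLogger(__name__)

OUTCOMES = ("efficacy", "somnolence", "eps", "mortality", "dropout")

#: outcome name -> ArmOutcome count attribute
_COUNT_ATTR = {
    "somnolence": "events_somnolence",
    "eps": "events_eps",
    "mortality": "deaths",
    "dropout": "dropouts",
}


class EffectSizeError(ValueError):
    """Effect size not computable from the given aggregates."""


@dataclass
class SmdConfig:
    """Choices the SMD construction leaves open.

    ``hedges_correction`` applies Hedges' J factor to d and its variance;
    ``sd_recovery_quantile`` selects the reference distribution used when
    inverting a p-value or CI back to a standard error (``"t"`` with
    df = n1+n2-2, or ``"normal"``).
    """

    hedges_correction: bool = False
    ci_level: float = 0.95
    sd_recovery_quantile: str = "t"

    def __post_init__(self):
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.sd_recovery_quantile not in ("t", "normal"):
            raise ValueError("sd_recovery_quantile must be 't' or 'normal'")


@dataclass
class EffectEstimate:
    """A point estimate with variance and provenance.

    ``scale`` is ``"smd"`` for standardized mean differences or
    ``"log_or"`` for log odds ratios; ``estimate`` and the CI are on that
    scale.  ``sd_source`` records how the SD entered an SMD (``reported``,
    ``from_p``, ``from_ci``, ``from_range``, ``imputed``) and is
    ``not_applicable`` for odds ratios.  ``corrections`` lists adjustments
    such as ``continuity_0.5`` or ``hedges_g``.
    """

    trial_id: str
    outcome: str
    scale: str
    estimate: float
    variance: float
    ci_low: float
    ci_high: float
    sd_source: str = "not_applicable"
    corrections: list[str] = field(default_factory=list)

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass
class EffectSet:
    """Effect estimates for one outcome, plus the skip log.

    ``skipped`` holds ``(trial_id, reason)`` pairs for trials that could
    not contribute (outcome not reported, or excluded from pooling because
    both arms had zero events).
    """

    outcome: str
    effects: list[EffectEstimate] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.effects)

    def __len__(self):
        return len(self.effects)


def _ci_from(estimate: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    return estimate - z * se, estimate + z * se


def _recovery_quantile(prob: float, n1: int, n2: int, cfg: SmdConfig) -> float:
    if cfg.sd_recovery_quantile == "t":
        return stats.t.ppf(prob, df=n1 + n2 - 2)
    return stats.norm.ppf(prob)


# ---------------------------------------------------------------------------
# SD reconstruction

def sd_from_p(mean_diff: float, n1: int, n2: int, p_two_sided: float,
              cfg: Optional[SmdConfig] = None) -> float:
    """Reconstruct the common change-score SD from a between-group p-value.

    Inverts the two-sample test: the quantile at 1 - p/2 gives the test
    statistic, |mean_diff| / statistic the standard error of the
    difference, and SE / sqrt(1/n1 + 1/n2) the (pooled) SD.
    """
    cfg = cfg or SmdConfig()
    if n1 < 2 or n2 < 2:
        raise EffectSizeError("need n >= 2 per arm")
    if not 0.0 < p_two_sided <= 1.0:
        raise EffectSizeError("p must be in (0, 1]")
    if mean_diff == 0 or p_two_sided == 1.0:
        raise EffectSizeError(
            "SE undefined for zero mean difference or p = 1")
    tstar = _recovery_quantile(1.0 - p_two_sided / 2.0, n1, n2, cfg)
    se = abs(mean_diff) / tstar
    return se / math.sqrt(1.0 / n1 + 1.0 / n2)


def sd_from_ci(ci_low: float, ci_high: float, n1: int, n2: int,
               cfg: Optional[SmdConfig] = None) -> float:
    """Reconstruct the common SD from a CI for the between-group difference."""
    cfg = cfg or SmdConfig()
    if n1 < 2 or n2 < 2:
        raise EffectSizeError("need n >= 2 per arm")
    if not ci_low < ci_high:
        raise EffectSizeError("degenerate confidence interval")
    q = _recovery_quantile(0.5 + cfg.ci_level / 2.0, n1, n2, cfg)
    se = (ci_high - ci_low) / (2.0 * q)
    return se / math.sqrt(1.0 / n1 + 1.0 / n2)


def sd_from_range(range_width: float) -> float:
    """Approximate the SD as range/4 (the usual rule for reported ranges)."""
    if range_width <= 0:
        raise EffectSizeError("range width must be positive")
    return range_width / 4.0


def impute_sd(trials: TrialSet, target: str, arm_role: str = "drug") -> float:
    """Impute a missing SD as the mean reported SD of comparable trials.

    Donors share the target trial's symptom indication and instrument and
    report ``sd_change`` in the same arm role (``"drug"`` or
    ``"placebo"``).  If the strict (symptom, instrument) stratum is empty,
    falls back to matching on instrument only, with a warning.
    """
    t = trials[target]
    if arm_role not in ("drug", "placebo"):
        raise ValueError("arm_role must be 'drug' or 'placebo'")

    def donors(match_symptom: bool) -> list[float]:
        out = []
        for other in trials:
            if other.trial_id == target:
                continue
            if other.instrument != t.instrument:
                continue
            if match_symptom and other.symptom != t.symptom:
                continue
            sd = getattr(other, arm_role).sd_change
            if sd is not None:
                out.append(sd)
        return out

    sds = donors(match_symptom=True)
    if not sds:
        sds = donors(match_symptom=False)
        if sds:
            logger.warning(
                "%s: no donor trials with symptom=%s and instrument=%s; "
                "imputing from instrument-only stratum (%d donors)",
                target, t.symptom, t.instrument, len(sds))
    if not sds:
        raise EffectSizeError(
            f"{target}: no donor trials share instrument {t.instrument!r} "
            "with a reported SD; cannot impute")
    return sum(sds) / len(sds)


# ---------------------------------------------------------------------------
# Continuous effects

def combine_arms(
    arms: Sequence[tuple[int, float, float]],
) -> tuple[int, float, float]:
    """Combine several dose/drug arms into one, as if patients were pooled.

    Each arm is ``(n, mean_change, sd_change)``.  The combined mean is the
    n-weighted mean; the combined variance pools within-arm and between-arm
    components exactly as the sample variance of the concatenated
    patient-level data would:

        sd^2 = [sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2] / (sum n_i - 1)
    """
    if not arms:
        raise EffectSizeError("no arms to combine")
    for n, _, sd in arms:
        if n < 1:
            raise EffectSizeError("arm n must be positive")
        if sd is None or sd <= 0:
            raise EffectSizeError("all arm SDs must be present and positive")
    if len(arms) == 1:
        return arms[0]
    ntot = sum(n for n, _, _ in arms)
    mbar = sum(n * m for n, m, _ in arms) / ntot
    ss = sum((n - 1) * sd * sd + n * (m - mbar) ** 2 for n, m, sd in arms)
    return ntot, mbar, math.sqrt(ss / (ntot - 1))


def smd_change(drug: tuple[int, float, float], placebo: tuple[int, float, float],
               cfg: Optional[SmdConfig] = None, *, trial_id: str = "",
               sd_source: str = "reported") -> EffectEstimate:
    """Standardized mean difference of change scores (drug minus placebo).

    d = (m_drug - m_placebo) / s_pooled with the usual pooled SD; the
    variance is (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)).  Negative d favors
    the drug.  With ``hedges_correction``, d and its SE are shrunk by
    J = 1 - 3 / (4 (n1+n2-2) - 1).
    """
    cfg = cfg or SmdConfig()
    n1, m1, s1 = drug
    n2, m2, s2 = placebo
    if n1 < 2 or n2 < 2:
        raise EffectSizeError("need n >= 2 per arm")
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise EffectSizeError("pooled SD is zero")
    d = (m1 - m2) / math.sqrt(sp2)
    var = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    corrections = []
    if cfg.hedges_correction:
        j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
        d *= j
        var *= j * j
        corrections.append("hedges_g")
    lo, hi = _ci_from(d, math.sqrt(var), cfg.ci_level)
    return EffectEstimate(trial_id=trial_id, outcome="efficacy", scale="smd",
                          estimate=d, variance=var, ci_low=lo, ci_high=hi,
                          sd_source=sd_source, corrections=corrections)


# ---------------------------------------------------------------------------
# Binary effects

def or_from_counts(events_drug: int, n_drug: int, events_plc: int, n_plc: int,
                   continuity: float = 0.5, *, trial_id: str = "",
                   outcome: str = "mortality",
                   ci_level: float = 0.95) -> Optional[EffectEstimate]:
    """Log odds ratio from 2x2 counts, with zero-cell continuity correction.

    If any cell is zero, ``continuity`` is added to all four cells and the
    estimate flagged.  Trials with zero events in *both* arms carry no
    information about the odds ratio and return ``None`` (callers exclude
    them from pooling and log the exclusion).
    """
    if n_drug <= 0 or n_plc <= 0:
        raise EffectSizeError("arm sizes must be positive")
    if not (0 <= events_drug <= n_drug and 0 <= events_plc <= n_plc):
        raise EffectSizeError("event counts must lie in [0, n]")
    if events_drug == 0 and events_plc == 0:
        return None
    a, b = float(events_drug), float(n_drug - events_drug)
    c, d = float(events_plc), float(n_plc - events_plc)
    corrections = []
    if min(a, b, c, d) == 0.0:
        a, b, c, d = (x + continuity for x in (a, b, c, d))
        corrections.append(f"continuity_{continuity:g}")
    log_or = math.log((a * d) / (b * c))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    lo, hi = _ci_from(log_or, math.sqrt(var), ci_level)
    return EffectEstimate(trial_id=trial_id, outcome=outcome, scale="log_or",
                          estimate=log_or, variance=var, ci_low=lo, ci_high=hi,
                          sd_source="not_applicable", corrections=corrections)


# ---------------------------------------------------------------------------
# Orchestration

def _resolve_sd(trials: TrialSet, t: TrialRecord,
                cfg: SmdConfig) -> tuple[float, float, str]:
    """Return (sd_drug, sd_placebo, source) by the reporting precedence.

    Order: reported per-arm SDs; else the between-group p-value; else the
    CI of the difference; else per-arm ranges; else imputation from
    comparable trials.  p/CI routes yield a single common SD used for both
    arms (they identify only the pooled SD).
    """
    drug, plc = t.drug, t.placebo
    if drug.sd_change is not None and plc.sd_change is not None:
        return drug.sd_change, plc.sd_change, "reported"
    p = drug.p_value_between if drug.p_value_between is not None \
        else plc.p_value_between
    diff = None
    if drug.mean_change is not None and plc.mean_change is not None:
        diff = drug.mean_change - plc.mean_change
    if p is not None and p < 1.0 and diff:
        sd = sd_from_p(diff, drug.n, plc.n, p, cfg)
        return sd, sd, "from_p"
    ci = (drug.ci_low, drug.ci_high) \
        if drug.ci_low is not None and drug.ci_high is not None \
        else (plc.ci_low, plc.ci_high)
    if ci[0] is not None and ci[1] is not None:
        sd = sd_from_ci(ci[0], ci[1], drug.n, plc.n, cfg)
        return sd, sd, "from_ci"
    if drug.range_width is not None or plc.range_width is not None:
        sd_d = sd_from_range(drug.range_width) \
            if drug.range_width is not None else None
        sd_p = sd_from_range(plc.range_width) \
            if plc.range_width is not None else None
        return sd_d if sd_d is not None else sd_p, \
            sd_p if sd_p is not None else sd_d, "from_range"
    sd_d = drug.sd_change if drug.sd_change is not None \
        else impute_sd(trials, t.trial_id, "drug")
    sd_p = plc.sd_change if plc.sd_change is not None \
        else impute_sd(trials, t.trial_id, "placebo")
    return sd_d, sd_p, "imputed"


def build_effects(trials: TrialSet, outcome: str,
                  cfg: Optional[SmdConfig] = None) -> EffectSet:
    """Construct one effect estimate per trial reporting the outcome.

    ``efficacy`` yields SMDs with SDs resolved by the reporting precedence;
    the binary outcomes yield log odds ratios.  Trials that do not report
    the outcome (or are double-zero for a binary outcome) appear in the
    returned :class:`EffectSet.skipped` log with a reason code.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; valid: {OUTCOMES}")
    cfg = cfg or SmdConfig()
    result = EffectSet(outcome=outcome)
    for t in trials:
        drug, plc = t.drug, t.placebo
        if outcome == "efficacy":
            if None in (drug.n, plc.n, drug.mean_change, plc.mean_change):
                result.skipped.append((t.trial_id, "no_change_data"))
                continue
            try:
                sd_d, sd_p, source = _resolve_sd(trials, t, cfg)
            except EffectSizeError as exc:
                result.skipped.append((t.trial_id, f"sd_unrecoverable: {exc}"))
                continue
            est = smd_change((drug.n, drug.mean_change, sd_d),
                             (plc.n, plc.mean_change, sd_p),
                             cfg, trial_id=t.trial_id, sd_source=source)
            result.effects.append(est)
        else:
            attr = _COUNT_ATTR[outcome]
            e_d, e_p = getattr(drug, attr), getattr(plc, attr)
            if None in (drug.n, plc.n, e_d, e_p):
                result.skipped.append((t.trial_id, "outcome_not_reported"))
                continue
            est = or_from_counts(e_d, drug.n, e_p, plc.n,
                                 trial_id=t.trial_id, outcome=outcome,
                                 ci_level=cfg.ci_level)
            if est is None:
                result.skipped.append((t.trial_id, "both_arms_zero_events"))
                continue
            result.effects.append(est)
    for trial_id, reason in result.skipped:
        logger.info("%s: skipped for %s (%s)", trial_id, outcome, reason)
    return result


def effects_to_rows(effects: EffectSet) -> list[dict]:
    """Flatten an EffectSet to CSV-ready records."""
    return [
        {
            "trial_id": e.trial_id, "outcome": e.outcome, "scale": e.scale,
            "estimate": e.estimate, "se": e.se,
            "ci_low": e.ci_low, "ci_high": e.ci_high,
            "sd_source": e.sd_source, "corrections": ";".join(e.corrections),
        }
        for e in effects
    ]
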