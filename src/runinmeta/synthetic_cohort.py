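"""Patient-level generator of antipsychotic-vs-placebo trial sets.

No per-trial outcome data for this literature are deposited anywhere, so
the pipeline is exercised on synthetic trial sets generated from an
explicit patient-level model of how a run-in phase reshapes the randomized
population.

Each enrolled patient carries a latent placebo response r_i (the change in
symptom score they would show without active drug, negative = improvement)
and a latent intolerance indicator.  During a run-in phase every patient
receives placebo-equivalent exposure; their observed run-in change is
r_i plus measurement noise.  Patients whose run-in *improvement* meets the
``placebo_responder_cut`` threshold — the strong placebo responders — are
deselected, as (optionally) are intolerant patients.  Survivors are
randomized 1:1.  The trial-phase change re-uses the same latent r_i (plus
fresh noise, plus ``drug_effect`` on drug), so run-in deselection truncates
the placebo-response distribution that the randomized arms inherit: the
placebo arm's apparent response shrinks and the change-score SD contracts,
inflating the standardized effect.  Intolerant patients on drug have
elevated odds of somnolence, EPS, and dropout (one shared multiplier), so
their removal deflates the drug arm's adverse-event odds ratios.

Generated records mirror what a reviewer can extract from published
aggregate tables: per-arm n, mean change with SD, and event counts.
:func:`degrade_reporting` then emulates incomplete reporting by replacing
SDs with the p-value, CI, or range they imply, or deleting them outright,
so the SD-reconstruction layer can be tested as an exact round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy import stats

from .trial_data import (ATYPICAL_DRUGS, CONVENTIONAL_DRUGS, ArmOutcome,
                         RunInSpec, TrialRecord, TrialSet)

_INSTRUMENT_FOR = {"diverse": "NPI", "psychosis": "BEHAVE-AD",
                   "agitation": "CMAI", "aggression": "CMAI"}


class SimulationError(RuntimeError):
    pass


@dataclass
class PatientModel:
    """Generative parameters for one patient population.

    Scales are symptom-instrument points (an NPI/CMAI-like scale).
    Defaults emulate the dementia NPS trial literature this pipeline
    targets: modest spontaneous/placebo improvement with wide person-level
    heterogeneity, a small additional drug effect (SMD around -0.2),
    somnolence/EPS/mortality odds ratios near 3 / 2 / 1.5 on placebo-arm
    risks of a few percent, and total dropout near 30%.
    """

    baseline_mean: float = 60.0
    baseline_sd: float = 15.0
    placebo_response_mean: float = -8.0
    placebo_response_sd: float = 10.0
    drug_effect: float = -2.5
    outcome_noise_sd: float = 8.0
    p_somnolence_plc: float = 0.07
    p_eps_plc: float = 0.06
    p_death_plc: float = 0.03
    or_somnolence: float = 3.0
    or_eps: float = 2.0
    or_death: float = 1.5
    p_dropout_base: float = 0.28
    intolerance_prob: float = 0.10
    intolerance_or_multiplier: float = 5.0

    def __post_init__(self):
        for name in ("p_somnolence_plc", "p_eps_plc", "p_death_plc",
                     "p_dropout_base", "intolerance_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("or_somnolence", "or_eps", "or_death",
                     "intolerance_or_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outcome_noise_sd <= 0:
            raise ValueError("outcome_noise_sd must be positive")


@dataclass
class RunInDesign:
    """Run-in phase of a simulated trial.

    ``placebo_responder_cut`` is the run-in improvement (in symptom points,
    positive = improvement) at or beyond which a patient is deselected as a
    placebo responder; ``math.inf`` disables that filter.  All patients
    receive placebo-equivalent exposure during run-in regardless of the
    ``replacement`` label, which affects metadata only.

    Defaults give mild selection: with the default :class:`PatientModel`,
    a cut of 20 points removes roughly the most responsive sixth of
    patients and intolerance screening another tenth, for post-run-in
    exclusion fractions within the 0-29% range this literature reports.
    """

    present: bool = True
    replacement: str = "placebo"
    duration_days: int = 7
    placebo_responder_cut: float = 20.0
    exclude_intolerant: bool = True

    def to_spec(self, pct_excluded: Optional[float]) -> RunInSpec:
        if not self.present:
            return RunInSpec(present=False)
        return RunInSpec(present=True, replacement=self.replacement,
                         duration_days=self.duration_days,
                         pct_excluded_after_runin=pct_excluded)


@dataclass
class SimConfig:
    """A reproducible trial-set scenario.

    ``patients_per_trial`` is the number enrolled into run-in (an int, or
    an inclusive ``(low, high)`` range sampled per trial); randomized n is
    what survives deselection.  ``share_with_runin`` of the trials receive
    the ``runin_design`` (with durations resampled between 2 days and 6
    weeks, mirroring the range this literature reports); the rest have no
    run-in.  The same seed always yields the identical trial set.
    """

    n_trials: int = 35
    patients_per_trial: Union[int, tuple[int, int]] = 220
    share_with_runin: float = 29 / 35
    patient_model: PatientModel = field(default_factory=PatientModel)
    runin_design: RunInDesign = field(default_factory=RunInDesign)
    seed: int = 0
    sample_durations: bool = True

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.share_with_runin <= 1.0:
            raise ValueError("share_with_runin must be in [0, 1]")


def _odds_to_prob(p_base: float, or_factor: float) -> float:
    if p_base == 0.0:
        return 0.0
    odds = p_base / (1.0 - p_base) * or_factor
    return odds / (1.0 + odds)


def _event_counts(rng, on_drug: np.ndarray, intolerant: np.ndarray,
                  p_plc: float, or_drug: float, mult: float,
                  apply_mult: bool) -> np.ndarray:
    """Per-patient Bernoulli events with drug and intolerance odds shifts."""
    p = np.full(on_drug.shape, p_plc)
    p[on_drug] = _odds_to_prob(p_plc, or_drug)
    if apply_mult:
        mask = on_drug & intolerant
        p[mask] = _odds_to_prob(p_plc, or_drug * mult)
    return rng.random(on_drug.shape) < p


def simulate_trial(model: PatientModel, runin: RunInDesign, n_patients: int,
                   rng: np.random.Generator, *, trial_id: str = "sim",
                   year: int = 2000, drug_class: str = "atypical",
                   drug_names: Optional[list[str]] = None,
                   setting: str = "nursing_home", symptom: str = "diverse",
                   ) -> TrialRecord:
    """Simulate one trial: enrollment, run-in deselection, randomization,
    trial-phase outcomes, and aggregation to a TrialRecord.
    """
    if n_patients < 8:
        raise SimulationError("need at least 8 enrolled patients")
    m = model
    latent_response = rng.normal(m.placebo_response_mean,
                                 m.placebo_response_sd, n_patients)
    intolerant = rng.random(n_patients) < m.intolerance_prob

    # drawn unconditionally so that a run-in with inactive filters follows
    # the same random path as a no-run-in trial of the same seed
    runin_change = latent_response + rng.normal(
        0.0, m.outcome_noise_sd, n_patients)

    pct_excluded: Optional[float] = None
    if runin.present:
        improvement = -runin_change
        excluded = improvement >= runin.placebo_responder_cut
        if runin.exclude_intolerant:
            excluded |= intolerant
        pct_excluded = float(excluded.sum()) / n_patients
        keep = ~excluded
        if keep.sum() < 4:
            raise SimulationError(
                "run-in deselection removed (nearly) all patients; "
                "use a milder placebo_responder_cut")
        latent_response = latent_response[keep]
        intolerant = intolerant[keep]

    n = latent_response.shape[0]
    perm = rng.permutation(n)
    on_drug = np.zeros(n, dtype=bool)
    on_drug[perm[: n // 2]] = True

    change = latent_response + rng.normal(0.0, m.outcome_noise_sd, n)
    change[on_drug] += m.drug_effect

    som = _event_counts(rng, on_drug, intolerant, m.p_somnolence_plc,
                        m.or_somnolence, m.intolerance_or_multiplier, True)
    eps = _event_counts(rng, on_drug, intolerant, m.p_eps_plc,
                        m.or_eps, m.intolerance_or_multiplier, True)
    death = _event_counts(rng, on_drug, intolerant, m.p_death_plc,
                          m.or_death, m.intolerance_or_multiplier, False)
    drop = _event_counts(rng, on_drug, intolerant, m.p_dropout_base,
                         1.0, m.intolerance_or_multiplier, True)

    def arm(mask: np.ndarray, label: str) -> ArmOutcome:
        vals = change[mask]
        return ArmOutcome(
            arm_label=label, n=int(mask.sum()),
            mean_change=float(vals.mean()),
            sd_change=float(vals.std(ddof=1)),
            events_somnolence=int(som[mask].sum()),
            events_eps=int(eps[mask].sum()),
            deaths=int(death[mask].sum()),
            dropouts=int(drop[mask].sum()),
        )

    if drug_names is None:
        drug_names = ["risperidone"] if drug_class != "conventional" \
            else ["haloperidol"]
    return TrialRecord(
        trial_id=trial_id, year=year, drug_class=drug_class,
        drug_names=drug_names, setting=setting, symptom=symptom,
        instrument=_INSTRUMENT_FOR[symptom],
        run_in=runin.to_spec(pct_excluded), n_randomized=n,
        drug=arm(on_drug, "antipsychotic"), placebo=arm(~on_drug, "placebo"),
    )


_CLASS_MENU = (
    ("conventional", sorted(CONVENTIONAL_DRUGS)),
    ("atypical", sorted(ATYPICAL_DRUGS)),
)
#: class mix of the trial literature: 11 conventional : 21 atypical : 3 both
_CLASS_WEIGHTS = {"conventional": 11, "atypical": 21, "both": 3}
#: replacement mix among run-in trials: 14 washout : 13 placebo : 2 active
_REPLACEMENT_WEIGHTS = {"washout_only": 14, "placebo": 13, "active_drug": 2}


def _allocate(n: int, weights: dict[str, int], rng) -> list[str]:
    labels = list(weights)
    total = sum(weights.values())
    counts = [int(round(n * weights[lab] / total)) for lab in labels]
    while sum(counts) > n:
        counts[counts.index(max(counts))] -= 1
    while sum(counts) < n:
        counts[counts.index(min(counts))] += 1
    out = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    rng.shuffle(out)
    return out


def simulate_trial_set(cfg: SimConfig) -> TrialSet:
    """Generate a full trial set under one scenario.

    Exactly ``round(share_with_runin * n_trials)`` trials receive a run-in
    design; which ones, their durations (2-42 days), replacement labels,
    drug classes, and target symptoms are drawn from the design stream.
    Per-trial randomness comes from independently spawned child streams,
    so enlarging the set leaves earlier trials untouched.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_trials + 1)
    design_rng = np.random.default_rng(children[0])

    n_runin = int(round(cfg.share_with_runin * cfg.n_trials))
    runin_flags = np.zeros(cfg.n_trials, dtype=bool)
    runin_flags[design_rng.permutation(cfg.n_trials)[:n_runin]] = True
    classes = _allocate(cfg.n_trials, _CLASS_WEIGHTS, design_rng)
    replacements = iter(_allocate(n_runin, _REPLACEMENT_WEIGHTS, design_rng))

    trials = []
    for i in range(cfg.n_trials):
        if runin_flags[i]:
            design = replace(
                cfg.runin_design, present=True,
                replacement=next(replacements),
                duration_days=int(design_rng.integers(2, 43))
                if cfg.sample_durations else cfg.runin_design.duration_days)
        else:
            design = RunInDesign(present=False)
        if isinstance(cfg.patients_per_trial, int):
            n_pat = cfg.patients_per_trial
        else:
            lo, hi = cfg.patients_per_trial
            n_pat = int(design_rng.integers(lo, hi + 1))
        cls = classes[i]
        if cls == "both":
            names = [sorted(ATYPICAL_DRUGS)[int(design_rng.integers(0, 6))],
                     "haloperidol"]
        else:
            menu = dict(_CLASS_MENU)[cls]
            names = [menu[int(design_rng.integers(0, len(menu)))]]
        symptom = ("diverse", "agitation", "psychosis",
                   "aggression")[int(design_rng.integers(0, 4))]
        trials.append(simulate_trial(
            cfg.patient_model, design, n_pat,
            np.random.default_rng(children[i + 1]),
            trial_id=f"sim_{i:03d}", year=1995 + i % 25, drug_class=cls,
            drug_names=names, symptom=symptom))
    ts = TrialSet(trials=trials,
                  provenance=f"synthetic (seed={cfg.seed}, "
                             f"n_trials={cfg.n_trials})")
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# Reporting degradation

DEGRADE_MODES = ("to_p", "to_ci", "to_range", "remove")


def degrade_reporting(trials: TrialSet, pattern: dict[str, float],
                      seed: int = 0, ci_level: float = 0.95) -> TrialSet:
    """Emulate incomplete SD reporting on a complete trial set.

    ``pattern`` maps degradation modes to trial fractions, e.g.
    ``{"to_p": 0.2, "remove": 0.1}``.  Selected trials lose their per-arm
    SDs and instead carry exactly one surrogate computed consistently from
    the true aggregates with the t reference distribution
    (df = n1 + n2 - 2): the between-group p-value, the CI of the
    between-group difference, or per-arm ranges equal to 4 SD.  ``remove``
    deletes the SDs outright, forcing imputation downstream.  SD
    reconstruction therefore inverts ``to_p``/``to_ci`` back to the pooled
    SD (and ``to_range`` to each arm SD) exactly, up to floating point.
    """
    unknown = set(pattern) - set(DEGRADE_MODES)
    if unknown:
        raise ValueError(f"unknown degrade modes: {sorted(unknown)}; "
                         f"valid: {DEGRADE_MODES}")
    if sum(pattern.values()) > 1.0 + 1e-9:
        raise ValueError("pattern fractions sum to more than 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xDE6)))
    order = rng.permutation(len(trials.trials))
    assignment: dict[int, str] = {}
    start = 0
    for mode, frac in pattern.items():
        count = int(round(frac * len(trials.trials)))
        for idx in order[start:start + count]:
            assignment[int(idx)] = mode
        start += count

    out = []
    for i, t in enumerate(trials):
        mode = assignment.get(i)
        if mode is None:
            out.append(t)
            continue
        d, p = t.drug, t.placebo
        if None in (d.n, p.n, d.mean_change, p.mean_change,
                    d.sd_change, p.sd_change):
            raise ValueError(f"{t.trial_id}: cannot degrade, aggregates "
                             "incomplete")
        new_d = replace(d, sd_change=None)
        new_p = replace(p, sd_change=None)
        if mode != "remove":
            n1, n2 = d.n, p.n
            sp = math.sqrt(((n1 - 1) * d.sd_change ** 2
                            + (n2 - 1) * p.sd_change ** 2) / (n1 + n2 - 2))
            se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
            diff = d.mean_change - p.mean_change
            df = n1 + n2 - 2
            if mode == "to_p":
                if diff == 0:
                    out.append(t)  # p carries no SD information here
                    continue
                pval = 2.0 * stats.t.sf(abs(diff) / se, df)
                new_d = replace(new_d, p_value_between=pval)
                new_p = replace(new_p, p_value_between=pval)
            elif mode == "to_ci":
                q = stats.t.ppf(0.5 + ci_level / 2.0, df)
                new_d = replace(new_d, ci_low=diff - q * se,
                                ci_high=diff + q * se)
                new_p = replace(new_p, ci_low=diff - q * se,
                                ci_high=diff + q * se)
            else:  # to_range: range = 4 SD, the inverse of the range/4 rule
                new_d = replace(new_d, range_width=4.0 * d.sd_change)
                new_p = replace(new_p, range_width=4.0 * p.sd_change)
        out.append(replace(t, drug=new_d, placebo=new_p))
    return TrialSet(trials=out,
                    provenance=f"{trials.provenance} | degraded({pattern})")


# ---------------------------------------------------------------------------
# Scenario presets

def null_scenario(seed: int = 0, n_trials: int = 20,
                  patients_per_trial: int = 200) -> SimConfig:
    """No drug effect, no run-in anywhere: the calibration null."""
    return SimConfig(
        n_trials=n_trials, patients_per_trial=patients_per_trial,
        share_with_runin=0.0,
        patient_model=PatientModel(drug_effect=0.0),
        runin_design=RunInDesign(present=False), seed=seed)


def runin_bias_scenario(seed: int = 0, n_trials: int = 24,
                        patients_per_trial: int = 400) -> SimConfig:
    """Strong run-in selection, for demonstrating the bias mechanisms.

    Placebo-response heterogeneity dominates measurement noise and the
    run-in improvement threshold removes roughly the most responsive 40%
    of patients, so deselection sharply truncates the latent response
    distribution; a quarter of patients are drug-intolerant with strongly
    elevated adverse-event odds and are screened out.  Half the trials use
    run-in, half do not, at equal size, so the stratum contrast isolates
    the design feature.
    """
    model = PatientModel(
        placebo_response_mean=-8.0, placebo_response_sd=13.0,
        outcome_noise_sd=3.5, drug_effect=-3.2,
        p_somnolence_plc=0.08, or_somnolence=3.0,
        p_eps_plc=0.07, or_eps=2.0,
        intolerance_prob=0.25, intolerance_or_multiplier=8.0)
    design = RunInDesign(present=True, replacement="placebo",
                         duration_days=7, placebo_responder_cut=11.4,
                         exclude_intolerant=True)
    return SimConfig(n_trials=n_trials, patients_per_trial=patients_per_trial,
                     share_with_runin=0.5, patient_model=model,
                     runin_design=design, seed=seed)
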