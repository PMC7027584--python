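"""Trial-level data model for the run-in meta-epidemiology pipeline.

The unit of analysis is a randomized placebo-controlled trial of an
antipsychotic versus placebo for neuropsychiatric symptoms (NPS) in
dementia, described by its design characteristics (publication year, drug
class, setting, target symptom, run-in design) and per-arm aggregate
outcomes (mean change on a symptom instrument with SD, and counts of
somnolence, extrapyramidal symptoms, deaths, and dropouts).

Trials are serialized to/from a flat CSV with one row per trial and two
per-arm column blocks prefixed ``drug_`` and ``plc_``.  Missing values are
empty cells, never sentinel numbers.  The packaged fixture
``fixtures/table1_trials.csv`` holds the design characteristics of the 35
trials in this literature; their per-trial outcome columns are empty
(aggregate outcomes were never published per trial) and are supplied by the
:mod:`runinmeta.synthetic_cohort` generator in tests and demonstrations.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Optional

logger = logging.getLogger(__name__)

DRUG_CLASSES = ("conventional", "atypical", "both")
REPLACEMENTS = ("none", "washout_only", "placebo", "active_drug")
SETTINGS = ("hospital", "nursing_home", "outpatients", "mixed", "not_reported")
SYMPTOMS = ("diverse", "agitation", "psychosis", "aggression")

#: Antipsychotics appearing in this literature, by pharmacological class.
CONVENTIONAL_DRUGS = frozenset({
    "trifluoperazine", "haloperidol", "thiothixene", "thioridazine",
    "loxapine", "perphenazine",
})
ATYPICAL_DRUGS = frozenset({
    "olanzapine", "risperidone", "quetiapine", "aripiprazole",
    "brexpiprazole", "pimavanserin", "tiapride",
})

FIXTURE_NAME = "table1_trials.csv"

CSV_COLUMNS = (
    "trial_id", "year", "drug_class", "drug_names", "setting", "symptom",
    "instrument", "run_in_present", "replacement", "duration_days",
    "duration_approximate", "pct_excluded_after_runin", "n_randomized",
) + tuple(
    f"{prefix}_{col}"
    for prefix in ("drug", "plc")
    for col in (
        "n", "mean_change", "sd_change", "p_between", "ci_low", "ci_high",
        "range_width", "somnolence", "eps", "deaths", "dropouts",
    )
)


class TrialDataError(Exception):
    """Base error for trial-data problems."""


class SchemaError(TrialDataError):
    """CSV header does not match the expected schema."""


class ValidationError(TrialDataError):
    """A trial record violates an invariant."""


@dataclass
class RunInSpec:
    """Design of the pre-randomization run-in phase.

    ``replacement`` says what eligible patients received during run-in:
    nothing beyond washout of prior drugs (``washout_only``), ``placebo``,
    or the ``active_drug`` under study; ``none`` is reserved for trials
    without a run-in.  ``duration_days`` may be missing when a trial
    reports a run-in but not its length; ``duration_approximate`` marks
    durations the source reports only loosely (e.g. "<1 week", "at least
    2 days").  ``pct_excluded_after_runin`` is the fraction of enrolled
    patients deselected at the end of run-in, in [0, 1].
    """

    present: bool
    replacement: str = "none"
    duration_days: Optional[int] = None
    duration_approximate: bool = False
    pct_excluded_after_runin: Optional[float] = None

    def problems(self) -> list[str]:
        out = []
        if self.replacement not in REPLACEMENTS:
            out.append(f"unknown replacement {self.replacement!r}")
        if not self.present:
            if self.replacement != "none":
                out.append("run-in absent but replacement is not 'none'")
            if self.duration_days is not None:
                out.append("run-in absent but duration_days given")
        else:
            if self.replacement == "none":
                out.append("run-in present but replacement is 'none'")
            if self.duration_days is not None and self.duration_days < 1:
                out.append("duration_days must be >= 1 when given")
        p = self.pct_excluded_after_runin
        if p is not None and not (0.0 <= p <= 1.0):
            out.append("pct_excluded_after_runin outside [0, 1]")
        return out


@dataclass
class ArmOutcome:
    """Aggregate outcomes for one randomized arm.

    ``mean_change`` is change from baseline to endpoint on the symptom
    instrument (negative = improvement).  The between-group p-value, CI of
    the between-group difference, or the range of changes may stand in for
    a missing ``sd_change``; the effect-size layer reconstructs the SD from
    whichever is available.
    """

    arm_label: str  # "antipsychotic" or "placebo"
    n: Optional[int] = None
    mean_change: Optional[float] = None
    sd_change: Optional[float] = None
    p_value_between: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    range_width: Optional[float] = None
    events_somnolence: Optional[int] = None
    events_eps: Optional[int] = None
    deaths: Optional[int] = None
    dropouts: Optional[int] = None

    def problems(self) -> list[str]:
        out = []
        if self.arm_label not in ("antipsychotic", "placebo"):
            out.append(f"unknown arm_label {self.arm_label!r}")
        if self.n is not None and self.n < 1:
            out.append("arm n must be positive")
        if self.sd_change is not None and self.sd_change <= 0:
            out.append("sd_change must be positive")
        p = self.p_value_between
        if p is not None and not (0.0 < p <= 1.0):
            out.append("p_value_between outside (0, 1]")
        if (self.ci_low is not None and self.ci_high is not None
                and not self.ci_low < self.ci_high):
            out.append("ci_low must be < ci_high")
        if self.range_width is not None and self.range_width <= 0:
            out.append("range_width must be positive")
        for name in ("events_somnolence", "events_eps", "deaths", "dropouts"):
            v = getattr(self, name)
            if v is None:
                continue
            if v < 0:
                out.append(f"{name} negative")
            elif self.n is not None and v > self.n:
                out.append(f"{name} ({v}) exceeds arm n ({self.n})")
        return out


@dataclass
class TrialRecord:
    """One trial: design characteristics plus its two aggregate arms.

    Multi-dose or multi-drug antipsychotic arms are pre-combined into a
    single ``drug`` arm (see :func:`runinmeta.effect_sizes.combine_arms`).
    """

    trial_id: str
    year: int
    drug_class: str
    drug_names: list[str]
    setting: str
    symptom: str
    run_in: RunInSpec
    n_randomized: int
    drug: ArmOutcome
    placebo: ArmOutcome
    instrument: Optional[str] = None

    def problems(self) -> list[str]:
        out = []
        if self.drug_class not in DRUG_CLASSES:
            out.append(f"unknown drug_class {self.drug_class!r}")
        if self.setting not in SETTINGS:
            out.append(f"unknown setting {self.setting!r}")
        if self.symptom not in SYMPTOMS:
            out.append(f"unknown symptom {self.symptom!r}")
        if self.n_randomized < 1:
            out.append("n_randomized must be positive")
        if self.drug.n is not None and self.placebo.n is not None:
            if self.drug.n + self.placebo.n != self.n_randomized:
                out.append(
                    f"arm sizes {self.drug.n}+{self.placebo.n} != "
                    f"n_randomized {self.n_randomized}")
        if self.drug_class == "both":
            names = set(self.drug_names)
            if not (names & CONVENTIONAL_DRUGS and names & ATYPICAL_DRUGS):
                out.append("drug_class 'both' requires a conventional and an "
                           "atypical drug name")
        out.extend(self.run_in.problems())
        for arm, tag in ((self.drug, "drug"), (self.placebo, "plc")):
            out.extend(f"{tag}: {msg}" for msg in arm.problems())
        return out


@dataclass
class TrialSet:
    """An ordered collection of trials with unique ids."""

    trials: list[TrialRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialRecord]:
        return iter(self.trials)

    def __getitem__(self, key):
        if isinstance(key, str):
            for t in self.trials:
                if t.trial_id == key:
                    return t
            raise KeyError(key)
        return self.trials[key]

    def problems(self) -> list[str]:
        out = []
        seen: set[str] = set()
        for t in self.trials:
            if t.trial_id in seen:
                out.append(f"duplicate trial_id {t.trial_id!r}")
            seen.add(t.trial_id)
            out.extend(f"{t.trial_id}: {msg}" for msg in t.problems())
        return out

    def validate(self) -> None:
        probs = self.problems()
        if probs:
            raise ValidationError("; ".join(probs))


# ---------------------------------------------------------------------------
# CSV (de)serialization

def _parse(value: str, kind: str, column: str, line: int):
    value = value.strip()
    if value == "":
        return None
    try:
        if kind == "int":
            return int(value)
        if kind == "float":
            return float(value)
        if kind == "bool":
            if value.lower() in ("yes", "true", "1"):
                return True
            if value.lower() in ("no", "false", "0"):
                return False
            raise ValueError(value)
        return value
    except ValueError as exc:
        raise TrialDataError(
            f"line {line}: cannot parse column {column!r} value {value!r}"
        ) from exc


_ARM_FIELDS = (
    ("n", "int"), ("mean_change", "float"), ("sd_change", "float"),
    ("p_between", "float"), ("ci_low", "float"), ("ci_high", "float"),
    ("range_width", "float"), ("somnolence", "int"), ("eps", "int"),
    ("deaths", "int"), ("dropouts", "int"),
)

_ARM_ATTR = {
    "n": "n", "mean_change": "mean_change", "sd_change": "sd_change",
    "p_between": "p_value_between", "ci_low": "ci_low", "ci_high": "ci_high",
    "range_width": "range_width", "somnolence": "events_somnolence",
    "eps": "events_eps", "deaths": "deaths", "dropouts": "dropouts",
}


def _row_to_trial(row: dict, line: int) -> TrialRecord:
    def get(col, kind):
        return _parse(row.get(col, ""), kind, col, line)

    arms = {}
    for prefix, label in (("drug", "antipsychotic"), ("plc", "placebo")):
        kwargs = {}
        for col, kind in _ARM_FIELDS:
            kwargs[_ARM_ATTR[col]] = get(f"{prefix}_{col}", kind)
        arms[prefix] = ArmOutcome(arm_label=label, **kwargs)

    run_in = RunInSpec(
        present=bool(get("run_in_present", "bool")),
        replacement=get("replacement", "str") or "none",
        duration_days=get("duration_days", "int"),
        duration_approximate=bool(get("duration_approximate", "bool")),
        pct_excluded_after_runin=get("pct_excluded_after_runin", "float"),
    )
    names = get("drug_names", "str") or ""
    return TrialRecord(
        trial_id=get("trial_id", "str") or "",
        year=get("year", "int") or 0,
        drug_class=get("drug_class", "str") or "",
        drug_names=[s for s in names.split(";") if s],
        setting=get("setting", "str") or "not_reported",
        symptom=get("symptom", "str") or "diverse",
        instrument=get("instrument", "str"),
        run_in=run_in,
        n_randomized=get("n_randomized", "int") or 0,
        drug=arms["drug"],
        placebo=arms["plc"],
    )


def read_trials_csv(path, strict: bool = True) -> TrialSet:
    """Read a trial table from CSV.

    With ``strict=True`` any schema or invariant violation raises; with
    ``strict=False`` offending rows are dropped with a logged warning and
    the remainder returned.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing columns: {', '.join(missing)}")
        trials: list[TrialRecord] = []
        dropped = 0
        for line, row in enumerate(reader, start=2):
            try:
                trial = _row_to_trial(row, line)
                probs = trial.problems()
                if probs:
                    raise ValidationError(
                        f"{trial.trial_id or f'line {line}'}: "
                        + "; ".join(probs))
            except TrialDataError:
                if strict:
                    raise
                dropped += 1
                logger.warning("dropping invalid row at line %d", line,
                               exc_info=True)
                continue
            trials.append(trial)
    ts = TrialSet(trials=trials, provenance=str(path))
    if strict:
        ts.validate()
    elif dropped:
        logger.warning("dropped %d invalid rows from %s", dropped, path)
    return ts


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_trials_csv(trials: TrialSet, path) -> None:
    """Write a trial table to CSV; missing values become empty cells.

    Round-trips: ``read_trials_csv(write_trials_csv(x))`` reproduces ``x``
    field for field.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for t in trials:
            row = [
                t.trial_id, t.year, t.drug_class, ";".join(t.drug_names),
                t.setting, t.symptom, t.instrument,
                t.run_in.present, t.run_in.replacement,
                t.run_in.duration_days, t.run_in.duration_approximate,
                t.run_in.pct_excluded_after_runin, t.n_randomized,
            ]
            for arm in (t.drug, t.placebo):
                row.extend(getattr(arm, _ARM_ATTR[col]) for col, _ in _ARM_FIELDS)
            writer.writerow([_fmt(v) for v in row])


def load_table1() -> TrialSet:
    """Load the packaged fixture of 35 trial design characteristics."""
    ref = resources.files(__package__) / "fixtures" / FIXTURE_NAME
    with resources.as_file(ref) as path:
        ts = read_trials_csv(path, strict=True)
    ts.provenance = "packaged fixture: design characteristics of 35 trials"
    return ts


# ---------------------------------------------------------------------------
# Filters

def _by_class(t: TrialRecord, cls: str, include_combined: bool = True) -> bool:
    if cls not in ("conventional", "atypical"):
        raise ValueError(f"unknown drug class {cls!r}")
    if include_combined:
        return t.drug_class in (cls, "both")
    return t.drug_class == cls


_FILTERS = {
    "by_class": _by_class,
    "by_run_in_presence": lambda t, present: t.run_in.present == present,
    "by_replacement": lambda t, replacement: t.run_in.replacement == replacement,
    "by_duration_cutoff": lambda t, max_days: (
        t.run_in.present and t.run_in.duration_days is not None
        and t.run_in.duration_days <= max_days),
    "exclude_combined_class": lambda t: t.drug_class != "both",
    "exclude_drug_name": lambda t, drug: drug not in t.drug_names,
}


def filter_trials(trials: TrialSet, name: str, **params) -> TrialSet:
    """Return the subset of trials passing a named design filter.

    Valid names: ``by_class`` (class subsets; trials testing both a
    conventional and an atypical drug count toward both classes unless
    ``include_combined=False``), ``by_run_in_presence``, ``by_replacement``,
    ``by_duration_cutoff`` (run-in duration <= ``max_days``),
    ``exclude_combined_class``, ``exclude_drug_name``.
    """
    try:
        pred = _FILTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown filter {name!r}; valid: {', '.join(sorted(_FILTERS))}"
        ) from None
    kept = [t for t in trials if pred(t, **params)]
    return TrialSet(trials=kept,
                    provenance=f"{trials.provenance} | {name}({params})")


def summarize_characteristics(trials: TrialSet) -> dict:
    """Tabulate design characteristics of a trial set.

    Returns counts of trials by drug class, run-in presence, replacement
    type and duration stratum (<=7 vs >7 days), run-in presence within each
    class, and the min/max of the post-run-in exclusion fraction over
    trials reporting it.
    """
    if len(trials) == 0:
        raise ValueError("empty trial set")
    by_class = {c: 0 for c in DRUG_CLASSES}
    by_replacement = {r: 0 for r in REPLACEMENTS}
    runin_by_class = {c: 0 for c in DRUG_CLASSES}
    duration = {"le_1_week": 0, "gt_1_week": 0, "missing": 0}
    n_runin = 0
    excl = []
    for t in trials:
        by_class[t.drug_class] += 1
        if t.run_in.present:
            n_runin += 1
            runin_by_class[t.drug_class] += 1
            by_replacement[t.run_in.replacement] += 1
            d = t.run_in.duration_days
            if d is None:
                duration["missing"] += 1
            elif d <= 7:
                duration["le_1_week"] += 1
            else:
                duration["gt_1_week"] += 1
        if t.run_in.pct_excluded_after_runin is not None:
            excl.append(t.run_in.pct_excluded_after_runin)
    return {
        "n_trials": len(trials),
        "run_in_present": n_runin,
        "run_in_absent": len(trials) - n_runin,
        "by_class": by_class,
        "run_in_by_class": runin_by_class,
        "replacement": by_replacement,
        "duration": duration,
        "pct_excluded_min": min(excl) if excl else None,
        "pct_excluded_max": max(excl) if excl else None,
        "pct_excluded_reported": len(excl),
    }
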