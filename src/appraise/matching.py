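"""Patient-trial eligibility matching, the L1-L4 pooling ladder, and PICO assembly.

The ladder relaxes matching and broadens grouping as the level rises:

========  ============  ==========
level     strictness    grouping
========  ============  ==========
L1        strict        drug+dose
L2        strict        drug
L3        relaxed       drug
L4        minimal       drug_class
========  ============  ==========

Strict enforces every structured criterion; relaxed keeps the pediatric/adult
age band plus excluded comorbidities; minimal keeps the age band only. Every
level's pair can be overridden in config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .corpus import ADULT_AGE, EvidenceCorpus, PatientProfile, TrialRecord
from .preferences import CriticalPreferenceSet

Strictness = Literal["strict", "relaxed", "minimal"]
Grouping = Literal["drug+dose", "drug", "drug_class"]

_STRICTNESS_ORDER = {"strict": 2, "relaxed": 1, "minimal": 0}


@dataclass(frozen=True)
class PoolingLevel:
    level: str
    eligibility_strictness: Strictness
    grouping: Grouping


DEFAULT_LEVELS: dict[str, PoolingLevel] = {
    "L1": PoolingLevel("L1", "strict", "drug+dose"),
    "L2": PoolingLevel("L2", "strict", "drug"),
    "L3": PoolingLevel("L3", "relaxed", "drug"),
    "L4": PoolingLevel("L4", "minimal", "drug_class"),
}


def get_level(level: str | PoolingLevel, overrides: Optional[dict] = None) -> PoolingLevel:
    if isinstance(level, PoolingLevel):
        return level
    if overrides and level in overrides:
        spec = overrides[level]
        return PoolingLevel(level, spec["strictness"], spec["grouping"])
    try:
        return DEFAULT_LEVELS[level]
    except KeyError:
        raise ValueError(f"unknown pooling level {level!r}") from None


@dataclass(frozen=True)
class PICOQuestion:
    """Patient / interventions / placebo comparator / critical outcomes."""

    patient_id: str
    interventions: frozenset[str]
    outcomes: CriticalPreferenceSet
    level: str
    comparator: str = "placebo"
    no_critical_preferences: bool = False


def _age_band(age: int) -> str:
    return "adult" if age >= ADULT_AGE else "pediatric"


def _trial_age_bands(trial: TrialRecord) -> set[str]:
    bands = set()
    if trial.eligibility.age_min < ADULT_AGE:
        bands.add("pediatric")
    if trial.eligibility.age_max >= ADULT_AGE:
        bands.add("adult")
    return bands


def check_eligibility(
    patient: PatientProfile, trial: TrialRecord, strictness: Strictness
) -> tuple[bool, list[str]]:
    """Apply the trial's criteria at the given strictness; reasons list every failure."""
    e = trial.eligibility
    reasons: list[str] = []

    # age band applies at every strictness
    if _age_band(patient.age) not in _trial_age_bands(trial):
        reasons.append(f"age band {_age_band(patient.age)} outside trial range {e.age_min}-{e.age_max}")

    if _STRICTNESS_ORDER[strictness] >= 1:
        overlap = patient.comorbidities & e.excluded_comorbidities
        if overlap:
            reasons.append(f"excluded comorbidities present: {sorted(overlap)}")

    if strictness == "strict":
        if not (e.age_min <= patient.age <= e.age_max):
            if not reasons or "age band" not in reasons[0]:
                reasons.append(f"age {patient.age} outside trial range {e.age_min}-{e.age_max}")
        if patient.sex not in e.sexes_allowed:
            reasons.append(f"sex {patient.sex} not allowed")
        cotreat = patient.current_treatments & e.excluded_cotreatments
        if cotreat:
            reasons.append(f"excluded co-treatments present: {sorted(cotreat)}")
        if e.min_severity is not None and patient.symptom_severity < e.min_severity:
            reasons.append(
                f"severity {patient.symptom_severity} below trial minimum {e.min_severity}"
            )
    return (not reasons, reasons)


def group_key(trial: TrialRecord, grouping: Grouping) -> str:
    if grouping == "drug+dose":
        return f"{trial.drug}@{trial.dose_bucket()}"
    if grouping == "drug":
        return trial.drug
    if grouping == "drug_class":
        return trial.drug_class
    raise ValueError(f"unknown grouping {grouping!r}")


def select_trials(
    patient: PatientProfile,
    corpus: EvidenceCorpus,
    level: str | PoolingLevel = "L3",
    overrides: Optional[dict] = None,
) -> dict[str, list[TrialRecord]]:
    """Eligible trials grouped by the level's key; empty groups are omitted."""
    lvl = get_level(level, overrides)
    groups: dict[str, list[TrialRecord]] = {}
    for trial in corpus.trials:
        ok, _ = check_eligibility(patient, trial, lvl.eligibility_strictness)
        if ok:
            groups.setdefault(group_key(trial, lvl.grouping), []).append(trial)
    return groups


def build_pico(
    patient: PatientProfile,
    critical_set: CriticalPreferenceSet,
    corpus: EvidenceCorpus,
    level: str | PoolingLevel = "L3",
    overrides: Optional[dict] = None,
) -> PICOQuestion:
    """Assemble the PICO question; an empty critical set yields a typed marker."""
    lvl = get_level(level, overrides)
    if len(critical_set) == 0:
        return PICOQuestion(
            patient_id=patient.patient_id,
            interventions=frozenset(),
            outcomes=critical_set,
            level=lvl.level,
            no_critical_preferences=True,
        )
    groups = select_trials(patient, corpus, lvl)
    return PICOQuestion(
        patient_id=patient.patient_id,
        interventions=frozenset(groups),
        outcomes=critical_set,
        level=lvl.level,
    )
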