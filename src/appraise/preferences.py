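"""Criticality thresholding of 1-9 preference ratings and the two combination rules.

A preference is *critical* when rated at or above the threshold (default 7).
The *comprehensive* combination keeps every preference either rater marked
critical (set union); the *conjoint* combination keeps only preferences both
raters marked critical (set intersection). A conjoint combination may be empty,
in which case the engine yields no recommendation downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .corpus import OutcomeCatalogue, PatientCase, RatingRecord

CRITICAL_THRESHOLD = 7

CombinationMode = Literal["comprehensive", "conjoint"]


@dataclass(frozen=True)
class CriticalPreferenceSet:
    """Critical outcome ids for one rater or one combination rule."""

    label: str  # patient | clinician | comprehensive | conjoint
    outcome_ids: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.outcome_ids)

    def __contains__(self, outcome_id: str) -> bool:
        return outcome_id in self.outcome_ids


def mark_critical(
    ratings: Iterable[RatingRecord],
    threshold: int = CRITICAL_THRESHOLD,
    max_critical: int | None = None,
) -> dict[str, CriticalPreferenceSet]:
    """Split ratings by rater and keep outcomes scored at or above ``threshold``.

    Returns one :class:`CriticalPreferenceSet` per rater present in the input.
    Duplicate (rater, outcome) pairs are rejected. ``max_critical`` is advisory:
    exceeding it emits a warning but does not truncate.
    """
    by_rater: dict[str, dict[str, int]] = {}
    for r in ratings:
        seen = by_rater.setdefault(r.rater, {})
        if r.outcome_id in seen:
            raise ValueError(f"duplicate rating for ({r.rater}, {r.outcome_id})")
        seen[r.outcome_id] = r.score
    out = {}
    for rater, scores in by_rater.items():
        crit = frozenset(oid for oid, s in scores.items() if s >= threshold)
        if max_critical is not None and len(crit) > max_critical:
            warnings.warn(
                f"{rater}: {len(crit)} critical preferences exceed advisory cap {max_critical}"
            )
        if not crit:
            warnings.warn(f"{rater}: no preference rated critical (threshold {threshold})")
        out[rater] = CriticalPreferenceSet(label=rater, outcome_ids=crit)
    return out


def combine_preferences(
    patient_set: CriticalPreferenceSet,
    clinician_set: CriticalPreferenceSet,
    mode: CombinationMode,
) -> CriticalPreferenceSet:
    """Union (comprehensive) or intersection (conjoint) of the two critical sets."""
    if mode == "comprehensive":
        ids = patient_set.outcome_ids | clinician_set.outcome_ids
    elif mode == "conjoint":
        ids = patient_set.outcome_ids & clinician_set.outcome_ids
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return CriticalPreferenceSet(label=mode, outcome_ids=frozenset(ids))


def critical_sets_for_case(
    case: PatientCase, threshold: int = CRITICAL_THRESHOLD
) -> dict[str, CriticalPreferenceSet]:
    """Per-rater and per-mode critical sets for one case.

    Missing ratings were flagged at load time and count as non-critical.
    """
    sets = mark_critical(case.ratings, threshold=threshold)
    patient = sets.get("patient", CriticalPreferenceSet(label="patient"))
    clinician = sets.get("clinician", CriticalPreferenceSet(label="clinician"))
    return {
        "patient": patient,
        "clinician": clinician,
        "comprehensive": combine_preferences(patient, clinician, "comprehensive"),
        "conjoint": combine_preferences(patient, clinician, "conjoint"),
    }


def preference_summary(
    cohort: Iterable[PatientCase],
    threshold: int = CRITICAL_THRESHOLD,
    catalogue: OutcomeCatalogue | None = None,
) -> pd.DataFrame:
    """Mean critical-set sizes and distinct-combination counts across a cohort.

    One row per label (patient, clinician, comprehensive, conjoint) with the
    mean set size and the number of distinct critical-preference combinations.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    rows = []
    per_label: dict[str, list[frozenset[str]]] = {
        "patient": [], "clinician": [], "comprehensive": [], "conjoint": []
    }
    for case in cohort:
        sets = critical_sets_for_case(case, threshold=threshold)
        for label in per_label:
            per_label[label].append(sets[label].outcome_ids)
    for label, sets_list in per_label.items():
        sizes = [len(s) for s in sets_list]
        rows.append(
            {
                "label": label,
                "n_cases": len(cohort),
                "mean_size": sum(sizes) / len(sizes),
                "distinct_combinations": len(set(sets_list)),
            }
        )
    return pd.DataFrame(rows)
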