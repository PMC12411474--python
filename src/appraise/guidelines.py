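"""Declarative encodings of clinical-practice-guideline recommenders.

Rulesets are shipped as editable YAML (first matching rule wins; a catch-all
makes every ruleset total). Fidelity to the source guidelines is approximate
and versioned. Only "in favor" recommendations are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .corpus import PatientProfile

BUNDLED_GUIDELINES = ("AAP", "NICE", "SHS", "CADDRA", "AADPA")


@dataclass(frozen=True)
class RuleCondition:
    age_min: Optional[int] = None
    age_max: Optional[int] = None
    any_comorbidity: frozenset[str] = frozenset()
    any_prior_failure: frozenset[str] = frozenset()

    def matches(self, patient: PatientProfile) -> bool:
        if self.age_min is not None and patient.age < self.age_min:
            return False
        if self.age_max is not None and patient.age > self.age_max:
            return False
        if self.any_comorbidity and not (patient.comorbidities & self.any_comorbidity):
            return False
        if self.any_prior_failure and not (patient.history_failures & self.any_prior_failure):
            return False
        return True


@dataclass(frozen=True)
class GuidelineRule:
    rule_id: str
    condition: RuleCondition
    recommend: frozenset[str]


@dataclass(frozen=True)
class GuidelineRuleset:
    guideline_id: str
    version: str
    rules: tuple[GuidelineRule, ...] = field(default_factory=tuple)


def parse_ruleset(data: dict) -> GuidelineRuleset:
    rules = []
    for raw in data["rules"]:
        when = raw.get("when") or {}
        rules.append(
            GuidelineRule(
                rule_id=raw["id"],
                condition=RuleCondition(
                    age_min=when.get("age_min"),
                    age_max=when.get("age_max"),
                    any_comorbidity=frozenset(when.get("any_comorbidity", [])),
                    any_prior_failure=frozenset(when.get("any_prior_failure", [])),
                ),
                recommend=frozenset(raw.get("recommend", [])),
            )
        )
    return GuidelineRuleset(
        guideline_id=data["guideline_id"], version=str(data.get("version", "")), rules=tuple(rules)
    )


def load_ruleset(source: str | Path) -> GuidelineRuleset:
    """Load a ruleset by bundled id (e.g. ``NICE``) or from a YAML file path."""
    if isinstance(source, str) and source.upper() in BUNDLED_GUIDELINES:
        text = (
            resources.files("appraise.data")
            .joinpath(f"guidelines/{source.lower()}.yaml")
            .read_text()
        )
    else:
        text = Path(source).read_text()
    return parse_ruleset(yaml.safe_load(text))


def load_bundled_rulesets() -> dict[str, GuidelineRuleset]:
    return {gid: load_ruleset(gid) for gid in BUNDLED_GUIDELINES}


def apply_guideline(patient: PatientProfile, ruleset: GuidelineRuleset) -> frozenset[str]:
    """First matching rule wins; an empty set arises only from an explicit rule."""
    for rule in ruleset.rules:
        if rule.condition.matches(patient):
            return rule.recommend
    raise ValueError(
        f"{ruleset.guideline_id}: no rule matches patient {patient.patient_id}; "
        "ruleset must be total"
    )
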