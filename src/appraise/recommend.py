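"""Risk-benefit judgment, recommendation direction/strength, and the therapeutic report.

The rule of thumb: an intervention is *favorable* against placebo when it
improves a strict majority of the critical efficacy outcomes and does not
increase the risk of any critical safety outcome or of treatment
discontinuation; it is *unfavorable* when it fails that majority and increases
at least one such risk; everything else is *neutral* (neither favorable nor
unfavorable). Judgment quality is the minimum outcome-level quality among the
critical outcomes with evidence, mapped onto a three-rung scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .corpus import EvidenceCorpus, OutcomeDefinition, PatientCase
from .matching import PICOQuestion, build_pico, get_level, select_trials
from .meta import (
    GradeConfig,
    MetaAnalysisResult,
    Model,
    OutcomeNotMeasured,
    arm_effect,
    grade_quality,
    pool_effects,
)
from .preferences import CombinationMode, critical_sets_for_case

Verdict = Literal["improves", "worsens", "inconclusive"]
Judgment = Literal["favorable", "unfavorable", "neutral"]
JudgmentQuality = Literal["high", "moderate", "low"]
Direction = Literal["for", "against", "none"]
Strength = Literal["strong", "weak", "not_applicable"]

_JUDGMENT_QUALITY_MAP = {"high": "high", "moderate": "moderate", "low": "low", "very_low": "low"}
_QUALITY_RANK = {"high": 3, "moderate": 2, "low": 1, "very_low": 0}


@dataclass(frozen=True)
class OutcomeVerdict:
    outcome_id: str
    kind: Literal["efficacy", "safety", "discontinuation"]
    verdict: Verdict
    result: Optional[MetaAnalysisResult] = None


@dataclass(frozen=True)
class RiskBenefitJudgment:
    group_key: str
    judgment: Judgment
    judgment_quality: Optional[JudgmentQuality]
    verdicts: tuple[OutcomeVerdict, ...] = ()
    insufficient_evidence: bool = False


@dataclass(frozen=True)
class Recommendation:
    target: str  # drug code or drug class, per the pooling level
    direction: Direction
    strength: Strength
    judgment: RiskBenefitJudgment


def classify_outcome_effect(
    result: MetaAnalysisResult, outcome: OutcomeDefinition
) -> OutcomeVerdict:
    """Verdict from the 95% CI after orienting by the outcome's benefit direction."""
    lo, hi = result.pooled.ci_low, result.pooled.ci_high
    if outcome.scale == "continuous":
        benefit_above_null = outcome.benefit_direction == "increase-is-good"
    else:
        benefit_above_null = not outcome.event_is_harm
    if benefit_above_null:
        improves, worsens = lo > 0, hi < 0
    else:
        # decrease-is-good, or harm events on the log-OR scale: benefit below null
        improves, worsens = hi < 0, lo > 0
    verdict: Verdict = "improves" if improves else ("worsens" if worsens else "inconclusive")
    return OutcomeVerdict(
        outcome_id=result.outcome_id, kind=outcome.kind, verdict=verdict, result=result
    )


def judge_risk_benefit(
    verdicts: Sequence[OutcomeVerdict], group_key: str = ""
) -> RiskBenefitJudgment:
    """Apply the favorable/unfavorable/neutral rule over the verdict set."""
    efficacy = [v for v in verdicts if v.kind == "efficacy"]
    harms = [v for v in verdicts if v.kind in ("safety", "discontinuation")]

    if not efficacy:
        return RiskBenefitJudgment(
            group_key=group_key,
            judgment="neutral",
            judgment_quality=_judgment_quality(verdicts),
            verdicts=tuple(verdicts),
            insufficient_evidence=True,
        )

    n_improve = sum(1 for v in efficacy if v.verdict == "improves")
    majority_improved = n_improve * 2 > len(efficacy)  # strict majority; ties fail
    any_harm_worsens = any(v.verdict == "worsens" for v in harms)

    if majority_improved and not any_harm_worsens:
        judgment: Judgment = "favorable"
    elif not majority_improved and any_harm_worsens:
        judgment = "unfavorable"
    else:
        judgment = "neutral"
    return RiskBenefitJudgment(
        group_key=group_key,
        judgment=judgment,
        judgment_quality=_judgment_quality(verdicts),
        verdicts=tuple(verdicts),
    )


def _judgment_quality(verdicts: Sequence[OutcomeVerdict]) -> Optional[JudgmentQuality]:
    qualities = [v.result.quality for v in verdicts if v.result is not None and v.result.quality]
    if not qualities:
        return None
    worst = min(qualities, key=lambda q: _QUALITY_RANK[q])
    return _JUDGMENT_QUALITY_MAP[worst]


def derive_recommendation(judgment: RiskBenefitJudgment) -> Recommendation:
    """Map judgment x quality onto direction and strength."""
    direction: Direction = {"favorable": "for", "unfavorable": "against", "neutral": "none"}[
        judgment.judgment
    ]
    if direction == "none":
        strength: Strength = "not_applicable"
    elif judgment.judgment_quality in ("high", "moderate"):
        strength = "strong"
    else:
        strength = "weak"
    return Recommendation(
        target=judgment.group_key, direction=direction, strength=strength, judgment=judgment
    )


# ---------------------------------------------------------------------------
# engine


@dataclass
class EngineRun:
    """Everything the engine produced for one patient at one mode/level."""

    case_id: str
    mode: CombinationMode
    level: str
    pico: PICOQuestion
    results: list[MetaAnalysisResult] = field(default_factory=list)
    recommendations: list[Recommendation] = field(default_factory=list)
    no_critical_preferences: bool = False

    @property
    def favorable_set(self) -> frozenset[str]:
        return frozenset(r.target for r in self.recommendations if r.direction == "for")

    @property
    def against_set(self) -> frozenset[str]:
        return frozenset(r.target for r in self.recommendations if r.direction == "against")


def run_engine(
    case: PatientCase,
    corpus: EvidenceCorpus,
    mode: CombinationMode = "comprehensive",
    level: str = "L3",
    model: Model = "random",
    grade_config: GradeConfig = GradeConfig(),
    threshold: int = 7,
    level_overrides: Optional[dict] = None,
) -> EngineRun:
    """Full pipeline for one patient: critical set -> PICO -> meta-analyses ->
    judgments -> recommendations."""
    critical = critical_sets_for_case(case, threshold=threshold)[mode]
    lvl = get_level(level, level_overrides)
    pico = build_pico(case.profile, critical, corpus, lvl)
    run = EngineRun(
        case_id=case.case_id,
        mode=mode,
        level=lvl.level,
        pico=pico,
        no_critical_preferences=pico.no_critical_preferences,
    )
    if pico.no_critical_preferences:
        return run

    groups = select_trials(case.profile, corpus, lvl)
    # discontinuation is always checked when data exist, critical or not
    outcome_ids = list(critical.outcome_ids)
    for o in corpus.catalogue.by_kind("discontinuation"):
        if o.outcome_id not in outcome_ids:
            outcome_ids.append(o.outcome_id)

    for key in sorted(groups):
        trials = groups[key]
        verdicts: list[OutcomeVerdict] = []
        for oid in sorted(outcome_ids):
            outcome = corpus.catalogue[oid]
            effects, used_trials = [], []
            for trial in trials:
                try:
                    effects.append(arm_effect(trial, outcome))
                    used_trials.append(trial)
                except OutcomeNotMeasured:
                    continue
            if not effects:
                continue  # excluded from the majority denominator, noted in the report
            result = pool_effects(
                effects,
                model=model,
                group_key=key,
                outcome_id=oid,
                study_ids=[t.trial_id for t in used_trials],
            )
            result = grade_quality(result, used_trials, grade_config)
            run.results.append(result)
            verdicts.append(classify_outcome_effect(result, outcome))
        critical_verdicts = [
            v for v in verdicts if v.outcome_id in critical or v.kind == "discontinuation"
        ]
        judgment = judge_risk_benefit(critical_verdicts, group_key=key)
        run.recommendations.append(derive_recommendation(judgment))
    return run


# ---------------------------------------------------------------------------
# therapeutic report


_DIRECTION_ORDER = {"for": 0, "against": 1, "none": 2}
_STRENGTH_ORDER = {"strong": 0, "weak": 1, "not_applicable": 2}


def render_report(run: EngineRun, corpus: EvidenceCorpus, fmt: str = "markdown") -> str:
    """Explanatory report: one section per intervention x critical outcome with
    evidence, then the recommendation list sorted by direction then strength.

    Deterministic: regenerating from the same run yields identical bytes.
    """
    recs = sorted(
        run.recommendations,
        key=lambda r: (_DIRECTION_ORDER[r.direction], _STRENGTH_ORDER[r.strength], r.target),
    )
    if fmt == "json":
        doc = {
            "case_id": run.case_id,
            "mode": run.mode,
            "level": run.level,
            "no_critical_preferences": run.no_critical_preferences,
            "sections": [
                {
                    "intervention": res.group_key,
                    "outcome_id": res.outcome_id,
                    "measure": res.pooled.measure,
                    "pooled": round(res.pooled.value, 4),
                    "ci": [round(res.pooled.ci_low, 4), round(res.pooled.ci_high, 4)],
                    "k": res.k,
                    "I2": round(res.I2, 1),
                    "quality": res.quality,
                    "downgrades": [
                        {"reason": d.reason, "points": d.points} for d in res.downgrades
                    ],
                }
                for res in sorted(run.results, key=lambda r: (r.group_key, r.outcome_id))
            ],
            "recommendations": [
                {"target": r.target, "direction": r.direction, "strength": r.strength,
                 "judgment_quality": r.judgment.judgment_quality}
                for r in recs
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    lines = [f"# Therapeutic report — case {run.case_id} ({run.mode}, {run.level})", ""]
    if run.no_critical_preferences:
        lines += ["No critical preference was selected by both raters under this mode;",
                  "no recommendation can be generated.", ""]
        return "\n".join(lines)
    if not run.recommendations:
        lines += ["No eligible trials were found for this patient;",
                  "no recommendation can be generated.", ""]
        return "\n".join(lines)
    lines.append("## Evidence by intervention and critical preference")
    for res in sorted(run.results, key=lambda r: (r.group_key, r.outcome_id)):
        outcome = corpus.catalogue[res.outcome_id]
        dg = ", ".join(f"{d.reason} (-{d.points})" for d in res.downgrades) or "none"
        lines.append(
            f"- **{res.group_key} / {outcome.label}**: {res.pooled.measure} "
            f"{res.pooled.value:.3f} (95% CI {res.pooled.ci_low:.3f} to "
            f"{res.pooled.ci_high:.3f}), k={res.k}, I²={res.I2:.1f}%, "
            f"quality={res.quality}, downgrades: {dg}"
        )
    lines += ["", "## Recommendations"]
    for r in recs:
        label = {
            ("for", "strong"): "strongly in favor",
            ("for", "weak"): "weakly in favor",
            ("against", "strong"): "strongly against",
            ("against", "weak"): "weakly against",
        }.get((r.direction, r.strength), "no recommendation")
        lines.append(f"- {r.target}: {label} (judgment quality: {r.judgment.judgment_quality})")
    lines.append("")
    return "\n".join(lines)
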