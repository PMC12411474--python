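"""Per-group, per-outcome meta-analysis and GRADE-style quality rating.

Continuous outcomes are pooled as standardized mean differences with the
small-sample (Hedges) correction; dichotomous outcomes as log odds ratios with
a 0.5 continuity correction when any cell is zero. Pooling is inverse-variance;
the random-effects model uses the DerSimonian-Laird between-study variance
tau^2 = max(0, (Q - df) / C).

Quality starts at "high" (4 points) and is downgraded for risk of bias,
heterogeneity, and imprecision; the floor is "very_low".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

from scipy import stats

from .corpus import OutcomeDefinition, TrialRecord

Measure = Literal["SMD", "logOR"]
Model = Literal["fixed", "random"]
Quality = Literal["high", "moderate", "low", "very_low"]

_QUALITY_BY_POINTS = {4: "high", 3: "moderate", 2: "low", 1: "very_low"}

Z95 = stats.norm.ppf(0.975)


class OutcomeNotMeasured(Exception):
    """Marker: the trial does not report this outcome in both arms."""


@dataclass(frozen=True)
class EffectEstimate:
    measure: Measure
    value: float
    se: float
    n_total: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        object.__setattr__(self, "ci_low", self.value - Z95 * self.se)
        object.__setattr__(self, "ci_high", self.value + Z95 * self.se)


@dataclass(frozen=True)
class GradeConfig:
    """Thresholds for the three downgrade triggers."""

    high_rob_weight_fraction: float = 0.5
    i2_moderate: float = 50.0
    i2_severe: float = 75.0
    optimal_information_size: int = 400
    decision_threshold_smd: float = 0.5
    decision_threshold_logor: float = math.log(1.25)

    def decision_threshold(self, measure: Measure) -> float:
        return self.decision_threshold_smd if measure == "SMD" else self.decision_threshold_logor


@dataclass(frozen=True)
class Downgrade:
    reason: Literal["risk_of_bias", "heterogeneity", "imprecision"]
    points: int


@dataclass(frozen=True)
class MetaAnalysisResult:
    group_key: str
    outcome_id: str
    model: Model
    pooled: EffectEstimate
    k: int
    Q: float
    I2: float
    tau2: float
    study_ids: tuple[str, ...] = ()
    fixed_weights: tuple[float, ...] = ()
    quality: Optional[Quality] = None
    downgrades: tuple[Downgrade, ...] = ()


def arm_effect(trial: TrialRecord, outcome: OutcomeDefinition) -> EffectEstimate:
    """Intervention-vs-placebo effect for one trial and one outcome.

    Continuous: Hedges-corrected SMD with its usual large-sample variance,
    negative values favoring the intervention for decrease-is-good outcomes.
    Dichotomous: log odds ratio; 0.5 added to every cell when any cell is zero.
    """
    intervention, placebo = trial.intervention_arm, trial.placebo_arm
    if not (intervention.measures(outcome.outcome_id) and placebo.measures(outcome.outcome_id)):
        raise OutcomeNotMeasured(f"{trial.trial_id}: outcome {outcome.outcome_id} not in both arms")

    if outcome.scale == "continuous":
        s1, s0 = intervention.continuous[outcome.outcome_id], placebo.continuous[outcome.outcome_id]
        n1, n0 = intervention.n, placebo.n
        df = n1 + n0 - 2
        pooled_sd = math.sqrt(((n1 - 1) * s1.sd**2 + (n0 - 1) * s0.sd**2) / df)
        if pooled_sd == 0:
            raise ValueError(f"{trial.trial_id}: zero variance in both arms for {outcome.outcome_id}")
        j = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = j * (s1.mean - s0.mean) / pooled_sd
        var = (n1 + n0) / (n1 * n0) + g**2 / (2.0 * (n1 + n0))
        return EffectEstimate(measure="SMD", value=g, se=math.sqrt(var), n_total=n1 + n0)

    e1 = intervention.dichotomous[outcome.outcome_id].events
    e0 = placebo.dichotomous[outcome.outcome_id].events
    a, b = float(e1), float(intervention.n - e1)
    c, d = float(e0), float(placebo.n - e0)
    if 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(measure="logOR", value=log_or, se=se, n_total=intervention.n + placebo.n)


def heterogeneity_stats(
    effects: Sequence[EffectEstimate], pooled_fixed: float
) -> tuple[float, float, float]:
    """Cochran's Q, I^2 (percent, truncated at 0) and DerSimonian-Laird tau^2."""
    k = len(effects)
    if k < 2:
        return 0.0, 0.0, 0.0
    w = [1.0 / e.se**2 for e in effects]
    q = sum(wi * (e.value - pooled_fixed) ** 2 for wi, e in zip(w, effects))
    df = k - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return q, i2, tau2


def pool_effects(
    effects: Sequence[EffectEstimate],
    model: Model = "random",
    group_key: str = "",
    outcome_id: str = "",
    study_ids: Sequence[str] = (),
) -> MetaAnalysisResult:
    """Inverse-variance pooling; random effects via DerSimonian-Laird."""
    if not effects:
        raise ValueError("no effects to pool")
    measures = {e.measure for e in effects}
    if len(measures) > 1:
        raise ValueError(f"mixed effect measures: {sorted(measures)}")
    measure = effects[0].measure
    n_total = sum(e.n_total for e in effects)

    w_fixed = [1.0 / e.se**2 for e in effects]
    pooled_fixed = sum(wi * e.value for wi, e in zip(w_fixed, effects)) / sum(w_fixed)
    q, i2, tau2 = heterogeneity_stats(effects, pooled_fixed)

    if model == "fixed" or len(effects) == 1:
        value, se = pooled_fixed, math.sqrt(1.0 / sum(w_fixed))
        tau2_used = 0.0 if len(effects) == 1 else tau2
    elif model == "random":
        w_rand = [1.0 / (e.se**2 + tau2) for e in effects]
        value = sum(wi * e.value for wi, e in zip(w_rand, effects)) / sum(w_rand)
        se = math.sqrt(1.0 / sum(w_rand))
        tau2_used = tau2
    else:
        raise ValueError(f"unknown model {model!r}")

    return MetaAnalysisResult(
        group_key=group_key,
        outcome_id=outcome_id,
        model=model,
        pooled=EffectEstimate(measure=measure, value=value, se=se, n_total=n_total),
        k=len(effects),
        Q=q,
        I2=i2,
        tau2=tau2_used,
        study_ids=tuple(study_ids),
        fixed_weights=tuple(w_fixed),
    )


def grade_quality(
    result: MetaAnalysisResult,
    trials: Sequence[TrialRecord],
    config: GradeConfig = GradeConfig(),
) -> MetaAnalysisResult:
    """Attach a quality rating and its downgrade trail to a pooled result.

    Downgrades: risk of bias (-1 when more than the configured fraction of
    fixed-effect weight comes from high-risk trials), heterogeneity (-1 above
    the moderate I^2 threshold, -2 above the severe one), and imprecision
    (-1 when total n is below the optimal information size or when the CI
    crosses both the null and a decision threshold).
    """
    downgrades: list[Downgrade] = []

    if trials and result.fixed_weights:
        total_w = sum(result.fixed_weights)
        high_w = sum(
            w for w, t in zip(result.fixed_weights, trials) if t.risk_of_bias == "high"
        )
        if total_w > 0 and high_w / total_w > config.high_rob_weight_fraction:
            downgrades.append(Downgrade(reason="risk_of_bias", points=1))

    if result.I2 > config.i2_severe:
        downgrades.append(Downgrade(reason="heterogeneity", points=2))
    elif result.I2 > config.i2_moderate:
        downgrades.append(Downgrade(reason="heterogeneity", points=1))

    thr = config.decision_threshold(result.pooled.measure)
    ci_low, ci_high = result.pooled.ci_low, result.pooled.ci_high
    crosses_null = ci_low < 0.0 < ci_high
    crosses_threshold = ci_low < -thr or ci_high > thr
    if result.pooled.n_total < config.optimal_information_size or (
        crosses_null and crosses_threshold
    ):
        downgrades.append(Downgrade(reason="imprecision", points=1))

    points = max(1, 4 - sum(d.points for d in downgrades))
    return replace(result, quality=_QUALITY_BY_POINTS[points], downgrades=tuple(downgrades))
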