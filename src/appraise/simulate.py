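"""Seeded generators for evidence corpora and patient cohorts.

Everything is a pure function of (config, seed): arm summaries are drawn from
configured true effects (normal change scores for continuous outcomes,
binomial events for dichotomous ones), and preference scores come from a
discretized latent-normal model whose shared factor controls patient-clinician
agreement. Defaults mirror the cohort marginals and preference means the
engine is calibrated against.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats

from .corpus import (
    ArmSummary,
    ContinuousSummary,
    DichotomousSummary,
    DrugRegistry,
    EligibilityCriteria,
    EvidenceCorpus,
    OutcomeCatalogue,
    PatientCase,
    PatientProfile,
    RatingRecord,
    TrialRecord,
    default_catalogue,
    default_registry,
)

ELIGIBILITY_TEMPLATES = {
    "pediatric": dict(age_min=6, age_max=17),
    "adult": dict(age_min=18, age_max=65),
    "broad": dict(age_min=6, age_max=65),
}

#: latent correlation giving a union mean of 6.4 when each rater marks
#: 4.8 of 18 outcomes critical (solved from the bivariate-normal tail)
DEFAULT_AGREEMENT = 0.7754


class DrugTruth(BaseModel):
    """Configured ground truth for one drug's trials."""

    n_trials: int = 3
    n_per_arm: int = Field(default=50, ge=2)
    smd: dict[str, float] = Field(default_factory=dict)  # raw-scale SMD per continuous outcome
    odds_ratio: dict[str, float] = Field(default_factory=dict)  # per dichotomous outcome
    default_odds_ratio: float = 1.0
    baseline_risk: float = Field(default=0.10, gt=0, lt=1)
    change_sd: float = Field(default=10.0, gt=0)
    rob_mix: list[str] = Field(default_factory=lambda: ["some-concerns", "high", "low"])
    eligibility: str | dict = "broad"
    dose_options: Optional[list[float]] = None


class PatientModel(BaseModel):
    age_min: int = 6
    age_max: int = 17
    age_mean: float = 12.3
    age_sd: float = 3.0
    male_fraction: float = 0.656
    subtype_probs: dict[str, float] = Field(
        default_factory=lambda: {"inattentive": 0.219, "hyperactive": 0.0, "combined": 0.781}
    )
    severity_mean: float = 34.4
    severity_sd: float = 6.0
    comorbidity_probs: dict[str, float] = Field(
        default_factory=lambda: {"tics_disorder": 0.03, "epilepsy": 0.06, "anxiety_disorder": 0.19}
    )
    psychotherapy_fraction: float = 0.469


class PreferenceModel(BaseModel):
    critical_probability: float = Field(default=4.8 / 18, gt=0, lt=1)
    agreement: float = Field(default=DEFAULT_AGREEMENT, ge=0, le=1)
    ensure_efficacy_critical: bool = False


class SimulationConfig(BaseModel):
    drugs: dict[str, DrugTruth] = Field(default_factory=dict)
    n_patients: int = 32
    patients: PatientModel = Field(default_factory=PatientModel)
    preferences: PreferenceModel = Field(default_factory=PreferenceModel)


def _sample_continuous(
    rng: np.random.Generator, mu: float, sd: float, n: int
) -> ContinuousSummary:
    mean = rng.normal(mu, sd / math.sqrt(n))
    sample_sd = sd * math.sqrt(rng.chisquare(n - 1) / (n - 1))
    return ContinuousSummary(mean=mean, sd=max(sample_sd, 1e-6))


def _eligibility(spec: str | dict) -> EligibilityCriteria:
    if isinstance(spec, str):
        try:
            spec = ELIGIBILITY_TEMPLATES[spec]
        except KeyError:
            raise ValueError(f"unknown eligibility template {spec!r}") from None
    return EligibilityCriteria(**spec)


def generate_corpus(
    config: SimulationConfig,
    seed: int,
    catalogue: Optional[OutcomeCatalogue] = None,
    registry: Optional[DrugRegistry] = None,
) -> EvidenceCorpus:
    """Draw an evidence corpus from the configured truths; deterministic per seed."""
    rng = np.random.default_rng(seed)
    catalogue = catalogue or default_catalogue()
    registry = registry or default_registry()

    trials: list[TrialRecord] = []
    for drug in sorted(config.drugs):
        truth = config.drugs[drug]
        info = registry[drug]
        for i in range(truth.n_trials):
            arms = []
            for role in ("intervention", "placebo"):
                cont: dict[str, ContinuousSummary] = {}
                dich: dict[str, DichotomousSummary] = {}
                n = truth.n_per_arm
                for outcome in catalogue.outcomes:
                    oid = outcome.outcome_id
                    if outcome.scale == "continuous":
                        mu = truth.smd.get(oid, 0.0) * truth.change_sd if role == "intervention" else 0.0
                        cont[oid] = _sample_continuous(rng, mu, truth.change_sd, n)
                    else:
                        p0 = truth.baseline_risk
                        if p0 <= 0:
                            raise ValueError(f"{drug}/{oid}: odds ratio with zero baseline risk")
                        if role == "placebo":
                            p = p0
                        else:
                            odds = truth.odds_ratio.get(oid, truth.default_odds_ratio) * p0 / (1 - p0)
                            p = odds / (1 + odds)
                        dich[oid] = DichotomousSummary(events=int(rng.binomial(n, p)))
                arms.append(
                    ArmSummary(
                        arm_role=role,
                        drug=drug if role == "intervention" else "placebo",
                        dose_mg_per_day=(
                            truth.dose_options[i % len(truth.dose_options)]
                            if role == "intervention" and truth.dose_options
                            else None
                        ),
                        n=n,
                        continuous=cont,
                        dichotomous=dich,
                    )
                )
            trials.append(
                TrialRecord(
                    trial_id=f"{drug}-{i + 1:02d}",
                    drug=drug,
                    dose_mg_per_day=(
                        truth.dose_options[i % len(truth.dose_options)] if truth.dose_options else None
                    ),
                    drug_class=info.drug_class,
                    year=2015 + (i % 10),
                    risk_of_bias=truth.rob_mix[i % len(truth.rob_mix)],  # type: ignore[arg-type]
                    eligibility=_eligibility(truth.eligibility),
                    arms=arms,
                )
            )
    return EvidenceCorpus(catalogue=catalogue, registry=registry, trials=trials)


def _score_from_uniform(u: float, p_critical: float) -> int:
    """Map a latent uniform to a 1-9 score with P(score >= 7) = p_critical."""
    if u > 1 - p_critical:
        return min(9, 7 + int(3 * (u - (1 - p_critical)) / p_critical))
    return min(6, 1 + int(6 * u / (1 - p_critical)))


def generate_patients(
    config: SimulationConfig, seed: int, catalogue: Optional[OutcomeCatalogue] = None
) -> list[PatientCase]:
    """Draw a cohort of profiles plus patient and clinician ratings."""
    rng = np.random.default_rng(seed + 1)
    catalogue = catalogue or default_catalogue()
    pm, prefs = config.patients, config.preferences
    a = math.sqrt(prefs.agreement)  # loading on the shared latent factor

    subtypes = sorted(pm.subtype_probs)
    subtype_p = np.array([pm.subtype_probs[s] for s in subtypes])
    subtype_p = subtype_p / subtype_p.sum()

    cases = []
    for i in range(config.n_patients):
        age = int(round(np.clip(rng.normal(pm.age_mean, pm.age_sd), pm.age_min, pm.age_max)))
        comorbidities = {c for c, p in sorted(pm.comorbidity_probs.items()) if rng.random() < p}
        profile = PatientProfile(
            patient_id=f"P{i + 1:03d}",
            age=age,
            sex="male" if rng.random() < pm.male_fraction else "female",
            adhd_subtype=str(rng.choice(subtypes, p=subtype_p)),  # type: ignore[arg-type]
            symptom_severity=round(float(rng.normal(pm.severity_mean, pm.severity_sd)), 1),
            comorbidities=comorbidities,
            psychotherapy_flag=bool(rng.random() < pm.psychotherapy_fraction),
        )
        ratings = []
        for outcome in catalogue.outcomes:
            z_shared = rng.normal()
            for rater in ("patient", "clinician"):
                z = z_shared if prefs.agreement == 1.0 else (
                    a * z_shared + math.sqrt(1 - prefs.agreement) * rng.normal()
                )
                score = _score_from_uniform(float(stats.norm.cdf(z)), prefs.critical_probability)
                ratings.append(RatingRecord(outcome_id=outcome.outcome_id, rater=rater, score=score))
        case = PatientCase(profile=profile, ratings=ratings)
        if prefs.ensure_efficacy_critical:
            _ensure_efficacy_critical(case, catalogue)
        cases.append(case)
    return cases


def _ensure_efficacy_critical(case: PatientCase, catalogue: OutcomeCatalogue) -> None:
    """Force at least one critical efficacy preference for both raters (the
    elicitation guidance requires a minimum of one treatment goal)."""
    efficacy_ids = {o.outcome_id for o in catalogue.by_kind("efficacy")}
    for rater in ("patient", "clinician"):
        if any(r.score >= 7 for r in case.ratings_for(rater) if r.outcome_id in efficacy_ids):
            continue
        for r in case.ratings:
            if r.rater == rater and r.outcome_id == "adhd_symptoms":
                r.score = 9


# ---------------------------------------------------------------------------
# fixtures


FixtureName = Literal["study2_like", "overlap_arithmetic", "favorable_drug"]


class FixtureBundle(BaseModel, arbitrary_types_allowed=True):
    name: str
    corpus: Optional[EvidenceCorpus] = None
    cohort: list[PatientCase] = Field(default_factory=list)
    system_outputs: dict[str, tuple] = Field(default_factory=dict)
    expected: dict[str, float] = Field(default_factory=dict)


def _beneficial_truth(catalogue: OutcomeCatalogue, magnitude: float = 0.8) -> dict[str, float]:
    """Sign the configured SMD so every efficacy outcome truly improves."""
    out = {}
    for o in catalogue.by_kind("efficacy"):
        out[o.outcome_id] = magnitude if o.benefit_direction == "increase-is-good" else -magnitude
    return out


def study2_like_config() -> SimulationConfig:
    catalogue = default_catalogue()
    benefit = _beneficial_truth(catalogue, 0.5)
    drugs = {}
    for drug in ("methylphenidate", "lisdexamfetamine", "dexamphetamine",
                 "atomoxetine", "guanfacine", "viloxazine"):
        drugs[drug] = DrugTruth(
            n_trials=3,
            n_per_arm=40,
            smd=benefit if drug != "viloxazine" else {},
            odds_ratio={"appetite_decrease": 1.8, "insomnia": 1.5},
            eligibility="pediatric",
        )
    return SimulationConfig(drugs=drugs, n_patients=32)


def end_to_end_fixture(name: FixtureName, seed: int = 20240117) -> FixtureBundle:
    """Deterministic corpus + cohort bundles used by the evaluation suite."""
    if name == "study2_like":
        config = study2_like_config()
        corpus = generate_corpus(config, seed)
        cohort = generate_patients(config, seed)
        # exactly one patient carries the comorbidity that triggers every
        # encoded CPG's second-line rule
        idx = int(np.random.default_rng(seed + 2).integers(len(cohort)))
        for i, case in enumerate(cohort):
            case.profile.comorbidities.discard("tics_disorder")
            if i == idx:
                case.profile.comorbidities.add("tics_disorder")
        return FixtureBundle(name=name, corpus=corpus, cohort=cohort)

    if name == "overlap_arithmetic":
        config = SimulationConfig(n_patients=32)
        cohort = generate_patients(config, seed)
        for case in cohort:
            case.profile.comorbidities.discard("tics_disorder")
        # 16 favorable engine sets, 7 of which share a drug with the NICE set
        # ({methylphenidate} for every pediatric patient without tics)
        engine_sets: list[frozenset[str]] = []
        for i in range(32):
            if i < 7:
                engine_sets.append(frozenset({"methylphenidate", "lisdexamfetamine"}))
            elif i < 16:
                engine_sets.append(frozenset({"atomoxetine"}))
            else:
                engine_sets.append(frozenset())
        nice_sets = [frozenset({"methylphenidate"})] * 32
        return FixtureBundle(
            name=name,
            cohort=cohort,
            system_outputs={"tdapp": tuple(engine_sets), "NICE": tuple(nice_sets)},
            expected={"overlap_all_patients": 21.9, "overlap_favorable_only": 43.8},
        )

    if name == "favorable_drug":
        catalogue = default_catalogue()
        harm_ids = [o.outcome_id for o in catalogue.outcomes if o.scale == "dichotomous"]
        config = SimulationConfig(
            drugs={
                "methylphenidate": DrugTruth(
                    n_trials=4,
                    n_per_arm=300,
                    smd=_beneficial_truth(catalogue, 0.8),
                    # mildly protective everywhere: truly no harm signal
                    odds_ratio={oid: 0.8 for oid in harm_ids},
                    baseline_risk=0.12,
                    rob_mix=["low"],
                    eligibility="broad",
                ),
                "viloxazine": DrugTruth(
                    n_trials=4,
                    n_per_arm=300,
                    # slightly worse than placebo on efficacy, real harm on a
                    # critical safety outcome and on discontinuation
                    smd={o.outcome_id: (0.1 if o.benefit_direction == "decrease-is-good" else -0.1)
                         for o in catalogue.by_kind("efficacy")},
                    odds_ratio={"seizures": 3.0, "treatment_discontinuation": 3.0},
                    baseline_risk=0.12,
                    rob_mix=["low"],
                    eligibility="broad",
                ),
            },
            n_patients=40,
            preferences=PreferenceModel(ensure_efficacy_critical=True),
        )
        corpus = generate_corpus(config, seed)
        cohort = generate_patients(config, seed)
        return FixtureBundle(name=name, corpus=corpus, cohort=cohort)

    raise ValueError(f"unknown fixture name {name!r}")
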