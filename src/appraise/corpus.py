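"""Domain model and I/O for the evidence corpus, outcome catalogue and patient records.

The corpus schema is this package's own: a single JSON document (canonical) or a
CSV bundle of five tables (``trials.csv``, ``arms.csv``, ``arm_outcomes.csv``,
``outcomes.csv``, ``drugs.csv``; cohorts add ``patients.csv`` and ``ratings.csv``).
Both dialects round-trip bit-stably.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

OutcomeKind = Literal["efficacy", "safety", "discontinuation"]
OutcomeScale = Literal["continuous", "dichotomous"]
BenefitDirection = Literal["decrease-is-good", "increase-is-good"]
RiskOfBias = Literal["low", "some-concerns", "high"]
Sex = Literal["male", "female"]

PLACEBO = "placebo"
NO_TREATMENT = "no_treatment"

#: pediatric/adult boundary in whole years
ADULT_AGE = 18


class SchemaError(ValueError):
    """Raised when an input file violates the documented corpus schema."""


class OutcomeDefinition(BaseModel):
    outcome_id: str
    label: str
    kind: OutcomeKind
    scale: OutcomeScale
    benefit_direction: Optional[BenefitDirection] = None
    event_is_harm: Optional[bool] = None

    @model_validator(mode="after")
    def _check_scale_fields(self) -> "OutcomeDefinition":
        if self.scale == "continuous":
            if self.benefit_direction is None:
                raise ValueError(f"{self.outcome_id}: continuous outcome needs benefit_direction")
        else:
            if self.event_is_harm is None:
                raise ValueError(f"{self.outcome_id}: dichotomous outcome needs event_is_harm")
        if self.kind == "discontinuation" and self.scale != "dichotomous":
            raise ValueError(f"{self.outcome_id}: discontinuation outcomes are dichotomous")
        return self


class OutcomeCatalogue(BaseModel):
    outcomes: list[OutcomeDefinition]
    provisional: bool = False

    @field_validator("outcomes")
    @classmethod
    def _unique_ids(cls, v: list[OutcomeDefinition]) -> list[OutcomeDefinition]:
        ids = [o.outcome_id for o in v]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate outcome ids: {dupes}")
        return v

    def __getitem__(self, outcome_id: str) -> OutcomeDefinition:
        for o in self.outcomes:
            if o.outcome_id == outcome_id:
                return o
        raise KeyError(outcome_id)

    def __contains__(self, outcome_id: str) -> bool:
        return any(o.outcome_id == outcome_id for o in self.outcomes)

    def __len__(self) -> int:
        return len(self.outcomes)

    def ids(self) -> list[str]:
        return [o.outcome_id for o in self.outcomes]

    def by_kind(self, kind: OutcomeKind) -> list[OutcomeDefinition]:
        return [o for o in self.outcomes if o.kind == kind]


class EligibilityCriteria(BaseModel):
    age_min: int
    age_max: int
    sexes_allowed: set[Sex] = Field(default_factory=lambda: {"male", "female"})
    required_diagnosis: str = "adhd"
    excluded_comorbidities: set[str] = Field(default_factory=set)
    excluded_cotreatments: set[str] = Field(default_factory=set)
    min_severity: Optional[float] = None
    other_flags: dict[str, bool] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _age_order(self) -> "EligibilityCriteria":
        if self.age_min > self.age_max:
            raise ValueError(f"age_min {self.age_min} > age_max {self.age_max}")
        return self


class ContinuousSummary(BaseModel):
    mean: float
    sd: float = Field(gt=0)


class DichotomousSummary(BaseModel):
    events: int = Field(ge=0)


class ArmSummary(BaseModel):
    arm_role: Literal["intervention", "placebo"]
    drug: str
    dose_mg_per_day: Optional[float] = None
    n: int = Field(ge=1)
    continuous: dict[str, ContinuousSummary] = Field(default_factory=dict)
    dichotomous: dict[str, DichotomousSummary] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ArmSummary":
        if self.arm_role == "placebo" and self.drug != PLACEBO:
            raise ValueError("placebo arm must carry drug 'placebo'")
        if self.arm_role == "intervention" and self.drug == PLACEBO:
            raise ValueError("intervention arm may not be 'placebo'")
        for oid, s in self.dichotomous.items():
            if s.events > self.n:
                raise ValueError(f"outcome {oid}: events {s.events} > n {self.n}")
        return self

    def measures(self, outcome_id: str) -> bool:
        return outcome_id in self.continuous or outcome_id in self.dichotomous


class TrialRecord(BaseModel):
    trial_id: str
    drug: str
    dose_mg_per_day: Optional[float] = None
    drug_class: str
    year: int
    risk_of_bias: RiskOfBias
    endpoint_summaries: bool = False  # False => change-from-baseline summaries
    eligibility: EligibilityCriteria
    arms: list[ArmSummary] = Field(min_length=2)

    @model_validator(mode="after")
    def _check_arms(self) -> "TrialRecord":
        placebo = [a for a in self.arms if a.arm_role == "placebo"]
        if len(placebo) != 1:
            raise ValueError(f"trial {self.trial_id}: exactly one placebo arm required")
        return self

    @property
    def placebo_arm(self) -> ArmSummary:
        return next(a for a in self.arms if a.arm_role == "placebo")

    @property
    def intervention_arm(self) -> ArmSummary:
        return next(a for a in self.arms if a.arm_role == "intervention")

    def dose_bucket(self) -> str:
        return "flexible" if self.dose_mg_per_day is None else f"{self.dose_mg_per_day:g}"


class DrugInfo(BaseModel):
    code: str
    name: str
    drug_class: str
    approved_adhd: bool = True
    targets: set[str] = Field(default_factory=set)
    modes: set[str] = Field(default_factory=set)
    chemical_family: str = ""
    enantiomer_of: Optional[str] = None
    prodrug_of: Optional[str] = None


class DrugRegistry(BaseModel):
    drugs: list[DrugInfo]

    def __getitem__(self, code: str) -> DrugInfo:
        for d in self.drugs:
            if d.code == code:
                return d
        raise KeyError(code)

    def __contains__(self, code: str) -> bool:
        return any(d.code == code for d in self.drugs)

    def codes(self) -> list[str]:
        return [d.code for d in self.drugs]


class PatientProfile(BaseModel):
    patient_id: str
    age: int = Field(ge=6, le=65)
    sex: Sex
    adhd_subtype: Literal["inattentive", "hyperactive", "combined"]
    symptom_severity: float
    comorbidities: set[str] = Field(default_factory=set)
    current_treatments: set[str] = Field(default_factory=set)
    history_failures: set[str] = Field(default_factory=set)
    history_serious_ae: set[str] = Field(default_factory=set)
    psychotherapy_flag: bool = False

    @property
    def age_band(self) -> str:
        return "adult" if self.age >= ADULT_AGE else "pediatric"


class RatingRecord(BaseModel):
    outcome_id: str
    rater: Literal["patient", "clinician"]
    score: int = Field(ge=1, le=9)


class PatientCase(BaseModel):
    profile: PatientProfile
    ratings: list[RatingRecord] = Field(default_factory=list)
    missing_ratings: list[str] = Field(default_factory=list)

    @property
    def case_id(self) -> str:
        return self.profile.patient_id

    def ratings_for(self, rater: str) -> list[RatingRecord]:
        return [r for r in self.ratings if r.rater == rater]


class EvidenceCorpus(BaseModel):
    catalogue: OutcomeCatalogue
    registry: DrugRegistry
    trials: list[TrialRecord] = Field(default_factory=list)


class Finding(BaseModel):
    severity: Literal["error", "warning"]
    record_id: str
    message: str


class ValidationReport(BaseModel):
    findings: list[Finding] = Field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]


# ---------------------------------------------------------------------------
# packaged defaults


def default_catalogue() -> OutcomeCatalogue:
    """The packaged 18-entry outcome catalogue (provisional)."""
    text = resources.files("appraise.data").joinpath("outcomes.json").read_text()
    return OutcomeCatalogue.model_validate(json.loads(text))


def default_registry() -> DrugRegistry:
    """The packaged drug registry with pharmacological profiles."""
    text = resources.files("appraise.data").joinpath("drugs.json").read_text()
    return DrugRegistry.model_validate(json.loads(text))


# ---------------------------------------------------------------------------
# validation


def validate_corpus(corpus: EvidenceCorpus) -> ValidationReport:
    """Check cross-references and arm-level invariants; findings are data, not exceptions."""
    findings: list[Finding] = []

    def err(rid: str, msg: str) -> None:
        findings.append(Finding(severity="error", record_id=rid, message=msg))

    for trial in corpus.trials:
        if trial.drug not in corpus.registry:
            err(trial.trial_id, f"unknown drug reference '{trial.drug}'")
        placebo_arms = [a for a in trial.arms if a.arm_role == "placebo"]
        if len(placebo_arms) != 1:
            err(trial.trial_id, "trial must have exactly one placebo arm")
        for i, arm in enumerate(trial.arms):
            rid = f"{trial.trial_id}/arm{i}"
            if arm.arm_role == "intervention" and arm.drug != trial.drug:
                err(rid, f"intervention arm drug '{arm.drug}' differs from trial drug '{trial.drug}'")
            for oid in list(arm.continuous) + list(arm.dichotomous):
                if oid not in corpus.catalogue:
                    err(rid, f"unknown outcome reference '{oid}'")
            for oid, s in arm.dichotomous.items():
                if s.events > arm.n:
                    err(rid, f"outcome {oid}: events {s.events} > n {arm.n}")
            for oid, s in arm.continuous.items():
                if s.sd <= 0:
                    err(rid, f"outcome {oid}: sd must be > 0")
            scale_errs = [
                oid for oid in arm.continuous
                if oid in corpus.catalogue and corpus.catalogue[oid].scale != "continuous"
            ] + [
                oid for oid in arm.dichotomous
                if oid in corpus.catalogue and corpus.catalogue[oid].scale != "dichotomous"
            ]
            for oid in scale_errs:
                err(rid, f"outcome {oid}: summary type does not match catalogue scale")
    return ValidationReport(findings=findings)


# ---------------------------------------------------------------------------
# JSON dialect


def save_corpus(corpus: EvidenceCorpus, path: str | Path) -> None:
    Path(path).write_text(corpus.model_dump_json(indent=1) + "\n")


def _load_corpus_json(path: Path) -> EvidenceCorpus:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    try:
        corpus = EvidenceCorpus.model_validate(data)
    except Exception as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    report = validate_corpus(corpus)
    if not report.ok:
        msgs = "; ".join(f"{f.record_id}: {f.message}" for f in report.errors())
        raise SchemaError(f"{path}: {msgs}")
    return corpus


# ---------------------------------------------------------------------------
# CSV bundle dialect


def _na(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or v == ""


def save_corpus_csv(corpus: EvidenceCorpus, outdir: str | Path) -> None:
    """Write the CSV bundle (UTF-8, comma, header row, '.' decimal)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "outcome_id": o.outcome_id,
                "label": o.label,
                "kind": o.kind,
                "scale": o.scale,
                "benefit_direction": o.benefit_direction or "",
                "event_is_harm": "" if o.event_is_harm is None else o.event_is_harm,
                "provisional": corpus.catalogue.provisional,
            }
            for o in corpus.catalogue.outcomes
        ]
    ).to_csv(outdir / "outcomes.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        [
            {
                "code": d.code,
                "name": d.name,
                "drug_class": d.drug_class,
                "approved_adhd": d.approved_adhd,
                "targets": ";".join(sorted(d.targets)),
                "modes": ";".join(sorted(d.modes)),
                "chemical_family": d.chemical_family,
                "enantiomer_of": d.enantiomer_of or "",
                "prodrug_of": d.prodrug_of or "",
            }
            for d in corpus.registry.drugs
        ]
    ).to_csv(outdir / "drugs.csv", index=False, float_format="%.17g")

    trial_rows, arm_rows, ao_rows = [], [], []
    for t in corpus.trials:
        e = t.eligibility
        trial_rows.append(
            {
                "trial_id": t.trial_id,
                "drug": t.drug,
                "dose_mg_per_day": "" if t.dose_mg_per_day is None else t.dose_mg_per_day,
                "drug_class": t.drug_class,
                "year": t.year,
                "risk_of_bias": t.risk_of_bias,
                "endpoint_summaries": t.endpoint_summaries,
                "age_min": e.age_min,
                "age_max": e.age_max,
                "sexes_allowed": ";".join(sorted(e.sexes_allowed)),
                "required_diagnosis": e.required_diagnosis,
                "excluded_comorbidities": ";".join(sorted(e.excluded_comorbidities)),
                "excluded_cotreatments": ";".join(sorted(e.excluded_cotreatments)),
                "min_severity": "" if e.min_severity is None else e.min_severity,
            }
        )
        for i, a in enumerate(t.arms):
            arm_id = f"{t.trial_id}/arm{i}"
            arm_rows.append(
                {
                    "trial_id": t.trial_id,
                    "arm_id": arm_id,
                    "arm_role": a.arm_role,
                    "drug": a.drug,
                    "dose_mg_per_day": "" if a.dose_mg_per_day is None else a.dose_mg_per_day,
                    "n": a.n,
                }
            )
            for oid, s in sorted(a.continuous.items()):
                ao_rows.append({"arm_id": arm_id, "outcome_id": oid, "mean": s.mean, "sd": s.sd, "events": ""})
            for oid, s in sorted(a.dichotomous.items()):
                ao_rows.append({"arm_id": arm_id, "outcome_id": oid, "mean": "", "sd": "", "events": s.events})
    pd.DataFrame(trial_rows).to_csv(outdir / "trials.csv", index=False, float_format="%.17g")
    pd.DataFrame(arm_rows).to_csv(outdir / "arms.csv", index=False, float_format="%.17g")
    pd.DataFrame(ao_rows).to_csv(outdir / "arm_outcomes.csv", index=False, float_format="%.17g")


def _split_set(v) -> set[str]:
    if _na(v):
        return set()
    return {s for s in str(v).split(";") if s}


def _load_corpus_csv(bundle_dir: Path) -> EvidenceCorpus:
    for fname in ("outcomes.csv", "drugs.csv", "trials.csv", "arms.csv", "arm_outcomes.csv"):
        if not (bundle_dir / fname).exists():
            raise SchemaError(f"{bundle_dir}: missing bundle file {fname}")

    out_df = pd.read_csv(bundle_dir / "outcomes.csv", float_precision="round_trip")
    outcomes = []
    for _, r in out_df.iterrows():
        outcomes.append(
            OutcomeDefinition(
                outcome_id=r["outcome_id"],
                label=r["label"],
                kind=r["kind"],
                scale=r["scale"],
                benefit_direction=None if _na(r.get("benefit_direction")) else r["benefit_direction"],
                event_is_harm=None if _na(r.get("event_is_harm")) else bool(r["event_is_harm"]),
            )
        )
    provisional = bool(out_df["provisional"].iloc[0]) if "provisional" in out_df else False
    catalogue = OutcomeCatalogue(outcomes=outcomes, provisional=provisional)

    drug_df = pd.read_csv(bundle_dir / "drugs.csv", float_precision="round_trip")
    registry = DrugRegistry(
        drugs=[
            DrugInfo(
                code=r["code"],
                name=r["name"],
                drug_class=r["drug_class"],
                approved_adhd=bool(r["approved_adhd"]),
                targets=_split_set(r.get("targets")),
                modes=_split_set(r.get("modes")),
                chemical_family="" if _na(r.get("chemical_family")) else r["chemical_family"],
                enantiomer_of=None if _na(r.get("enantiomer_of")) else r["enantiomer_of"],
                prodrug_of=None if _na(r.get("prodrug_of")) else r["prodrug_of"],
            )
            for _, r in drug_df.iterrows()
        ]
    )

    arm_out = pd.read_csv(bundle_dir / "arm_outcomes.csv", float_precision="round_trip")
    by_arm: dict[str, tuple[dict, dict]] = {}
    for _, r in arm_out.iterrows():
        cont, dich = by_arm.setdefault(r["arm_id"], ({}, {}))
        if not _na(r.get("events")):
            dich[r["outcome_id"]] = DichotomousSummary(events=int(r["events"]))
        else:
            cont[r["outcome_id"]] = ContinuousSummary(mean=float(r["mean"]), sd=float(r["sd"]))

    arms_df = pd.read_csv(bundle_dir / "arms.csv", float_precision="round_trip")
    arms_by_trial: dict[str, list[ArmSummary]] = {}
    for _, r in arms_df.iterrows():
        cont, dich = by_arm.get(r["arm_id"], ({}, {}))
        try:
            arm = ArmSummary(
                arm_role=r["arm_role"],
                drug=r["drug"],
                dose_mg_per_day=None if _na(r.get("dose_mg_per_day")) else float(r["dose_mg_per_day"]),
                n=int(r["n"]),
                continuous=cont,
                dichotomous=dich,
            )
        except Exception as exc:
            raise SchemaError(f"arms.csv: record {r['arm_id']}: {exc}") from exc
        arms_by_trial.setdefault(r["trial_id"], []).append(arm)

    trials_df = pd.read_csv(bundle_dir / "trials.csv", float_precision="round_trip")
    trials = []
    for _, r in trials_df.iterrows():
        tid = r["trial_id"]
        try:
            trials.append(
                TrialRecord(
                    trial_id=tid,
                    drug=r["drug"],
                    dose_mg_per_day=None if _na(r.get("dose_mg_per_day")) else float(r["dose_mg_per_day"]),
                    drug_class=r["drug_class"],
                    year=int(r["year"]),
                    risk_of_bias=r["risk_of_bias"],
                    endpoint_summaries=bool(r["endpoint_summaries"]),
                    eligibility=EligibilityCriteria(
                        age_min=int(r["age_min"]),
                        age_max=int(r["age_max"]),
                        sexes_allowed=_split_set(r.get("sexes_allowed")) or {"male", "female"},
                        required_diagnosis=r.get("required_diagnosis", "adhd"),
                        excluded_comorbidities=_split_set(r.get("excluded_comorbidities")),
                        excluded_cotreatments=_split_set(r.get("excluded_cotreatments")),
                        min_severity=None if _na(r.get("min_severity")) else float(r["min_severity"]),
                    ),
                    arms=arms_by_trial.get(tid, []),
                )
            )
        except Exception as exc:
            raise SchemaError(f"trials.csv: record {tid}: {exc}") from exc

    corpus = EvidenceCorpus(catalogue=catalogue, registry=registry, trials=trials)
    report = validate_corpus(corpus)
    if not report.ok:
        msgs = "; ".join(f"{f.record_id}: {f.message}" for f in report.errors())
        raise SchemaError(f"{bundle_dir}: {msgs}")
    return corpus


def load_corpus(path: str | Path, format: Optional[str] = None) -> EvidenceCorpus:
    """Load an evidence corpus from a JSON document or a CSV bundle directory.

    Format is inferred from the path when not given: directories are CSV
    bundles, files are JSON.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv-bundle" if path.is_dir() else "json"
    if format == "json":
        return _load_corpus_json(path)
    if format == "csv-bundle":
        return _load_corpus_csv(path)
    raise ValueError(f"unknown corpus format {format!r}")


# ---------------------------------------------------------------------------
# patient records


def save_patient_records(cases: list[PatientCase], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "case_id": c.profile.patient_id,
                "age": c.profile.age,
                "sex": c.profile.sex,
                "adhd_subtype": c.profile.adhd_subtype,
                "symptom_severity": c.profile.symptom_severity,
                "comorbidities": ";".join(sorted(c.profile.comorbidities)),
                "current_treatments": ";".join(sorted(c.profile.current_treatments)),
                "history_failures": ";".join(sorted(c.profile.history_failures)),
                "history_serious_ae": ";".join(sorted(c.profile.history_serious_ae)),
                "psychotherapy_flag": c.profile.psychotherapy_flag,
            }
            for c in cases
        ]
    ).to_csv(outdir / "patients.csv", index=False)
    pd.DataFrame(
        [
            {"case_id": c.profile.patient_id, "rater": r.rater, "outcome_id": r.outcome_id, "score": r.score}
            for c in cases
            for r in c.ratings
        ]
    ).to_csv(outdir / "ratings.csv", index=False)


def load_patient_records(
    path: str | Path, catalogue: Optional[OutcomeCatalogue] = None
) -> list[PatientCase]:
    """Load a cohort from a directory holding ``patients.csv`` and ``ratings.csv``.

    Missing (rater, outcome) ratings are flagged on the case, not imputed.
    """
    path = Path(path)
    catalogue = catalogue or default_catalogue()
    patients_df = pd.read_csv(path / "patients.csv", float_precision="round_trip")
    ratings_df = pd.read_csv(path / "ratings.csv", float_precision="round_trip")

    ratings_by_case: dict[str, list[RatingRecord]] = {}
    for _, r in ratings_df.iterrows():
        score = int(r["score"])
        if not 1 <= score <= 9:
            raise SchemaError(
                f"ratings.csv: case {r['case_id']} outcome {r['outcome_id']}: "
                f"score {score} outside 1-9"
            )
        if r["outcome_id"] not in catalogue:
            raise SchemaError(
                f"ratings.csv: case {r['case_id']}: unknown outcome '{r['outcome_id']}'"
            )
        ratings_by_case.setdefault(str(r["case_id"]), []).append(
            RatingRecord(outcome_id=r["outcome_id"], rater=r["rater"], score=score)
        )

    cases = []
    for _, r in patients_df.iterrows():
        cid = str(r["case_id"])
        try:
            profile = PatientProfile(
                patient_id=cid,
                age=int(r["age"]),
                sex=r["sex"],
                adhd_subtype=r["adhd_subtype"],
                symptom_severity=float(r["symptom_severity"]),
                comorbidities=_split_set(r.get("comorbidities")),
                current_treatments=_split_set(r.get("current_treatments")),
                history_failures=_split_set(r.get("history_failures")),
                history_serious_ae=_split_set(r.get("history_serious_ae")),
                psychotherapy_flag=bool(r["psychotherapy_flag"]),
            )
        except Exception as exc:
            raise SchemaError(f"patients.csv: record {cid}: {exc}") from exc
        ratings = ratings_by_case.get(cid, [])
        have = {(x.rater, x.outcome_id) for x in ratings}
        missing = [
            f"{rater}:{oid}"
            for rater in ("patient", "clinician")
            for oid in catalogue.ids()
            if (rater, oid) not in have
        ]
        cases.append(PatientCase(profile=profile, ratings=ratings, missing_ratings=missing))
    return cases
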