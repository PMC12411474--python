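# appraise

Automated, personalized, participatory GRADE-style treatment recommendations
for ADHD, plus the comparison toolkit needed to evaluate the engine against
encoded clinical-practice-guideline (CPG) recommenders: Blau diversity over
distinct recommendation sets, overlap concordance, a nomenclature-derived
pharmacological distance (0–33), and UPGMA dendrograms.

The engine pipeline per patient:

1. **Preferences** — patient and clinician rate 18 treatment outcomes 1–9;
   ratings ≥ 7 are *critical*. The *comprehensive* rule keeps the union of the
   two critical sets, the *conjoint* rule the intersection.
2. **Matching** — trials whose eligibility criteria the patient meets are
   selected and grouped on a four-level pooling ladder (L1 strict match,
   per drug and dose → L4 minimal match, per drug class).
3. **Evidence synthesis** — per group × critical outcome: standardized mean
   differences (Hedges) or log odds ratios pooled by inverse variance
   (DerSimonian–Laird random effects by default), then GRADE-style quality
   rating with downgrades for risk of bias, heterogeneity and imprecision.
4. **Recommendation** — a risk–benefit judgment (favorable iff a strict
   majority of critical efficacy outcomes improve and no critical safety
   outcome or treatment discontinuation worsens; unfavorable iff the majority
   fails and some harm worsens; otherwise neutral) is mapped to a
   direction (for / against / none) and strength (strong / weak), and an
   explanatory therapeutic report is rendered.

A synthetic-data module generates seeded evidence corpora and patient cohorts
with the statistical structure the engine assumes, so every stage is testable
offline.

## CLI

```sh
appraise simulate --seed 17 --out demo/          # synthetic corpus + cohort
appraise validate demo/corpus.json               # schema and invariant checks
appraise preferences --cohort demo               # critical-preference summary
appraise match     --corpus demo/corpus.json --cohort demo --patient P001 --level L3
appraise recommend --corpus demo/corpus.json --cohort demo --patient P001 \
                   --mode comprehensive --level L3
appraise guideline --id NICE --cohort demo --patient P001
appraise evaluate  --corpus demo/corpus.json --cohort demo \
                   --systems tdapp,NICE,AAP,SHS,CADDRA,AADPA
```

`appraise simulate --fixture {study2_like,overlap_arithmetic,favorable_drug}`
writes the packaged end-to-end fixture bundles.

## Data formats

An evidence corpus is one JSON document (canonical) or a CSV bundle
(`trials.csv`, `arms.csv`, `arm_outcomes.csv`, `outcomes.csv`, `drugs.csv`;
UTF-8, comma separator, header row, `.` decimal). Cohorts are
`patients.csv` + `ratings.csv` (`case_id, rater, outcome_id, score`).
Both dialects round-trip bit-stably. The packaged outcome catalogue
(18 entries, provisional), drug registry with pharmacological profiles, and
editable CPG rulesets (`guidelines/*.yaml`) live under `src/appraise/data/`.
The drug distance matrix is regenerated deterministically from the profiles
and can be exported/overridden as CSV (`DistanceMatrix.to_csv/from_csv`).

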