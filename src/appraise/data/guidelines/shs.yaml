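guideline_id: SHS
version: "2025.1"
description: Stimulant and non-stimulant options; non-stimulants only under a tic-disorder
  contraindication.
rules:
  - id: pediatric-tics-second-line
    when: {age_min: 6, age_max: 17, any_comorbidity: [tics_disorder]}
    recommend: [atomoxetine, guanfacine]
  - id: pediatric-first-line
    when: {age_min: 6, age_max: 17}
    recommend: [methylphenidate, lisdexamfetamine, atomoxetine, guanfacine]
  - id: adult-first-line
    when: {age_min: 18}
    recommend: [methylphenidate, lisdexamfetamine, atomoxetine]
  - id: no-treatment
    when: {}
    recommend: []
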