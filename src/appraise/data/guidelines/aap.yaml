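guideline_id: AAP
version: "2025.1"
description: Stimulant and non-stimulant options for school-age children; non-stimulants
  only when a tic disorder contraindicates stimulants.
rules:
  - id: pediatric-tics-second-line
    when: {age_min: 6, age_max: 17, any_comorbidity: [tics_disorder]}
    recommend: [atomoxetine, clonidine, guanfacine]
  - id: pediatric-first-line
    when: {age_min: 6, age_max: 17}
    recommend: [methylphenidate, dexmethylphenidate, dexamphetamine, lisdexamfetamine,
                mixed_amphetamine_salts, atomoxetine, clonidine, guanfacine]
  - id: adult-first-line
    when: {age_min: 18}
    recommend: [methylphenidate, lisdexamfetamine, atomoxetine]
  - id: no-treatment
    when: {}
    recommend: []
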