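guideline_id: NICE
version: "2025.1"
description: First-line methylphenidate for children and adolescents; non-stimulants
  when stimulants are contraindicated by a tic disorder.
rules:
  - id: pediatric-tics-second-line
    when: {age_min: 6, age_max: 17, any_comorbidity: [tics_disorder]}
    recommend: [atomoxetine, guanfacine]
  - id: pediatric-first-line
    when: {age_min: 6, age_max: 17}
    recommend: [methylphenidate]
  - id: adult-first-line
    when: {age_min: 18}
    recommend: [lisdexamfetamine, methylphenidate]
  - id: no-treatment
    when: {}
    recommend: []
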