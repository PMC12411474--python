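{
  "outcomes": [
    {"outcome_id": "adhd_symptoms", "label": "ADHD symptom improvement", "kind": "efficacy", "scale": "continuous", "benefit_direction": "decrease-is-good"},
    {"outcome_id": "clinical_impression", "label": "Clinical global impression", "kind": "efficacy", "scale": "continuous", "benefit_direction": "decrease-is-good"},
    {"outcome_id": "quality_of_life", "label": "Quality of life", "kind": "efficacy", "scale": "continuous", "benefit_direction": "increase-is-good"},
    {"outcome_id": "academic_performance", "label": "Academic performance", "kind": "efficacy", "scale": "continuous", "benefit_direction": "increase-is-good"},
    {"outcome_id": "emotional_regulation", "label": "Emotional regulation", "kind": "efficacy", "scale": "continuous", "benefit_direction": "increase-is-good"},
    {"outcome_id": "executive_function", "label": "Executive function", "kind": "efficacy", "scale": "continuous", "benefit_direction": "increase-is-good"},
    {"outcome_id": "seizures", "label": "Seizures", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "vasovagal_syncope", "label": "Vasovagal syncope", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "appetite_decrease", "label": "Appetite decrease", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "insomnia", "label": "Insomnia", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "headache", "label": "Headache", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "abdominal_pain", "label": "Abdominal pain", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "irritability", "label": "Irritability", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "tics_worsening", "label": "Tics onset or worsening", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "weight_loss", "label": "Weight loss", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "blood_pressure_increase", "label": "Blood pressure increase", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "anxiety_emergent", "label": "Treatment-emergent anxiety", "kind": "safety", "scale": "dichotomous", "event_is_harm": true},
    {"outcome_id": "treatment_discontinuation", "label": "Treatment discontinuation", "kind": "discontinuation", "scale": "dichotomous", "event_is_harm": true}
  ],
  "provisional": true
}
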