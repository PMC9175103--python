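[
 {
  "query_id": "causal_intra",
  "ordered": true,
  "max_sentence_span": 1,
  "max_intervening_words": 50,
  "require_same_section": true,
  "items": [
   {"classes": ["shoulder_symptom", "shoulder_diagnosis"]},
   {"classes": ["causal_trigger"]},
   {"classes": ["vaccine", "cause_accident", "cause_work", "cause_medical_condition", "cause_exercise", "cause_daily_activity"]}
  ]
 },
 {
  "query_id": "causal_cross",
  "ordered": true,
  "max_sentence_span": 4,
  "max_intervening_words": 50,
  "require_same_section": true,
  "items": [
   {"classes": ["shoulder_symptom", "shoulder_diagnosis"]},
   {"query": {
     "query_id": "trigger_cause",
     "ordered": true,
     "max_sentence_span": 1,
     "max_intervening_words": 3,
     "items": [
      {"classes": ["causal_trigger"]},
      {"classes": ["vaccine", "cause_accident", "cause_work", "cause_medical_condition", "cause_exercise", "cause_daily_activity"]}
     ]
   }}
  ]
 }
]
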