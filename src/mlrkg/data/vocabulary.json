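{
  "comment": "Synthetic themed vocabulary for fixture corpora. Drug-like, symptom-like and comorbidity-like tokens so generated corpora resemble respiratory-medicine text. None of these tokens overlaps the tagger's verb or adposition lexicon, and none contains the default query keyword 'asthma'.",
  "nouns": [
    "budesonide", "formoterol", "tiotropium", "dupilumab", "reslizumab",
    "mepolizumab", "omalizumab", "salbutamol", "corticosteroids",
    "bronchodilator", "inhaler", "spacer", "nebulizer", "eosinophils",
    "neutrophils", "cytokines", "interleukins", "antibodies", "wheezing",
    "coughing", "dyspnea", "tightness", "exacerbations", "remodeling",
    "obesity", "rhinitis", "sinusitis", "bronchitis", "dermatitis",
    "reflux", "apnea", "anxiety"
  ],
  "modifiers": [
    "severe", "mild", "chronic", "acute", "persistent", "inhaled",
    "oral", "nocturnal", "allergic", "refractory", "pediatric", "adult"
  ],
  "verbs": [
    "treats", "causes", "reduces", "induces", "includes", "recommends",
    "improves", "relieves", "prevents", "triggers", "worsens", "controls",
    "suggests", "requires"
  ],
  "prepositional_verbs": [
    ["binds", "to"], ["associated", "with"], ["delivered", "with"]
  ],
  "intransitive_verbs": ["persists"]
}
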