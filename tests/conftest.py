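import pytest

from mlrkg import RuleTagger, Triplet, TripletTable

#: Sixteen asthma-guideline triplets (multi-word entities, surface-form
#: relations, one prepositional relation) used across the CSV and graph
#: round-trip tests.
GUIDELINE_ROWS = [
    ("ICS", "included", "SABA corticosteroid"),
    ("Increase frequency", "add", "SABA spacer"),
    ("acute care Patients", "monitored", "little SABA treatment"),
    ("severe asthma", "improve", "SABA alone"),
    ("ideally SABA reliever", "Reducing", "important asthma treatment"),
    ("current GINA", "recommends", "serious dose ICS exacerbations"),
    ("SABA", "include", "separate inhalers"),
    ("Older inhaler patients", "may", "multiple inhaler devices"),
    ("poor inhaler diagnosis", "appear", "incorrect inhaler technique"),
    ("symptoms", "relieved", "inhaled bronchodilator"),
    ("Oral bronchodilator therapy", "recommended", "inhaled SABA"),
    ("Reslizumab benralizumab", "binds to", "cell eosinophils"),
    ("Mechanism", "signaling", "interleukin-4 receptor IL-4"),
    ("Clinician receptor judgment", "used", "worsening receptor asthma"),
    ("eosinophilic airway patients", "respond", "corticosteroid asthma treatment"),
    ("needed ICS formoterol", "delivered", "symptom relief"),
]


@pytest.fixture
def guideline_table() -> TripletTable:
    rows = [Triplet.from_strings(s, r, o) for s, r, o in GUIDELINE_ROWS]
    return TripletTable(rows=rows, stage_label="guideline")


@pytest.fixture
def tagger() -> RuleTagger:
    return RuleTagger()
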