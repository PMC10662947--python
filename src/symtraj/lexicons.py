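"""Default lexicons: symptom surface forms, suffixes, negation and relation words.

The symptom vocabulary maps lowercase surface forms to ICD-10 level-3
categories, mostly from chapter 18 ("Symptoms, signs and abnormal clinical
and laboratory findings", R00-R99) plus a few non-chapter-18 codes that are
classic pancreatic-cancer presentations (intestinal obstruction, pancreatitis).
It is deliberately small: a reviewable stand-in for a full clinical
dictionary, used both by the synthetic note generator and as the default
tagging vocabulary.
"""

from __future__ import annotations

# surface form (singular, lowercase) -> ICD-10 level-3 code
DEFAULT_SYMPTOM_TERMS: dict[str, str] = {
    "cough": "R05",
    "haemoptysis": "R04",
    "abdominal pain": "R10",
    "nausea": "R11",
    "vomiting": "R11",
    "heartburn": "R12",
    "dysphagia": "R13",
    "jaundice": "R17",
    "ascites": "R18",
    "haematuria": "R31",
    "polyuria": "R35",
    "dizziness": "R42",
    "fever": "R50",
    "headache": "R51",
    "pain": "R52",
    "fatigue": "R53",
    "syncope": "R55",
    "oedema": "R60",
    "weight loss": "R63",
    "anorexia": "R63",
    "cachexia": "R64",
    "intestinal obstruction": "K56",
    "pancreatitis": "K85",
}

# word endings appended to every base term to catch inflected variants
DEFAULT_SUFFIXES: list[str] = ["s", "es"]

# a sentence containing any of these words is treated as negated
NEGATION_LEXICON: frozenset[str] = frozenset(
    {"no", "not", "never", "without", "denies", "negative"}
)

# a sentence containing any of these words is attributed to someone other
# than the patient (family history and the like)
OTHER_PERSON_LEXICON: frozenset[str] = frozenset(
    {
        "mother",
        "father",
        "brother",
        "sister",
        "husband",
        "wife",
        "son",
        "daughter",
        "grandmother",
        "grandfather",
    }
)

# generic hospital-contact code used for encounters that carry no symptom
CONTACT_CODE = "Z76"

# pancreatic cancer, the index diagnosis
CANCER_CODE = "C25"
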