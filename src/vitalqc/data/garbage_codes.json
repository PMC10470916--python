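{
  "provenance": "Default subset of the garbage-code concept introduced by the Global Burden of Disease study: underlying-cause ICD-10 codes that should be redistributed before public-health analysis. Types: 1 = cannot/should not be an underlying cause, 2 = intermediate cause, 3 = immediate cause (final step of a pathway), 4 = non-specific within a broad grouping. This shipped list covers the canonical examples plus ICD-10 Chapter XVIII; supply a complete list as a file with the same structure for production use.",
  "entries": [
    {"start": "M54", "end": "M54", "type": 1, "label": "dorsalgia (low back pain)"},
    {"start": "R00", "end": "R99", "type": 1, "label": "symptoms, signs and ill-defined causes (Chapter XVIII, incl. senility R54)"},
    {"start": "A40", "end": "A41", "type": 2, "label": "streptococcal and other sepsis"},
    {"start": "I50", "end": "I50", "type": 2, "label": "heart failure"},
    {"start": "D65", "end": "D65", "type": 3, "label": "disseminated intravascular coagulation"},
    {"start": "I46", "end": "I46", "type": 3, "label": "cardiac arrest"},
    {"start": "C76", "end": "C76", "type": 4, "label": "malignant neoplasm of ill-defined sites"},
    {"start": "C80", "end": "C80", "type": 4, "label": "malignant neoplasm, unspecified site"},
    {"start": "I519", "end": "I519", "type": 4, "label": "heart disease, unspecified"}
  ]
}
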