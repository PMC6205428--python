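[
 {"study_id": "synthetic_pain_01", "affect": "pain", "aus": [4, 6, 7, 9, 10, 14, 17, 20, 25, 43, 45]},
 {"study_id": "synthetic_pain_02", "affect": "pain", "aus": [4, 6, 7, 9, 10, 12, 17, 20, 26, 27]},
 {"study_id": "synthetic_pain_03", "affect": "pain", "aus": [4, 6, 9, 10, 20, 25, 26, 27, 43, 45]},
 {"study_id": "synthetic_pain_04", "affect": "pain", "aus": [4, 6, 7, 9, 10, 12, 17, 20, 43, 45]},
 {"study_id": "synthetic_pain_05", "affect": "pain", "aus": [4, 6, 9, 10, 12, 15, 20, 25, 26, 27]},
 {"study_id": "synthetic_pain_06", "affect": "pain", "aus": [2, 4, 6, 7, 9, 10, 17, 20, 43, 45]},
 {"study_id": "synthetic_pain_07", "affect": "pain", "aus": [4, 6, 9, 10, 12, 20, 25, 26, 27]},
 {"study_id": "synthetic_pain_08", "affect": "pain", "aus": [4, 6, 7, 9, 10, 17, 20, 43, 45]},
 {"study_id": "synthetic_pain_09", "affect": "pain", "aus": [1, 4, 6, 9, 10, 12, 20, 25, 26, 27]},
 {"study_id": "synthetic_pain_10", "affect": "pain", "aus": [4, 6, 7, 9, 10, 17, 20, 43, 45]},
 {"study_id": "synthetic_pain_11", "affect": "pain", "aus": [4, 6, 9, 10, 12, 20, 25, 26, 27]},
 {"study_id": "synthetic_orgasm_01", "affect": "orgasm", "aus": [4, 6, 10, 25, 26, 27, 43]},
 {"study_id": "synthetic_orgasm_02", "affect": "orgasm", "aus": [4, 6, 10, 12, 25, 26, 27, 43]},
 {"study_id": "synthetic_orgasm_03", "affect": "orgasm", "aus": [4, 6, 25, 26, 27, 43]}
]
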