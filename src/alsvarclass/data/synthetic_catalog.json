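{
  "description": "Synthetic known-variant catalog. A hand-built stand-in for ClinVar/ALSoD-style assertion databases, covering only the amino-acid changes and report counts needed by the packaged worked examples. 'established' marks changes with laboratory-evaluable evidence (PS1/PM5 grade); 'reports' counts independent reputable-source assertions (PP5/BP6 grade).",
  "entries": [
    {"gene": "SOD1", "protein_change": "G73S", "established": true, "asserted_class": "pathogenic", "reports": 3},
    {"gene": "SOD1", "protein_change": "L85F", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "SOD1", "protein_change": "L145F", "established": true, "asserted_class": "pathogenic", "reports": 3},
    {"gene": "SOD1", "protein_change": "L68R", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "SOD1", "protein_change": "D91G", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "SOD1", "protein_change": "G86R", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "SOD1", "protein_change": "G94C", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "SOD1", "protein_change": "I114T", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "SOD1", "protein_change": "D91A", "established": false, "asserted_class": "pathogenic", "reports": 1},
    {"gene": "SOD1", "protein_change": "L68P", "established": false, "asserted_class": "pathogenic", "reports": 1},
    {"gene": "SOD1", "protein_change": "G94D", "established": false, "asserted_class": "pathogenic", "reports": 1},
    {"gene": "SOD1", "protein_change": "I114F", "established": false, "asserted_class": "pathogenic", "reports": 1},
    {"gene": "SOD1", "protein_change": "I150T", "established": false, "asserted_class": "pathogenic", "reports": 1},
    {"gene": "TARDBP", "protein_change": "G294A", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "TARDBP", "protein_change": "G294V", "established": false, "asserted_class": "pathogenic", "reports": 3},
    {"gene": "TARDBP", "protein_change": "G376V", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "TARDBP", "protein_change": "A382T", "established": false, "asserted_class": "pathogenic", "reports": 6},
    {"gene": "FUS", "protein_change": "R514S", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "FUS", "protein_change": "R514G", "established": false, "asserted_class": "pathogenic", "reports": 1},
    {"gene": "VCP", "protein_change": "R155H", "established": true, "asserted_class": "pathogenic", "reports": 0},
    {"gene": "VCP", "protein_change": "R155C", "established": false, "asserted_class": "pathogenic", "reports": 5}
  ]
}
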