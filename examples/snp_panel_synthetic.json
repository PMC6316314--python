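[
  {"rsid": "rs2237892", "risk_allele": "C", "other_allele": "T", "odds_ratio": 1.26},
  {"rsid": "rs2206734", "risk_allele": "T", "other_allele": "C", "odds_ratio": 1.19},
  {"rsid": "rs2383208", "risk_allele": "A", "other_allele": "G", "odds_ratio": 1.20},
  {"rsid": "rs6780569", "risk_allele": "G", "other_allele": "A", "odds_ratio": 1.16},
  {"rsid": "rs1470579", "risk_allele": "C", "other_allele": "A", "odds_ratio": 1.23}
]
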