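{
  "description": "Default mapping from each predictor's native output to a binary deleterious/neutral call. Numeric outputs are compared against 'cutoff' with 'op' (lt/le/gt/ge: deleterious when the comparison holds); string outputs are matched case-insensitively against the label sets. Edit and pass to harmonize_call / the CLI to audit or change any mapping.",
  "tools": {
    "SIFT": {
      "op": "lt",
      "cutoff": 0.05,
      "deleterious_labels": ["deleterious", "damaging", "d"],
      "neutral_labels": ["tolerated", "neutral", "t", "n"]
    },
    "PolyPhen2": {
      "op": "ge",
      "cutoff": 0.5,
      "deleterious_labels": ["probably damaging", "possibly damaging", "damaging", "d", "p"],
      "neutral_labels": ["benign", "neutral", "b", "n"]
    },
    "PhD-SNP": {
      "deleterious_labels": ["disease", "deleterious", "d"],
      "neutral_labels": ["neutral", "n"]
    },
    "SNPs&GO": {
      "deleterious_labels": ["disease", "deleterious", "d"],
      "neutral_labels": ["neutral", "n"]
    },
    "SNAP": {
      "deleterious_labels": ["non-neutral", "nonneutral", "non neutral", "d"],
      "neutral_labels": ["neutral", "n"]
    },
    "FATHMM": {
      "op": "le",
      "cutoff": -1.5,
      "deleterious_labels": ["damaging", "deleterious", "d"],
      "neutral_labels": ["tolerated", "neutral", "t", "n"]
    },
    "PANTHER": {
      "op": "le",
      "cutoff": -3.0,
      "deleterious_labels": ["probably damaging", "possibly damaging", "deleterious", "d"],
      "neutral_labels": ["probably benign", "benign", "neutral", "n"]
    }
  }
}
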