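{
  "description": "Published benchmark of eight missense-effect predictors on IARC-classified BRCA1/BRCA2 variants. 'confusion': Tp/Tn/Fp/Fn counts of each predictor against the binarized five-tier gold standard (classes 4-5 positive, 1-2 negative, 3 excluded). 'printed': the sensitivity (%), specificity (%) and MCC values as printed in the source table, kept as strings to preserve printed precision (some cells are truncated rather than rounded). 'deleterious_counts': per-predictor deleterious call counts over each gene's full retrieved cohort, with the printed percentages; where a predictor returned no output for some variants, 'n_missing' gives the implied gap (printed percentages are over non-missing outputs).",
  "confusion": {
    "BRCA1": {
      "SIFT":     {"tp": 21, "tn": 40, "fp": 52, "fn": 1,  "sensitivity_pct": "95.45", "specificity_pct": "43.48", "mcc": "0.32"},
      "PolyPhen2":{"tp": 20, "tn": 36, "fp": 56, "fn": 2,  "sensitivity_pct": "90.91", "specificity_pct": "39.13", "mcc": "0.2515"},
      "PANTHER":  {"tp": 21, "tn": 63, "fp": 29, "fn": 1,  "sensitivity_pct": "95.45", "specificity_pct": "68.48", "mcc": "0.5085"},
      "PhD-SNP":  {"tp": 22, "tn": 54, "fp": 38, "fn": 0,  "sensitivity_pct": "100",   "specificity_pct": "58.7",  "mcc": "0.4639"},
      "SNPs&GO":  {"tp": 22, "tn": 16, "fp": 76, "fn": 0,  "sensitivity_pct": "100",   "specificity_pct": "17.39", "mcc": "0.197"},
      "SNAP":     {"tp": 22, "tn": 29, "fp": 63, "fn": 0,  "sensitivity_pct": "100",   "specificity_pct": "31.52", "mcc": "0.2856"},
      "FATHMM":   {"tp": 8,  "tn": 52, "fp": 40, "fn": 14, "sensitivity_pct": "36.36", "specificity_pct": "56.5",  "mcc": "-0.0569"},
      "I-Mutant": {"tp": 14, "tn": 30, "fp": 62, "fn": 8,  "sensitivity_pct": "63.64", "specificity_pct": "32.61", "mcc": "-0.0314"}
    },
    "BRCA2": {
      "SIFT":     {"tp": 11, "tn": 42, "fp": 50, "fn": 1,  "sensitivity_pct": "91.6",  "specificity_pct": "45.65", "mcc": "0.2421"},
      "PolyPhen2":{"tp": 12, "tn": 32, "fp": 60, "fn": 0,  "sensitivity_pct": "100",   "specificity_pct": "34.7",  "mcc": "0.24"},
      "PANTHER":  {"tp": 9,  "tn": 41, "fp": 27, "fn": 3,  "sensitivity_pct": "75",    "specificity_pct": "60.29", "mcc": "0.253"},
      "PhD-SNP":  {"tp": 9,  "tn": 80, "fp": 12, "fn": 3,  "sensitivity_pct": "75",    "specificity_pct": "86.95", "mcc": "0.493"},
      "SNPs&GO":  {"tp": 12, "tn": 2,  "fp": 90, "fn": 0,  "sensitivity_pct": "100",   "specificity_pct": "2.17",  "mcc": "0.05"},
      "SNAP":     {"tp": 8,  "tn": 56, "fp": 36, "fn": 4,  "sensitivity_pct": "66.67", "specificity_pct": "60.8",  "mcc": "0.178"},
      "FATHMM":   {"tp": 12, "tn": 65, "fp": 27, "fn": 0,  "sensitivity_pct": "100",   "specificity_pct": "70.65", "mcc": "0.466"},
      "I-Mutant": {"tp": 8,  "tn": 42, "fp": 50, "fn": 4,  "sensitivity_pct": "66.67", "specificity_pct": "45.65", "mcc": "0.079"}
    }
  },
  "deleterious_counts": {
    "BRCA1": {
      "n_total": 520,
      "SIFT": {"n_deleterious": 337, "printed_pct": "64.8"},
      "PolyPhen2": {"n_deleterious": 335, "printed_pct": "64.4"},
      "PANTHER": {"n_deleterious": 198, "printed_pct": "38"},
      "SNAP": {"n_deleterious": 327, "printed_pct": "62.8"},
      "SNPs&GO": {"n_deleterious": 459, "printed_pct": "88.2"},
      "PhD-SNP": {"n_deleterious": 254, "printed_pct": "48.8"},
      "FATHMM": {"n_deleterious": 223, "printed_pct": "42.8"}
    },
    "BRCA2": {
      "n_total": 814,
      "SIFT": {"n_deleterious": 356, "printed_pct": "43.7"},
      "PolyPhen2": {"n_deleterious": 438, "printed_pct": "53.8"},
      "PANTHER": {"n_deleterious": 242, "printed_pct": "37.6", "n_missing": 170},
      "SNAP": {"n_deleterious": 273, "printed_pct": "33.5"},
      "SNPs&GO": {"n_deleterious": 766, "printed_pct": "94.1"},
      "PhD-SNP": {"n_deleterious": 111, "printed_pct": "13.6"},
      "FATHMM": {"n_deleterious": 260, "printed_pct": "31.9"}
    }
  }
}
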