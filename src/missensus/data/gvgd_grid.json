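{
  "description": "Grade boundaries for the GV/GD classifier. A substitution receives the highest grade whose boundary it meets: GD >= intercept + slope * GV; substitutions below every boundary are C0. Default boundaries are a linear reconstruction anchored to the grade names (GD intercepts 15..65 at GV = 0, an invariant position) and to the classical binary rule that GV <= 61.3 with GD >= 61.3 is deleterious: the slope places the point (GV=61.3, GD=61.3) exactly on the C45 boundary. Edit to substitute an alternative grid.",
  "deleterious_grades": ["C45", "C55", "C65"],
  "slope": 0.2659053833605221,
  "boundaries": [
    {"grade": "C65", "intercept": 65.0},
    {"grade": "C55", "intercept": 55.0},
    {"grade": "C45", "intercept": 45.0},
    {"grade": "C35", "intercept": 35.0},
    {"grade": "C25", "intercept": 25.0},
    {"grade": "C15", "intercept": 15.0}
  ]
}
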