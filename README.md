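# missensus

Consensus classification of missense variants, built around the analysis
style used for BRCA1/BRCA2 variants of uncertain significance (VUS):
harmonize the verdicts of several in-silico effect predictors, score
substitutions biophysically against an ortholog alignment, apply protein-
stability thresholds, aggregate everything into a vote rank, and benchmark
any caller against a five-tier clinical gold standard.

It is aimed at researchers who already have per-variant outputs from tools
such as SIFT, PolyPhen2, PhD-SNP, SNPs&GO, SNAP, FATHMM, PANTHER, I-Mutant,
FoldX and ConSurf (the package never runs those servers) and want a tested,
auditable pipeline from raw tool outputs to ranked calls and performance
metrics.

## What it computes

**Harmonization.** Each predictor's native score or label is mapped to a
binary deleterious/neutral call through an editable JSON rule table
(e.g. SIFT score < 0.05 ⇒ deleterious). Missing outputs stay missing.

**Grantham variation / deviation (GV/GD).** At an alignment position, the
residues observed across orthologs span ranges in Grantham's three
physicochemical properties — composition *c*, polarity *p*, volume *v*.
With the classical constants (α = 1.833, β = 0.1018, γ = 0.000399,
ρ = 50.723):

    GV = ρ · [α·(Δc)² + β·(Δp)² + γ·(Δv)²]^½   over the per-property ranges
    GD = ρ-scaled distance of the mutant's (c, p, v) to the range box

GD = 0 whenever the mutant lies inside the tolerated ranges. The (GV, GD)
pair maps to grades C0 (most likely neutral) … C65 (most likely
deleterious) via a bundled, editable grid; C45/C55/C65 count as
deleterious. `grantham_distance` reproduces the published 20×20 integer
matrix to rounding.

**Stability rules.** I-Mutant-style ΔΔG is banded (neutral in [−0.5, 0.5]
kcal/mol inclusive, large decrease below, large increase above) with two
binary modes (`sign`: deleterious iff ΔΔG < 0; `band`). FoldX-style
ΔΔG = ΔG(MT) − ΔG(WT) is stabilizing (< 0), destabilizing (0 < ΔΔG ≤ 3)
or highly destabilizing (> 3 kcal/mol, flagged pathogenic; cutoff
configurable).

**Vote rank.** Seven tools vote (SIFT, PhD-SNP, PolyPhen2, SNPs&GO, SNAP,
FATHMM, I-Mutant): 0–1 deleterious votes ⇒ rank 1, 2–3 ⇒ rank 2, 4–5 ⇒
rank 3, 6–7 ⇒ rank 4; ranks 3–4 are the deleterious consensus. A variant
is *extremely deleterious* when all seven vote deleterious **and** its
GV/GD grade is C45/C55/C65.

**Benchmarking.** Against the IARC-style five-tier classification
(4/5 positive, 1/2 negative, class 3 = VUS excluded):

    Sensitivity = Tp/(Tp+Fn),  Specificity = Tn/(Tn+Fp)
    MCC = (Tp·Tn − Fp·Fn) / √((Tp+Fp)(Tp+Fn)(Tn+Fp)(Tn+Fn))

**Conservation.** Consensus-deleterious vs neutral ConSurf grades (1–9)
compared with a two-sided Mann-Whitney U test plus a common-language
effect size.

**Synthetic cohorts.** A seeded generator emulates the assembled variant
table — latent pathogenic/benign labels, per-tool operating points
(defaulting to the bundled published BRCA1 benchmark), two-component ΔΔG
channels, label-shifted conservation grades and a VUS fraction — so every
stage is testable without running any external predictor.

## Worked example

```python
from missensus import (ConfusionMatrix, sensitivity, specificity, mcc,
                       CohortConfig, simulate_cohort, evaluate_all)
from missensus.pipeline import annotate_records

# a predictor that called 21 of 22 pathogenic and 63 of 92 benign correctly
cm = ConfusionMatrix(tp=21, tn=63, fp=29, fn=1)
print(f"sensitivity = {sensitivity(cm):.2f}%")
print(f"specificity = {specificity(cm):.2f}%")
print(f"MCC         = {mcc(cm):.4f}")

# simulate 1000 variants at the bundled benchmark's operating points,
# harmonize + rank them, and benchmark every tool and the consensus
records = simulate_cohort(CohortConfig(n_variants=1000, seed=1))
annotate_records(records)
table = evaluate_all(records).table
print(table[["sensitivity_pct", "specificity_pct", "mcc"]].round(2))
```

prints

```
sensitivity = 95.45%
specificity = 68.48%
MCC         = 0.5085

            sensitivity_pct  specificity_pct   mcc
classifier
SIFT                  97.89            43.86  0.35
PhD-SNP              100.00            60.00  0.49
PolyPhen2             88.95            43.17  0.27
SNPs&GO              100.00            16.55  0.20
SNAP                 100.00            31.59  0.30
FATHMM                30.00            55.86 -0.12
I-Mutant              65.26            32.41 -0.02
PANTHER               93.90            66.98  0.49
consensus            100.00            29.10  0.28
```

The first block is the confusion-matrix arithmetic on one predictor's
counts. The table shows each simulated tool recovering roughly its
configured operating point (e.g. SIFT was configured at 95.45 % / 43.48 %),
and the seven-tool consensus inheriting the voters' high sensitivity at
the cost of specificity — the behaviour that motivates requiring *all*
tools to agree before flagging a variant extremely deleterious.

A CLI mirrors the library (`missensus simulate | score-gvgd |
classify-stability | rank | benchmark | conservation | report | run`);
`missensus run --config cfg.json` executes the full pipeline and writes
an annotated table plus a JSON report.

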