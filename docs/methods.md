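# Methods

This note documents the models and rules the package implements, the
choices made where the published descriptions leave latitude, and what
the synthetic-data tests do and do not establish.

## Variant model

Variants are single amino-acid substitutions in 1-based protein
coordinates, restricted to the 20 standard residues (selenocysteine and
ambiguity codes are rejected; the analysis' physicochemical machinery is
undefined for them). One-letter, three-letter and `p.`-prefixed
spellings are accepted and normalized; the canonical output form is
three-letter (`Cys64Gly`). No nucleotide or transcript coordinates are
modelled — every rule in the pipeline operates at the protein-change
level. Missing tool outputs are first-class: empty table cells become
missing values, never zeros, and each stage states explicitly how it
treats them.

## Grantham machinery

`grantham_distance` evaluates the 1974 quadratic form over side-chain
composition, polarity and volume with α = 1.833, β = 0.1018,
γ = 0.000399 and ρ = 50.723 (mean pairwise distance ≈ 100). The bundled
integer matrix is this form rounded to integers; the test suite anchors
it to 54 independently transcribed entries of the published matrix and
requires ±1 agreement (rounding) on all 190 pairs.

**GV** is the Grantham-form length of the per-property min–max ranges of
the residues observed at an alignment position (gaps dropped — the score
is defined over residue physicochemistry only, so a gap carries no
information here). **GD** is the Grantham-form distance from the
mutant's property point to the nearest face of that range box, zero
inside it. Two useful degenerate cases fall out of the definitions and
are used as test oracles: a two-residue column's GV equals the pairwise
distance, and a single-residue column's GD equals the distance to that
residue.

### Grade grid

The C0–C65 grade boundaries are a bundled, editable JSON table rather
than hard-coded constants, because the seven-grade grid is not printed
in the source material this package follows and no reference
implementation was available to transcribe. The default grid is a
linear-boundary reconstruction with two anchors taken from the
published classifier family:

* at GV = 0 (invariant position) the GD thresholds are the grade names
  themselves, 15, 25, …, 65;
* the slope (61.3 − 45)/61.3 places the classical binary-rule corner
  (GV = 61.3, GD = 61.3 ⇒ deleterious) exactly on the C45 boundary.

A substitution gets the highest grade whose boundary
GD ≥ intercept + slope·GV it meets (boundaries inclusive, with a 1e-9
epsilon against float noise); anything below every boundary is C0.
This guarantees the structural properties the analysis relies on —
grades partition the whole (GV, GD) quadrant, are monotone in GD at
fixed GV, mutant-within-range always grades C0 — but absolute grade
assignments near the boundaries should be treated as grid-dependent;
users comparing against another implementation should load that
implementation's grid. Grade counts on real cohorts are additionally
alignment-dependent (depth and taxon sampling), which is why the tests
assert grid properties rather than any published grade histogram.

## Stability rules

The SVM-channel (I-Mutant-style) ΔΔG is banded with the published
boundaries, ±0.5 kcal/mol inclusive into neutral. Two binary modes are
exposed because the published usage is internally inconsistent: the
band rule follows the tool's three-class definition, while the results
being reproduced use the sign rule (any ΔΔG < 0 deleterious). The
default is `sign`, matching the results-level usage; `band` is a config
switch.

The force-field channel (FoldX-style) classifies ΔΔG = ΔG(MT) − ΔG(WT):
negative stabilizing, positive destabilizing, above +3.0 kcal/mol
highly destabilizing and flagged pathogenic. The cutoff is a config
value (the +3.0 default traces to experimentally calibrated designs).
ΔΔG exactly 0 falls in neither published half-line; it is kept as an
explicit neutral-zero category rather than silently assigned, and
collapses to neutral in binary calls. The category depends only on the
difference, checked by a translation-invariance property test.

## Vote rank and the extreme flag

Exactly seven named tools vote; PANTHER is summarized but never votes
(it frequently returns no score, and the rank bins are defined over
seven voters). Missing votes count as non-deleterious — the
conservative reading of bins defined over a fixed denominator — and are
tallied in `n_missing` so users can filter on completeness instead.
The rank is `n_deleterious // 2 + 1`; tests check it against an
explicit bin table over all 128 call vectors. The extremely-deleterious
flag is the conjunction of all seven votes plus a deleterious GV/GD
grade; any missing input makes it false (with the reason logged), never
an error, since an eight-way conjunction with an unknown conjunct
cannot be affirmed.

## Benchmarking

Gold classes 4/5 are positives, 1/2 negatives, class 3 (VUS) excluded:
a variant of uncertain significance cannot anchor either truth label.
This binarization is config-visible, and per-tool evaluable counts are
always reported because published per-tool denominators differ (tools
miss different variants). Sensitivity, specificity and MCC use their
standard forms; a printed MCC formula in the source material is
typographically garbled and the standard form is implemented. Metrics
with zero denominators raise an undefined-metric signal rather than
returning 0 or 1 — MCC with a zero marginal is genuinely undefined.
MCC is cross-checked in tests against the Pearson correlation of the
binary indicator vectors, which it equals algebraically.

The bundled reference benchmark (`data/reference_benchmark.json`)
carries a published 2 genes × 8 predictors table of confusion counts
with the printed metric values. The printed values mix rounding and
truncation (e.g. 11/12 printed as 91.6), so reproduction tests assert
agreement at each cell's printed precision under either convention.
One printed distribution percentage implies a reduced denominator
(242 deleterious "37.6 %" ⇒ 644 non-missing of 814); the data file
records the implied 170 missing outputs, consistent with percentages
being computed over non-missing calls.

## Conservation comparison

Grades are ordinal 1–9 with heavy ties, so the two groups are compared
with a two-sided Mann-Whitney U test (tie-corrected normal
approximation) rather than a t-test; the choice is visible in the
report. The effect is summarized by the common-language effect size
P(deleterious grade > neutral grade) + ½P(tie), which makes the
antisymmetry property (swap groups ⇒ e → 1 − e) exact. The 1–3 / 4–6 /
7–9 reporting bins are symmetric around the scale's stated anchor
points (1 variable, 5 average, 9 conserved) and are never used in the
test itself. When every grade in both groups is identical the test is
degenerate and the comparison reports p = 1 directly.

## Synthetic cohorts

The generator emulates the assembled analysis table, not the upstream
tools: a latent Bernoulli(prevalence) label (default 0.2, near the
positive fraction of the bundled benchmark's evaluable variants), and
per-tool calls drawn conditionally independently given the label at
configured operating points (defaults: the benchmark's BRCA1 column).
Raw outputs are emitted on each tool's native scale (SIFT scores,
PolyPhen2 labels, FATHMM scores, …) so simulated tables exercise the
same harmonization path as real ones. PANTHER output is missing with
probability 0.1 by default, mirroring its known gaps.

The SVM stability channel draws the binary call from its operating
point and then a sign-consistent magnitude (half-normal, means 1.0/0.3
kcal/mol), so the sign rule reproduces the drawn call exactly and
parameter recovery holds for all seven voters. The force-field channel
is a two-component normal mixture (benign N(0, 1), pathogenic
N(3.5, 1.5) kcal/mol) chosen so the +3.0 cutoff is high-specificity /
moderate-sensitivity. Conservation grades come from two discrete
distributions over 1–9, pathogenic mass shifted toward 9. Gold classes
follow the label (4/5 vs 1/2, uniformly) with a 10 % VUS override by
default. All draws come from one `numpy` generator seeded from the
config, making tables byte-reproducible.

What passing tests show: the pipeline's stages compose correctly, the
metrics recover configured operating points within binomial error
(3 SDs at n = 5000, seeds 1–3), VUS records never move a metric, and
the conservation contrast is detected at the configured shift. What
they do not show: behaviour under correlated tool errors (a correlation
knob is deliberately out of scope in v1 — conditional independence is
the simplest testable structure, and real predictors sharing training
data will violate it), realistic alignment phylogenetics (MSA columns
are i.i.d. draws from allowed residue sets, sufficient for GV/GD
oracles but not a substitution-model simulation), or the true cohort
composition of any real gene.

## Problem sizes

The default test suite runs cohorts up to n = 5000 (three seeds) and
exhaustive enumerations up to ~10⁵ points; `scripts/acceptance.py`
uses one n = 5000 cohort per seed plus the closed-form table
computations. These sizes put Monte-Carlo error well inside the
asserted 3-SD envelopes while keeping a full run in seconds.

## Known limitations

* The grade grid is a documented reconstruction (see above), not a
  transcription of the original classifier's thresholds.
* Harmonization defaults (SIFT < 0.05, PolyPhen2 damaging labels,
  FATHMM ≤ −1.5, PANTHER ≤ −3) are field-standard cutoffs shipped as
  data; the material being reproduced never states its own, so users
  replicating a specific study should supply that study's table.
* Cohort-scale published counts that depend on running the external
  predictors (per-tool deleterious totals, grade histograms, extreme
  variant lists, FoldX operating points) are covered by the synthetic
  route and property tests, not reproduced.
* No ROC/AUC over continuous scores: the consensus scheme consumes
  binary calls only. No weighted or probabilistic ensemble is provided;
  the implemented scheme is deliberately the unweighted vote.
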