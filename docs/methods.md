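# Methods

## Problem and model

A breast tumour arising in a carrier of a pathogenic germline *BRCA1* or
*BRCA2* variant is very likely to show homologous-recombination
deficiency (HRD), while tumours of non-carriers are mostly HR-proficient
(HRP). The package treats a tumour's predicted HR category as a
diagnostic test for germline pathogenicity and calibrates it as a
likelihood ratio (LR): the probability of observing the category in
carriers divided by the probability in non-carriers. Under Bayes'
theorem this LR multiplies the prior odds that the patient's germline
variant is pathogenic, so it can be carried into ACMG/AMP variant
classification as a weighted evidence item.

The unit of observation is the patient (one tumour per patient); LRs are
estimated cross-sectionally from a case–control contrast of group
proportions, not from per-variant segregation. Evidence for a specific
variant is then the evidence attached to the category its carrier's
tumour falls in.

## Patient grouping

Variants in the 11-gene panel (*BRCA1*, *BRCA2*, *ATM*, *BARD1*,
*BRIP1*, *CHEK2*, *PALB2*, *PTEN*, *RAD51C*, *RAD51D*, *TP53*) are
collapsed to three classes. Precedence: an explicit precomputed class
wins; then a gnomAD filtering allele frequency (FAF) ≥ 1e-4 forces
B/LB (too common for a high-penetrance allele); then ClinVar P/LP and
B/LB are taken as-is; anything else with a usable annotation is a VUS.
Bioinformatic scores (BayesDel, SpliceAI, CADD) never set the class;
they may only derive the *suspicious VUS* flag, whose cutoffs are left
to the user because no canonical values exist.

Categories cross class with gene set (A/C/E for *BRCA1/2* × P/LP, VUS,
B/LB; B/D/F for the other nine genes, a suspicious VUS joining B
conservatively). Group assignment precedence: any B → Excluded;
only-D → Excluded; A in *BRCA1* → BRCA1-positive (wins over *BRCA2*,
with a warning — no real patient forces the choice); A in *BRCA2* →
BRCA2-positive; any C → BRCA1/2-VUS; else negative. Two deliberately
resolved ambiguities, both configurable:

* **A + plain D** (a BRCA P/LP plus a non-suspicious other-gene VUS)
  goes to the positive group — the Excluded-for-VUS rule is read as
  applying only when the VUS is the patient's most significant finding.
* **C + D** goes to BRCA1/2-VUS (C outranks D), because the VUS-group
  definition requires only the absence of other *P/LP* variants.

The sensitivity re-analysis bypasses the Excluded rules for category-A
carriers, adding them to the case groups; the remaining Excluded
patients stay out of the analysis by default (a flag can move them into
the controls instead, since either reading is defensible).

## HR status calls

Published decision thresholds are applied as strict inequalities for the
probabilistic tools and inclusively for the scar score: CHORD > 0.5,
HRDetect > 0.7, HRDsum ≥ 42. CHORD's gene subtype is taken from the
larger of its BRCA1-type/BRCA2-type component probabilities when that
maximum reaches 0.5; ties or smaller maxima yield *undetermined*. This
is a surrogate for CHORD's own undetermined logic (which depends on
internal mutation counts); the 0.5 floor is configurable. A missing
score is a missing-data marker, not an error, and drops the patient from
that tool's tables only.

## Scar counters

HRDsum = HRD-LOH + LST + NtAI over allele-specific copy-number segments
(0-based half-open coordinates; 1-based input convertible on read).
Operational definitions follow the widely used genomic-scar conventions,
all lengths configurable:

* **HRD-LOH**: segments with minor allele count 0, ≥ 15 Mb, not spanning
  the whole chromosome.
* **LST**: after dropping fragments < 3 Mb and re-merging equal-copy
  neighbours separated by < 3 Mb, breakpoints between two segments each
  ≥ 10 Mb with a gap < 3 Mb; breakpoints at the centromere (the gap
  interval intersects it) are not counted.
* **NtAI**: maximal contiguous runs of allelic imbalance (major ≠ minor)
  that touch a chromosome end, stay on one arm, do not span the whole
  chromosome, and are ≥ 11 Mb.

Allelic imbalance is not ploidy-normalised (AI ≡ major ≠ minor); a
whole-genome-duplicated tumour would need ploidy-aware preprocessing
upstream. Each counter is verified against an independent brute-force
scanner on randomly generated small profiles, and the preprocessing
guarantees order- and refinement-invariance (splitting a segment into
equal-copy pieces never changes a count).

## Likelihood ratios and evidence

With category count x of n in each group, `p = (x + c)/(n + 2c)` where
the Haldane correction `c = 0.5` is applied to all four implicit 2×2
cells exactly when either count is zero — the simple rule that keeps
degenerate categories estimable. The CI is the Katz log-scale Wald
interval with z = 1.96. In subtype-stratified tables, undetermined-
subtype HRD patients remain in the denominators but in no subtype
numerator, so the subtype rows plus undetermined partition the HRD row.

Evidence mapping uses exponential scaling of the Very Strong odds
(default 350): pathogenic boundaries 350^(1/8) ≈ 2.08, 350^(1/4) ≈ 4.33,
350^(1/2) ≈ 18.71, 350, inclusive on the extreme side; reciprocals with
negated points on the benign side. A 95% CI containing 1 forces zero
points: the label is *Not significant* when the point estimate would
otherwise have reached a tier, and *Indeterminate* when the estimate
itself falls between the innermost boundaries. The gate is configurable
off. Display rounding is 2 decimals; computation is full precision.

Reported proportions in the table are the raw x/n (the corrected values
enter only the LR and CI), matching how such tables are conventionally
printed.

For VUS carriers, the per-variant report assigns the calibration row
matching the carrier's tumour: the gene's stratified subtype row for a
concordant HRD subtype, the dichotomous HRD row for an undetermined
subtype, the HRP row for a proficient tumour, and zero points for an HRD
tumour of the *opposite* subtype — a mismatched deficiency pattern is
not evidence about this gene's variant.

## Association statistics

Chi-square tests are Pearson without Yates correction (configurable);
zero-marginal rows/columns are dropped with a warning. Cramér's
V = sqrt(chi2 / (n·(min(r,c)−1))) without bias correction. The Wilcoxon
rank-sum test uses exact enumeration when both samples have ≤ 8
observations and no ties, otherwise the normal approximation with
midrank-tie and continuity corrections (which agrees with the exact
p-value to < 0.02 at n = 8). Missing marker values are excluded per
variable, never imputed.

## Synthetic cohorts

The **fixture** mode emits, deterministically and independently of the
seed, a 350-patient cohort whose germline partition (27 / 21 / 232 / 62
/ 8) and group × HR-status cross-tabulation equal the reference cohort's
— including 2 HRP and 2 BRCA1-type tumours among the 21 BRCA2-positive
patients, the 17 / 15 / 3 subtype split of the 35 HRD negatives, 13 HRD
tumours among the 36 Excluded P/LP carriers, and the 2 + 3 category-A
carriers inside Excluded that the sensitivity analysis recovers (their
HR status is not printed anywhere and is set to concordant-subtype HRD,
which keeps the evidence categories unchanged under re-analysis, as
reported qualitatively). Variant rows are constructed so that curation
reassigns exactly the intended group, exercising every classification
path (ClinVar lookups, the FAF rule, suspicious VUS, score-only VUS,
structural-variant rows). ER-negative and grade-3 frequencies follow the
printed per-group proportions; PR/HER2 frequencies are not printed and
are plausible defaults. Tumour purity is fixed at the cohort mean 0.58.

The **stochastic** mode samples HR status, subtype, scores and markers
per patient from the configured conditionals (defaults = the fixture
frequencies). Scores are *threshold-consistent draws* — uniform strictly
above or below each cutoff, with subtype components at 0.9/0.05 (or
0.43/0.43 for undetermined) of the HRD probability — because no per-group
score distributions are available to emulate; the calibration consumes
only the dichotomised calls, so passing tests validate the decision
logic, not realistic score shapes.

The copy-number generator works on a 22-chromosome toy genome (240 Mb
down to 72 Mb, 3 Mb centromeres at 40% of each length). An HRD
chromosome receives a ≥ 16 Mb interstitial q-arm LOH block (1 LOH +
2 LSTs) with probability 0.9 and a ≥ 12 Mb p-telomeric imbalance (1 NtAI
+ 1 LST) with probability 0.6, giving an expected HRDsum of ~86; HRP
chromosomes receive only sub-threshold events (rate 0.1), scoring 0.
This is a consistency harness for the counters, not a model of real
breast-cancer copy-number evolution: real profiles have focal events,
whole-genome duplication and noisy segmentation that the generator does
not attempt.

## Problem sizes and numerical choices

The test suite runs the oracle comparison on 500+ random two-chromosome
profiles, simulator recovery at n = 2000 per group, generator/scorer
agreement on 400 profiles, and CI coverage on 1000 simulated tables —
sizes chosen to make binomial noise negligible relative to the tested
tolerances while keeping the whole suite under a minute of CPU.
Degenerate inputs are handled explicitly: empty variant tables partition
everyone to negative; a tool calling everything HRP still yields a
well-defined (corrected, gated) table; empty VUS reports are valid.

## Known limitations

* The calibration assumes one tumour per patient and independence of
  patients; multi-tumour LR multiplication is out of scope.
* The printed reference table contains one internally inconsistent point
  estimate (a stratified LR printed as 23.65 whose own CI (8.64, 21.57)
  matches the value 13.65 computed from its printed counts); the package
  reports the computed value and the test suite asserts the
  inconsistency rather than reproducing the misprint.
* CHORD's and HRDetect's internal classifiers are consumed as scores,
  never re-implemented; full VCEP classification logic is likewise out
  of scope (a precomputed class column bypasses the collapse).
* HR evidence is not combined with other ACMG/AMP codes into a final
  classification.
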