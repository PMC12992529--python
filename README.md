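# hrdevidence

Calibration of breast-tumour **homologous-recombination (HR) status** as
weighted ACMG/AMP evidence for germline *BRCA1*/*BRCA2* variant
classification.

Pathogenic germline variants in *BRCA1* and *BRCA2* leave a recognisable
footprint of homologous-recombination deficiency (HRD) in the tumour
genome. Tools such as CHORD, HRDetect and the HRDsum genomic-scar score
predict a tumour's HR status from somatic sequencing data; this package
turns those predictions into *quantitative germline evidence*: how much
does observing an HRD (or HR-proficient) breast tumour shift the odds that
a germline *BRCA1*/*BRCA2* variant carried by that patient is pathogenic?

It is aimed at variant curators and statistical-genetics researchers who
want to reproduce, stress-test or extend this calibration on their own
cohorts — or on fully synthetic ones.

## What it computes

For a case group (patients carrying a pathogenic/likely pathogenic
*BRCA1* or *BRCA2* variant) versus the *BRCA1/2*-negative control group,
the likelihood ratio for an HR category is the ratio of proportions

```
LR = p_case / p_ctrl,        p = (x + c) / (n + 2c)
```

with a Haldane continuity correction `c = 0.5` on all cells whenever a
category count is zero, and a Katz log-scale Wald 95% CI

```
exp( ln LR ± 1.96 · sqrt( (1−p_case)/((n_case+2c)·p_case) + (1−p_ctrl)/((n_ctrl+2c)·p_ctrl) ) ).
```

LRs map to ACMG/AMP evidence through the Bayesian points framework
(Very Strong odds = 350): boundaries `350^(1/8)`, `350^(1/4)`,
`350^(1/2)`, `350` on the pathogenic side, their reciprocals on the
benign side, points ±1/±2/±4/±8. An LR whose 95% CI includes 1
contributes no evidence.

The package also provides:

- **variant curation** — collapse of ClinVar/gnomAD annotations to
  P/LP / VUS / B/LB, the six categories A–F across an 11-gene panel, and
  the five-group patient partition (BRCA1-positive, BRCA2-positive,
  negative, Excluded, BRCA1/2-VUS);
- **HR calling** — dichotomisation at CHORD > 0.5, HRDetect > 0.7,
  HRDsum ≥ 42, plus CHORD BRCA1-type/BRCA2-type subtype attribution and
  cross-tool concordance;
- **scar scores** — HRD-LOH, LST and NtAI counters over allele-specific
  copy-number segments, summing to HRDsum;
- **a cohort simulator** — a deterministic 350-patient fixture whose
  group × HR-status cross-tabulation matches the published reference
  cohort, a stochastic mode with configurable conditional probabilities,
  and a copy-number profile generator;
- **association statistics** — chi-square / Cramér's V / Wilcoxon
  rank-sum links between HR status and histopathology markers.

## Worked example

```python
from hrdevidence import (fixture_cohort, partition_cohort, call_cohort,
                         build_calibration_table)

cohort = fixture_cohort()                                    # 350 patients
groups, counts = partition_cohort(cohort.variants, cohort.samples)
print(counts.to_dict())
# {'BRCA1_positive': 27, 'BRCA2_positive': 21, 'negative': 232,
#  'excluded': 62, 'BRCA12_VUS': 8}

calls = call_cohort(cohort.scores, "CHORD")
table = build_calibration_table(groups, calls)
print(table[["gene", "section", "category", "lr", "ci_low", "ci_high",
             "strength", "points"]].to_string(index=False))
```

```
 gene     section          category    lr  ci_low  ci_high            strength  points
BRCA1 dichotomous               HRP  0.02    0.00     0.33       Benign Strong      -4
BRCA1 dichotomous               HRD  6.63    4.88     9.00 Pathogenic Moderate       2
BRCA1  stratified               HRP  0.02    0.00     0.33       Benign Strong      -4
BRCA1  stratified HRD_BRCA1_subtype 13.65    8.64    21.57 Pathogenic Moderate       2
BRCA1  stratified HRD_BRCA2_subtype  0.27    0.02     4.37     Not significant       0
BRCA2 dichotomous               HRP  0.11    0.03     0.42     Benign Moderate      -2
BRCA2 dichotomous               HRD  6.00    4.29     8.39 Pathogenic Moderate       2
BRCA2  stratified               HRP  0.11    0.03     0.42     Benign Moderate      -2
BRCA2  stratified HRD_BRCA1_subtype  1.30    0.32     5.25       Indeterminate       0
BRCA2  stratified HRD_BRCA2_subtype 12.52    7.36    21.31 Pathogenic Moderate       2
```

Reading: an HRD breast tumour in a *BRCA1* carrier versus a non-carrier
multiplies the odds of pathogenicity by 6.63 (Pathogenic Moderate, +2
points); an HR-proficient tumour is strong benign evidence (−4). The
CHORD gene subtype sharpens this: a BRCA1-type HRD tumour gives LR 13.65
for *BRCA1*, while an HRD tumour of the *opposite* subtype is not
significant and contributes nothing.

The same pipeline is exposed on the command line
(`hrdevidence simulate | curate | call-hr | score-scars | calibrate |
report-vus | associate`); each subcommand reads and writes plain TSV.

## Layout

- `src/hrdevidence/curation.py` — class collapse, categories, groups
- `src/hrdevidence/hrcalls.py` — thresholds, subtypes, concordance
- `src/hrdevidence/scars.py`, `genome.py` — scar counters and annotation
- `src/hrdevidence/calibration.py` — LRs, CIs, evidence, reports
- `src/hrdevidence/association.py` — histopathology associations
- `src/hrdevidence/simulate.py` — fixture and stochastic cohorts, segments
- `docs/methods.md` — model, assumptions, parameter choices, limitations
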